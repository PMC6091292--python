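"""Classification-based evaluation of the prioritized pathways.

Feature genes are harvested from pathways in final rank order (within a
pathway, by descending |t|), capped at k (default 80), and fed to a
linear-kernel SVM under repeated stratified 10-fold cross-validation; the
mean held-out AUC is compared against a plain t-test gene ranking of the
same size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .candidate_genes import DEGSet, PathwayCandidateMap
from .io_formats import ExpressionMatrix, PhenotypeVector
from .ranking import RankResult

logger = logging.getLogger(__name__)


@dataclass
class FeatureGeneSet:
    """Ordered feature genes with (pathway, pathway-rank) provenance."""

    genes: list[str]
    provenance: list[tuple[str, int]]
    k: int

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate feature gene")
        if len(self.genes) > self.k:
            raise ValueError("more features than target size k")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CVResult:
    """Per-fold AUCs of repeated stratified cross-validation."""

    fold_aucs: np.ndarray  # (repeats, folds)
    folds: int
    repeats: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(self.fold_aucs.mean())


def select_feature_genes(
    result: RankResult,
    pcm: PathwayCandidateMap,
    degs: DEGSet,
    k: int = 80,
) -> FeatureGeneSet:
    """Greedy harvest: pathways in rank order, genes by descending |t| within.

    De-duplicates genes appearing in several top pathways; stops at k or
    when candidates are exhausted (then returns fewer, with a warning).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    t_by_gene = dict(zip(degs.table["gene"], np.abs(degs.table["t"])))
    genes: list[str] = []
    provenance: list[tuple[str, int]] = []
    seen: set[str] = set()
    for rank, pathway in enumerate(result.ordering, 1):
        if pathway not in pcm.candidates:
            continue
        members = sorted(pcm[pathway], key=lambda g: (-t_by_gene.get(g, 0.0), g))
        for g in members:
            if g in seen:
                continue
            seen.add(g)
            genes.append(g)
            provenance.append((pathway, rank))
            if len(genes) == k:
                return FeatureGeneSet(genes, provenance, k)
    logger.warning("select_feature_genes: only %d of %d requested genes available", len(genes), k)
    return FeatureGeneSet(genes, provenance, k)


def _default_classifier():
    # standardize then linear-kernel max-margin classifier, default C
    return make_pipeline(StandardScaler(), SVC(kernel="linear"))


def cv_auc(
    expr: ExpressionMatrix,
    pheno: PhenotypeVector,
    features: FeatureGeneSet | list[str],
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    classifier_factory=None,
) -> CVResult:
    """Repeated stratified k-fold AUC of a classifier on the feature genes.

    Each repeat reshuffles the stratified folds with a seed derived from
    ``seed``; per-fold AUC comes from held-out decision scores.  Bit-for-bit
    reproducible under a fixed seed.
    """
    pheno = pheno.aligned_to(expr)
    gene_list = features.genes if isinstance(features, FeatureGeneSet) else list(features)
    if not gene_list:
        raise ValueError("no feature genes")
    x = expr.subset_genes(gene_list).T  # samples x features
    y = pheno.labels
    factory = classifier_factory or _default_classifier
    aucs = np.empty((repeats, folds))
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for fold, (train, test) in enumerate(skf.split(x, y)):
            if len(set(y[train])) < 2 or len(set(y[test])) < 2:
                raise ValueError("a fold lost one phenotype class; reduce fold count")
            clf = factory()
            clf.fit(x[train], y[train])
            scores = clf.decision_function(x[test])
            aucs[rep, fold] = roc_auc_score(y[test], scores)
    return CVResult(aucs, folds, repeats, seed)


def ttest_baseline(
    expr: ExpressionMatrix, pheno: PhenotypeVector, k: int = 80
) -> FeatureGeneSet:
    """Top-k genes by ascending Welch t-test p-value (ties by gene id)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    pheno = pheno.aligned_to(expr)
    case = expr.values[:, pheno.labels == 1]
    ctrl = expr.values[:, pheno.labels == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    order = sorted(range(expr.n_genes), key=lambda i: (p[i], expr.gene_ids[i]))[:k]
    genes = [expr.gene_ids[i] for i in order]
    return FeatureGeneSet(genes, [("ttest", 0)] * len(genes), k)
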