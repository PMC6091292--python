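"""Differential expression, PPI filtering and pathway projection.

The candidate gene set (CGS) is the subset of differentially expressed
genes (DEGs) that share at least one PPI edge with another DEG — genes
whose expression change is supported by a physical interaction partner
that also changed.  Candidates are then projected onto each pathway's
member list; pathways left with no candidate are dropped, since the
downstream activity score averages over candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, PathwayCollection, PhenotypeVector, PPINetwork

logger = logging.getLogger(__name__)

#: finite sentinel replacing an infinite t statistic (zero variance, unequal means)
T_SENTINEL = 1e12


@dataclass
class DEGSet:
    """Per-gene Welch t statistics with BH-adjusted significance calls.

    ``table`` holds one row per gene of the expression matrix (columns:
    gene, t, p, q, diff, flagged); ``genes`` is the selected DEG set.
    """

    table: pd.DataFrame
    genes: set[str]
    q_threshold: float
    min_abs_diff: float

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def abs_t(self, gene: str) -> float:
        return float(abs(self.table.set_index("gene").at[gene, "t"])) if gene else 0.0


@dataclass
class CandidateGeneSet:
    """DEGs retained because both endpoints of a PPI edge are DEGs."""

    genes: set[str]

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PathwayCandidateMap:
    """Pathway -> candidate genes present in the expression matrix.

    ``candidates`` preserves pathway-file gene order; ``full_sizes`` keeps
    the original pathway gene count (used by the enrichment test, whose
    universe is the whole pathway, not just measured candidates).
    """

    candidates: dict[str, list[str]]
    full_sizes: dict[str, int]

    @property
    def names(self) -> list[str]:
        return list(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __getitem__(self, name: str) -> list[str]:
        return self.candidates[name]


def differential_genes(
    expr: ExpressionMatrix,
    pheno: PhenotypeVector,
    q_threshold: float = 0.05,
    min_abs_diff: float = 1.0,
) -> DEGSet:
    """Welch two-sample t-test per gene with Benjamini-Hochberg adjustment.

    A gene is called differential when its BH-adjusted q is at most
    ``q_threshold`` AND its absolute mean (case - control) difference is at
    least ``min_abs_diff`` (1.0 on a log2 scale = 2-fold change).

    Genes with zero variance in both groups get t = 0 when the means agree
    and a large finite sentinel (flagged) when they differ.
    """
    pheno = pheno.aligned_to(expr)
    labels = pheno.labels
    case = expr.values[:, labels == 1]
    ctrl = expr.values[:, labels == 0]
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("each phenotype class needs at least 2 samples")

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    diff = case.mean(axis=1) - ctrl.mean(axis=1)

    zero_var = (case.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
    equal_means = zero_var & (diff == 0)
    degenerate = zero_var & (diff != 0)
    t = np.where(equal_means, 0.0, t)
    p = np.where(equal_means, 1.0, p)
    t = np.where(degenerate, np.sign(diff) * T_SENTINEL, t)
    p = np.where(degenerate, 0.0, p)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    selected = (q <= q_threshold) & (np.abs(diff) >= min_abs_diff)

    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "t": t,
            "p": p,
            "q": q,
            "diff": diff,
            "flagged": degenerate,
        }
    )
    genes = set(np.array(expr.gene_ids, dtype=object)[selected])
    logger.info("differential_genes: %d / %d genes selected", len(genes), expr.n_genes)
    return DEGSet(table, genes, q_threshold, min_abs_diff)


def ppi_filter(degs: DEGSet, ppi: PPINetwork) -> CandidateGeneSet:
    """Union of endpoints over PPI edges whose BOTH endpoints are DEGs."""
    cgs: set[str] = set()
    for a, b in ppi.edges:
        if a in degs.genes and b in degs.genes:
            cgs.add(a)
            cgs.add(b)
    if not cgs:
        logger.warning("ppi_filter: empty candidate gene set")
    return CandidateGeneSet(cgs)


def map_to_pathways(
    cgs: CandidateGeneSet,
    pathways: PathwayCollection,
    expr: ExpressionMatrix,
) -> PathwayCandidateMap:
    """Project candidates onto pathways; drop pathways with no candidate.

    A candidate must also be measured (present in the expression matrix) to
    count; gene order follows the pathway file.
    """
    candidates: dict[str, list[str]] = {}
    full_sizes: dict[str, int] = {}
    dropped = 0
    for name, members in pathways.entries.items():
        kept = [g for g in members if g in cgs.genes and g in expr]
        if kept:
            candidates[name] = kept
            full_sizes[name] = len(members)
        else:
            dropped += 1
    if dropped:
        logger.info("map_to_pathways: dropped %d pathway(s) with no candidates", dropped)
    return PathwayCandidateMap(candidates, full_sizes)
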