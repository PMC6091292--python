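"""End-to-end orchestration: inputs -> DEG -> CGS -> activity/MI -> network
-> GeneRank -> enrichment -> evaluation, with reproducible run metadata.

Every stage's intermediate is written to the output directory, and the
metadata JSON records all parameters, the seed, and the counts at each
stage so a run can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from importlib.metadata import version as pkg_version
from pathlib import Path

import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import activity_mi, candidate_genes, evaluation, io_formats, ranking, similarity_network

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed in a data-dependent way (not a format problem)."""


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    expression: str
    phenotype: str
    gene_sets: str
    ppi: str
    ontology: str
    annotations: str
    q_threshold: float = 0.05
    min_abs_diff: float = 1.0
    theta: float | None = None  # absolute threshold; None -> percentile rule
    theta_percentile: float = 75.0
    d: float = 0.85
    epsilon: float = 1e-10
    max_iter: int = 1000
    k_features: int = 80
    folds: int = 10
    repeats: int = 10
    seed: int = 0
    weighted_network: bool = False
    namespaces: tuple[str, ...] = io_formats.NAMESPACES
    bh_on_enrichment: bool = False
    genome_size: int | None = None  # enrichment universe; None -> expression genes
    exclude_iea: bool = False
    run_evaluation: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.q_threshold <= 1.0:
            raise ValueError("q_threshold must lie in (0, 1]")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("damping d must lie in [0, 1]")
        if not 0.0 <= self.theta_percentile <= 100.0:
            raise ValueError("theta_percentile must lie in [0, 100]")
        if self.folds < 2 or self.repeats < 1 or self.k_features < 1:
            raise ValueError("folds >= 2, repeats >= 1, k_features >= 1 required")
        self.namespaces = tuple(self.namespaces)
        for ns in self.namespaces:
            if ns not in io_formats.NAMESPACES:
                raise ValueError(f"unknown namespace {ns!r}")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key:value YAML config; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class AnalysisResult:
    """In-memory outputs of the ranking stages (no evaluation)."""

    degs: candidate_genes.DEGSet
    cgs: candidate_genes.CandidateGeneSet
    pcm: candidate_genes.PathwayCandidateMap
    profile: activity_mi.ActivityProfile
    net: similarity_network.PathwaySimilarityNetwork
    theta: float
    result: ranking.RankResult


def analyze(
    expr,
    pheno,
    pathways,
    ppi,
    dag,
    ann,
    q_threshold: float = 0.05,
    min_abs_diff: float = 1.0,
    theta: float | None = None,
    theta_percentile: float = 75.0,
    d: float = 0.85,
    epsilon: float = 1e-10,
    max_iter: int = 1000,
    weighted_network: bool = False,
    namespaces=io_formats.NAMESPACES,
    genome_size: int | None = None,
) -> AnalysisResult:
    """Run DEG -> CGS -> activity/MI -> network -> GeneRank on in-memory inputs."""
    pheno = pheno.aligned_to(expr)
    degs = candidate_genes.differential_genes(expr, pheno, q_threshold, min_abs_diff)
    cgs = candidate_genes.ppi_filter(degs, ppi)
    if not cgs.genes:
        raise PipelineError(
            "empty candidate gene set: no PPI edge joins two differential genes; "
            "relax q_threshold / min_abs_diff or check identifier spaces"
        )
    pcm = candidate_genes.map_to_pathways(cgs, pathways, expr)
    if len(pcm) < 2:
        raise PipelineError("fewer than 2 pathways retain candidate genes")
    profile = activity_mi.profile_from_candidates(pcm, expr, pheno)
    sim, _ = similarity_network.similarity_matrix(pcm, ann, dag, None, tuple(namespaces))
    theta_eff = (theta if theta is not None
                 else similarity_network.percentile_threshold(sim, theta_percentile))
    net = similarity_network.build_network(sim, theta_eff, pcm.names, weighted_network)
    universe = genome_size or expr.n_genes
    nd = len(degs.genes)
    enrich = []
    for name in pcm.names:
        members = pathways[name]
        x = sum(1 for g in members if g in degs.genes)
        enrich.append(ranking.EnrichmentInput(universe, nd, len(members), x))
    result = ranking.rank_pathways(profile.mi, net, enrich, d, epsilon, max_iter,
                                   [len(pcm[n]) for n in pcm.names])
    return AnalysisResult(degs, cgs, pcm, profile, net, theta_eff, result)


def run(config: RunConfig, out_dir, stop_after: str | None = None) -> dict:
    """Execute the pipeline, writing intermediates and metadata to ``out_dir``.

    ``stop_after`` in {"deg", "activity", "similarity", "rank"} truncates the
    run after that stage (None runs everything).  Returns the metadata dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "parameters": _config_dict(config),
        "package_version": _safe_version(),
        "counts": {},
    }

    expr = io_formats.read_expression(config.expression)
    pheno = io_formats.read_phenotype(config.phenotype).aligned_to(expr)
    pathways = io_formats.read_gene_sets(config.gene_sets)
    ppi = io_formats.read_ppi(config.ppi)
    meta["counts"]["genes"] = expr.n_genes
    meta["counts"]["samples"] = expr.n_samples
    meta["counts"]["pathways_input"] = len(pathways)
    meta["counts"]["ppi_edges"] = len(ppi)
    logger.info("inputs: %d genes x %d samples, %d pathways, %d PPI edges",
                expr.n_genes, expr.n_samples, len(pathways), len(ppi))

    # --- differential genes ------------------------------------------------
    degs = _stage("deg", candidate_genes.differential_genes,
                  expr, pheno, config.q_threshold, config.min_abs_diff)
    degs.table.to_csv(out / "deg_table.tsv", sep="\t", index=False)
    meta["counts"]["degs"] = len(degs.genes)
    if stop_after == "deg":
        return _finish(meta, out)

    cgs = _stage("ppi_filter", candidate_genes.ppi_filter, degs, ppi)
    meta["counts"]["cgs"] = len(cgs)
    if not cgs.genes:
        raise PipelineError(
            "empty candidate gene set: no PPI edge joins two differential genes; "
            "relax q_threshold / min_abs_diff or check identifier spaces"
        )
    pcm = _stage("map_to_pathways", candidate_genes.map_to_pathways, cgs, pathways, expr)
    meta["counts"]["pathways_retained"] = len(pcm)
    if len(pcm) < 2:
        raise PipelineError("fewer than 2 pathways retain candidate genes")

    # --- activity + mutual information -------------------------------------
    profile = _stage("activity", activity_mi.profile_from_candidates, pcm, expr, pheno)
    pd.DataFrame(profile.activity, index=profile.pathway_names,
                 columns=expr.sample_ids).to_csv(out / "activity.tsv", sep="\t", index_label="pathway")
    pd.DataFrame({"pathway": profile.pathway_names, "mi": profile.mi}).to_csv(
        out / "mi.tsv", sep="\t", index=False)
    if stop_after == "activity":
        return _finish(meta, out)

    # --- similarity network -------------------------------------------------
    dag = io_formats.read_ontology(config.ontology)
    ann = io_formats.read_annotations(config.annotations, dag, config.exclude_iea)
    sim, _ = _stage("similarity", similarity_network.similarity_matrix,
                    pcm, ann, dag, None, config.namespaces)
    theta = (config.theta if config.theta is not None
             else similarity_network.percentile_threshold(sim, config.theta_percentile))
    net = similarity_network.build_network(sim, theta, pcm.names, config.weighted_network)
    meta["counts"]["network_edges"] = net.n_edges
    meta["parameters"]["theta_effective"] = theta
    pd.DataFrame(sim, index=pcm.names, columns=pcm.names).to_csv(
        out / "similarity.tsv", sep="\t", index_label="pathway")
    _write_edges(net, out / "network_edges.tsv")
    if stop_after == "similarity":
        return _finish(meta, out)

    # --- ranking -------------------------------------------------------------
    universe = config.genome_size or expr.n_genes
    nd = len(degs.genes)
    enrich = []
    for name in pcm.names:
        members = pathways[name]
        x = sum(1 for g in members if g in degs.genes)
        enrich.append(ranking.EnrichmentInput(universe, nd, len(members), x))
    result = _stage("rank", ranking.rank_pathways, profile.mi, net, enrich,
                    config.d, config.epsilon, config.max_iter,
                    [len(pcm[n]) for n in pcm.names])
    if config.bh_on_enrichment:
        result.pvalues = multipletests(result.pvalues, method="fdr_bh")[1]
    io_formats.write_rank_table(result, out / "rank_table.tsv")
    meta["counts"]["generank_iterations"] = result.iterations_used
    meta["counts"]["generank_converged"] = bool(result.converged)
    if stop_after == "rank" or not config.run_evaluation:
        return _finish(meta, out)

    # --- evaluation -----------------------------------------------------------
    features = _stage("select_features", evaluation.select_feature_genes,
                      result, pcm, degs, config.k_features)
    cv = evaluation.cv_auc(expr, pheno, features, config.folds, config.repeats, config.seed)
    baseline_features = evaluation.ttest_baseline(expr, pheno, config.k_features)
    cv_baseline = evaluation.cv_auc(expr, pheno, baseline_features,
                                    config.folds, config.repeats, config.seed)
    report = {
        "feature_genes": features.genes,
        "feature_provenance": [[p, r] for p, r in features.provenance],
        "mean_auc": cv.mean_auc,
        "fold_aucs": cv.fold_aucs.tolist(),
        "baseline_genes": baseline_features.genes,
        "baseline_mean_auc": cv_baseline.mean_auc,
        "baseline_fold_aucs": cv_baseline.fold_aucs.tolist(),
        "folds": config.folds,
        "repeats": config.repeats,
        "seed": config.seed,
    }
    (out / "evaluation.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    meta["counts"]["feature_genes"] = len(features)
    meta["evaluation"] = {"mean_auc": cv.mean_auc, "baseline_mean_auc": cv_baseline.mean_auc}
    return _finish(meta, out)


# ---------------------------------------------------------------------------


def _stage(name, fn, *args):
    try:
        return fn(*args)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def _write_edges(net, path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_a\tpathway_b\tweight\n")
        n = net.n
        for i in range(n):
            for j in range(i + 1, n):
                if net.w[i, j] > 0:
                    fh.write(f"{net.pathway_names[i]}\t{net.pathway_names[j]}\t{net.w[i, j]:.10g}\n")


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["namespaces"] = list(config.namespaces)
    return d


def _safe_version() -> str:
    try:
        return pkg_version("pathnet")
    except Exception:
        return "unknown"


def _finish(meta: dict, out: Path) -> dict:
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return meta
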