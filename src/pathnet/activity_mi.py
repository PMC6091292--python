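"""Pathway activity scores and phenotype mutual information.

A pathway's activity in a sample is the arithmetic mean expression of its
candidate genes in that sample.  Each pathway's activity vector over the m
samples is discretized into B = floor(log2(m) + 1) equal-width bins
(Sturges-style) and scored against the binary phenotype by plug-in mutual
information in bits; the MI vector seeds the downstream random walk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidate_genes import PathwayCandidateMap
from .io_formats import ExpressionMatrix, PhenotypeVector


@dataclass
class ActivityProfile:
    """Pathway x sample activity with discretization and per-pathway MI."""

    pathway_names: list[str]
    activity: np.ndarray  # (n_pathways, m) real
    n_bins: int
    discretized: np.ndarray  # (n_pathways, m) int bin indices
    mi: np.ndarray  # per-pathway MI against phenotype, bits

    @property
    def n_samples(self) -> int:
        return self.activity.shape[1]


def sturges_bins(m: int) -> int:
    """B = floor(log2(m) + 1) for m samples."""
    if m < 2:
        raise ValueError("need at least 2 samples")
    return int(np.floor(np.log2(m) + 1))


def activity_scores(pcm: PathwayCandidateMap, expr: ExpressionMatrix) -> np.ndarray:
    """Mean expression of each pathway's candidate genes per sample.

    Returns a (n_pathways, n_samples) matrix in ``pcm`` pathway order.
    Every pathway must carry at least one candidate (pre-filtered upstream).
    """
    rows = []
    for name in pcm.names:
        genes = pcm[name]
        if not genes:
            raise ValueError(f"pathway {name!r} has no candidate genes")
        rows.append(expr.subset_genes(genes).mean(axis=0))
    return np.vstack(rows)


def discretize(a_row: np.ndarray, m: int | None = None) -> np.ndarray:
    """Equal-width binning of an activity vector into Sturges bins.

    Bins span [min, max] of the vector; the maximum lands in the top bin
    (right-closed last bin).  A constant vector collapses to bin 0.
    """
    a_row = np.asarray(a_row, dtype=float)
    if m is None:
        m = a_row.size
    b = sturges_bins(m)
    lo, hi = a_row.min(), a_row.max()
    if hi == lo:
        return np.zeros(a_row.size, dtype=int)
    idx = np.floor((a_row - lo) / (hi - lo) * b).astype(int)
    return np.clip(idx, 0, b - 1)


def mutual_information(a_disc: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in mutual information (bits) between a discrete vector and labels.

    Empirical frequencies, no pseudo-counts; 0 * log(0) terms contribute 0.
    """
    a_disc = np.asarray(a_disc)
    labels = np.asarray(labels)
    if a_disc.shape != labels.shape:
        raise ValueError("vector lengths differ")
    m = a_disc.size
    xs, xi = np.unique(a_disc, return_inverse=True)
    ys, yi = np.unique(labels, return_inverse=True)
    joint = np.zeros((xs.size, ys.size))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= m
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)  # clip -0.0 / rounding at exact independence


def phenotype_scores(
    pathway_names: list[str],
    activity: np.ndarray,
    pheno: PhenotypeVector,
    sample_ids: list[str] | None = None,
) -> ActivityProfile:
    """Discretize each pathway's activity row and score it against phenotype.

    ``sample_ids``, when given, must match the phenotype's sample order
    (hard error otherwise) — activity columns carry no ids of their own.
    """
    if sample_ids is not None and list(sample_ids) != list(pheno.sample_ids):
        raise ValueError("sample ids misaligned between activity matrix and phenotype")
    m = activity.shape[1]
    if m != len(pheno.sample_ids):
        raise ValueError("sample count mismatch")
    disc = np.vstack([discretize(row, m) for row in activity])
    mi = np.array([mutual_information(row, pheno.labels) for row in disc])
    return ActivityProfile(list(pathway_names), activity, sturges_bins(m), disc, mi)


def profile_from_candidates(
    pcm: PathwayCandidateMap, expr: ExpressionMatrix, pheno: PhenotypeVector
) -> ActivityProfile:
    """Convenience: activity_scores + phenotype_scores in pathway-map order."""
    act = activity_scores(pcm, expr)
    return phenotype_scores(pcm.names, act, pheno.aligned_to(expr), expr.sample_ids)
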