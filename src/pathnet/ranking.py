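"""Pathway prioritization: GeneRank random walk + hypergeometric significance.

The walk blends a prior (L1-normalized pathway-phenotype mutual
information) with network diffusion over the thresholded similarity
network:

    r_j <- (1 - d) * ex_j + d * sum_i w_ij r_i / deg_i

with damping d (default 0.85), starting from r = ex, stopping when the L1
change between iterations falls below epsilon.  Isolated pathways
(deg = 0) contribute nothing outward but keep receiving their prior term.

Each pathway additionally gets an enrichment p-value: the hypergeometric
upper-tail probability of observing at least x differential genes in a
pathway of M genes given Nd differential genes in a universe of U.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .similarity_network import PathwaySimilarityNetwork


@dataclass
class EnrichmentInput:
    """Counts for the hypergeometric test of one pathway."""

    universe: int  # U: genes in the universe
    n_differential: int  # Nd: differential genes in the universe
    pathway_size: int  # M: genes in the pathway
    n_hits: int  # x: differential genes in the pathway

    def __post_init__(self) -> None:
        u, nd, m, x = self.universe, self.n_differential, self.pathway_size, self.n_hits
        if not (0 <= x <= min(m, nd) and m <= u and nd <= u):
            raise ValueError(
                f"inconsistent enrichment counts U={u}, Nd={nd}, M={m}, x={x}"
            )


@dataclass
class RankResult:
    """GeneRank output with seeds, convergence trace, p-values and ordering."""

    pathway_names: list[str]
    ex_raw: np.ndarray  # raw MI seeds
    ex: np.ndarray  # L1-normalized seeds
    r: np.ndarray  # rank scores (not renormalized)
    d: float
    epsilon: float
    iterations_used: int
    converged: bool
    residual_history: list[float]
    pvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    n_candidates: list[int] = field(default_factory=list)
    pathway_sizes: list[int] = field(default_factory=list)
    n_deg_in_pathway: list[int] = field(default_factory=list)

    @property
    def ordering(self) -> list[str]:
        """Pathways by descending r; ties by descending MI then name."""
        order = sorted(
            range(len(self.pathway_names)),
            key=lambda i: (-self.r[i], -self.ex_raw[i], self.pathway_names[i]),
        )
        return [self.pathway_names[i] for i in order]

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.pathway_names)}


def generank(
    ex_raw: np.ndarray,
    w: np.ndarray,
    deg: np.ndarray,
    d: float = 0.85,
    epsilon: float = 1e-10,
    max_iter: int = 1000,
    pathway_names: list[str] | None = None,
) -> RankResult:
    """Iterate the damped walk from the normalized seed to its fixed point.

    ``w`` must be symmetric with a zero diagonal (binary or weighted);
    ``ex_raw`` non-negative with at least one positive entry.  The result r
    is the raw fixed point — it is NOT renormalized after convergence.
    """
    ex_raw = np.asarray(ex_raw, dtype=float)
    w = np.asarray(w, dtype=float)
    deg = np.asarray(deg, dtype=float)
    if not 0.0 <= d <= 1.0:
        raise ValueError("damping d must lie in [0, 1]")
    if np.any(ex_raw < 0) or ex_raw.sum() == 0:
        raise ValueError("seed vector must be non-negative with a positive total")
    if w.shape != (ex_raw.size, ex_raw.size) or not np.allclose(w, w.T):
        raise ValueError("adjacency must be square and symmetric")
    if np.any(np.diag(w) != 0):
        raise ValueError("adjacency diagonal must be zero")

    ex = ex_raw / np.abs(ex_raw).sum()
    inv_deg = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)

    r = ex.copy()
    residuals: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        r_new = (1.0 - d) * ex + d * (w.T @ (r * inv_deg))
        res = float(np.abs(r_new - r).sum())
        residuals.append(res)
        r = r_new
        if res <= epsilon:
            converged = True
            break

    names = pathway_names if pathway_names is not None else [str(i) for i in range(ex.size)]
    return RankResult(
        list(names), ex_raw, ex, r, float(d), float(epsilon), n_iter, converged, residuals
    )


def hypergeometric_pvalue(inp: EnrichmentInput) -> float:
    """Upper-tail P[X >= x] for X ~ Hypergeom(U, M, Nd); x = 0 gives 1.

    Computed via the scipy survival function (log-space internally), so it
    stays accurate deep in the tail.
    """
    if inp.n_hits == 0:
        return 1.0
    p = float(
        stats.hypergeom.sf(
            inp.n_hits - 1, inp.universe, inp.pathway_size, inp.n_differential
        )
    )
    # survival probabilities are in (0, 1]; guard rounding at the floor
    return min(max(p, np.finfo(float).tiny), 1.0)


def rank_pathways(
    mi: np.ndarray,
    net: PathwaySimilarityNetwork,
    enrichment: list[EnrichmentInput],
    d: float = 0.85,
    epsilon: float = 1e-10,
    max_iter: int = 1000,
    n_candidates: list[int] | None = None,
) -> RankResult:
    """Run GeneRank on the pathway network and attach per-pathway p-values."""
    if len(mi) != net.n or len(enrichment) != net.n:
        raise ValueError("pathway indexing misaligned across inputs")
    result = generank(mi, net.w, net.deg, d, epsilon, max_iter, net.pathway_names)
    result.pvalues = np.array([hypergeometric_pvalue(e) for e in enrichment])
    result.pathway_sizes = [e.pathway_size for e in enrichment]
    result.n_deg_in_pathway = [e.n_hits for e in enrichment]
    result.n_candidates = list(n_candidates) if n_candidates is not None else [0] * net.n
    return result
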