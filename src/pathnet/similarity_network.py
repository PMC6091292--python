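"""GO semantic similarity and the pathway-pathway similarity network.

Gene-gene similarity uses Wang's graph-based measure: each GO term is
described by the S-values of its ancestor closure (S = 1 at the term,
decaying through is_a / part_of edges by fixed contribution factors), and
two terms are compared by the S-value mass of their shared ancestors
relative to their total semantic value.  Term similarities are combined to
gene level by best-match averaging (BMA) per namespace, then averaged over
the namespaces in which both genes are annotated.

Pathway similarity is the sum of all cross-pathway gene-pair similarities
divided by M + N (the two candidate-gene counts) — note this is NOT
normalized to [0, 1]: identical singleton pathways score 0.5, and the upper
bound is M*N/(M+N).  Thresholding the similarity matrix at theta yields the
binary pathway network whose degrees drive the random walk.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .candidate_genes import PathwayCandidateMap
from .io_formats import NAMESPACES, AnnotationMap, OntologyDAG


@dataclass
class TermSimilarityParams:
    """Contribution factors for Wang S-value decay along ontology edges."""

    is_a_weight: float = 0.8
    part_of_weight: float = 0.6

    def __post_init__(self) -> None:
        for w in (self.is_a_weight, self.part_of_weight):
            if not 0.0 < w < 1.0:
                raise ValueError("contribution factors must lie in (0, 1)")

    def weight(self, relation: str) -> float:
        return self.is_a_weight if relation == "is_a" else self.part_of_weight


@dataclass
class PathwaySimilarityNetwork:
    """Thresholded pathway-pathway similarity network."""

    pathway_names: list[str]
    sim: np.ndarray  # symmetric (n, n)
    theta: float
    w: np.ndarray  # binary adjacency, zero diagonal
    deg: np.ndarray  # row sums of w
    weighted: bool = False

    @property
    def n(self) -> int:
        return len(self.pathway_names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.w, 1)))


class WangSimilarity:
    """Wang term-level semantic similarity over one OntologyDAG, with caching."""

    def __init__(self, dag: OntologyDAG, params: TermSimilarityParams | None = None):
        self.dag = dag
        self.params = params or TermSimilarityParams()
        self._svalues: dict[str, dict[str, float]] = {}
        self._sv: dict[str, float] = {}
        self._term_cache: dict[tuple[str, str], float] = {}

    def _semantic_values(self, term: str) -> dict[str, float]:
        """S-values of ``term`` over its ancestor closure (term included).

        S(term) = 1; walking child -> parent, each ancestor's S-value is the
        maximum over its contributing children of child-S x edge weight.
        """
        cached = self._svalues.get(term)
        if cached is not None:
            return cached
        closure = {term} | nx.descendants(self.dag.graph, term)  # ancestors (child->parent edges)
        sub = self.dag.graph.subgraph(closure)
        s = {term: 1.0}
        for node in nx.topological_sort(sub):  # children before parents
            if node not in s:
                continue
            for parent, rel in self.dag.parents(node):
                if parent not in closure:
                    continue
                cand = s[node] * self.params.weight(rel)
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
        self._svalues[term] = s
        self._sv[term] = sum(s.values())
        return s

    def term_similarity(self, t1: str, t2: str) -> float:
        """Wang similarity of two terms of the same namespace, in [0, 1]."""
        ns1, ns2 = self.dag.namespace.get(t1), self.dag.namespace.get(t2)
        if ns1 != ns2:
            raise ValueError(f"terms {t1!r} and {t2!r} are in different namespaces")
        if t1 == t2:
            return 1.0
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        hit = self._term_cache.get(key)
        if hit is not None:
            return hit
        s1, s2 = self._semantic_values(t1), self._semantic_values(t2)
        common = s1.keys() & s2.keys()
        if not common:
            sim = 0.0
        else:
            sim = sum(s1[t] + s2[t] for t in common) / (self._sv[t1] + self._sv[t2])
        self._term_cache[key] = sim
        return sim


def wang_term_similarity(
    t1: str, t2: str, dag: OntologyDAG, params: TermSimilarityParams | None = None
) -> float:
    """Functional wrapper around :class:`WangSimilarity` for single pairs."""
    return WangSimilarity(dag, params).term_similarity(t1, t2)


class GeneSimilarity:
    """BMA gene-gene similarity over shared annotation namespaces, cached."""

    def __init__(
        self,
        ann: AnnotationMap,
        dag: OntologyDAG,
        params: TermSimilarityParams | None = None,
        namespaces: tuple[str, ...] = NAMESPACES,
    ):
        self.ann = ann
        self.wang = WangSimilarity(dag, params)
        self.namespaces = namespaces
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, g1: str, g2: str) -> float:
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        per_ns = []
        for ns in self.namespaces:
            terms1 = sorted(self.ann.terms_for(g1, ns))
            terms2 = sorted(self.ann.terms_for(g2, ns))
            if terms1 and terms2:
                per_ns.append(self._bma(terms1, terms2))
        sim = float(np.mean(per_ns)) if per_ns else 0.0
        self._cache[key] = sim
        return sim

    def _bma(self, terms1: list[str], terms2: list[str]) -> float:
        mat = np.array(
            [[self.wang.term_similarity(a, b) for b in terms2] for a in terms1]
        )
        return 0.5 * (mat.max(axis=1).mean() + mat.max(axis=0).mean())


def gene_similarity(
    g1: str,
    g2: str,
    ann: AnnotationMap,
    dag: OntologyDAG,
    params: TermSimilarityParams | None = None,
) -> float:
    """Functional wrapper around :class:`GeneSimilarity` for single pairs."""
    return GeneSimilarity(ann, dag, params)(g1, g2)


def pathway_similarity(
    genes_i: list[str],
    genes_j: list[str],
    gene_sim,
    sim_floor: float = 0.0,
) -> float:
    """Sum of all cross-pathway gene-pair similarities over M + N.

    ``gene_sim`` is any callable (g1, g2) -> similarity.  Pairs below
    ``sim_floor`` contribute 0 (default floor 0 counts every pair).
    """
    m, n = len(genes_i), len(genes_j)
    if m == 0 or n == 0:
        raise ValueError("pathway similarity needs non-empty gene sets")
    total = 0.0
    for gx in genes_i:
        for gy in genes_j:
            s = gene_sim(gx, gy)
            if s >= sim_floor:
                total += s
    return total / (m + n)


def similarity_matrix(
    pcm: PathwayCandidateMap,
    ann: AnnotationMap,
    dag: OntologyDAG,
    params: TermSimilarityParams | None = None,
    namespaces: tuple[str, ...] = NAMESPACES,
    sim_floor: float = 0.0,
) -> tuple[np.ndarray, GeneSimilarity]:
    """All-pairs pathway similarity over candidate genes, with a shared cache.

    The diagonal carries each pathway's self-similarity (Eq-style value
    M*M-pair sum over 2M; unused by the binary network, which zeroes it).
    """
    names = pcm.names
    if len(names) < 2:
        raise ValueError("need at least 2 retained pathways")
    gsim = GeneSimilarity(ann, dag, params, namespaces)
    n = len(names)
    sim = np.zeros((n, n))
    for i in range(n):
        sim[i, i] = pathway_similarity(pcm[names[i]], pcm[names[i]], gsim, sim_floor)
    for i, j in combinations(range(n), 2):
        s = pathway_similarity(pcm[names[i]], pcm[names[j]], gsim, sim_floor)
        sim[i, j] = sim[j, i] = s
    return sim, gsim


def percentile_threshold(sim: np.ndarray, percentile: float = 75.0) -> float:
    """Theta as a percentile of the off-diagonal similarity distribution."""
    n = sim.shape[0]
    off = sim[~np.eye(n, dtype=bool)]
    return float(np.percentile(off, percentile))


def build_network(
    sim: np.ndarray,
    theta: float,
    pathway_names: list[str] | None = None,
    weighted: bool = False,
) -> PathwaySimilarityNetwork:
    """Threshold the similarity matrix into the pathway network.

    An edge exists when sim >= theta (ties at theta included); the diagonal
    is zeroed; isolated nodes stay in the network (the random walk keeps
    feeding them through their seed term).  In weighted mode w carries the
    similarity value instead of 1 on retained edges.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    mask = (sim >= theta) & ~np.eye(n, dtype=bool)
    w = np.where(mask, sim if weighted else 1.0, 0.0)
    deg = w.sum(axis=1)
    names = pathway_names if pathway_names is not None else [str(i) for i in range(n)]
    return PathwaySimilarityNetwork(list(names), sim, float(theta), w, deg, weighted)
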