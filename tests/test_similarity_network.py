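import networkx as nx
import numpy as np
import pytest

from pathnet.candidate_genes import PathwayCandidateMap
from pathnet.io_formats import AnnotationMap, OntologyDAG
from pathnet.similarity_network import (
    GeneSimilarity,
    TermSimilarityParams,
    WangSimilarity,
    build_network,
    gene_similarity,
    pathway_similarity,
    percentile_threshold,
    similarity_matrix,
    wang_term_similarity,
)
from pathnet.synthetic import SyntheticSpec, generate


class TestWangTermSimilarity:
    def test_self_similarity_is_one(self, sibling_dag):
        assert wang_term_similarity("A", "A", sibling_dag) == 1.0
        assert wang_term_similarity("R", "R", sibling_dag) == 1.0

    def test_two_siblings_give_four_ninths(self, sibling_dag):
        # S-values: S_A(A)=1, S_A(R)=0.8, SV=1.8 for both; common ancestor R
        # contributes (0.8+0.8)/(1.8+1.8) = 4/9
        assert wang_term_similarity("A", "B", sibling_dag) == pytest.approx(4 / 9, abs=1e-12)

    def test_disjoint_ancestries_score_zero(self):
        g = nx.DiGraph()
        g.add_edge("A1", "RA", relation="is_a")
        g.add_edge("B1", "RB", relation="is_a")
        dag = OntologyDAG(g, {t: "BP" for t in ["A1", "RA", "B1", "RB"]})
        assert wang_term_similarity("A1", "B1", dag) == 0.0

    def test_cross_namespace_rejected(self, sibling_dag):
        sibling_dag.namespace["B"] = "MF"
        with pytest.raises(ValueError):
            wang_term_similarity("A", "B", sibling_dag)

    def test_part_of_contribution_factor(self, sibling_dag):
        # halving edge weights lowers sibling similarity
        lo = wang_term_similarity("A", "B", sibling_dag, TermSimilarityParams(0.4, 0.3))
        assert lo == pytest.approx((0.4 + 0.4) / (1.4 + 1.4), abs=1e-12)

    def test_symmetry_and_range_on_random_dag(self):
        dag, _ = _random_dag(seed=3)
        wang = WangSimilarity(dag)
        terms = [t for t in dag.terms() if dag.namespace[t] == "BP"]
        rng = np.random.default_rng(0)
        for _ in range(200):
            t1, t2 = rng.choice(terms, 2)
            s = wang.term_similarity(t1, t2)
            assert 0.0 <= s <= 1.0
            assert s == wang.term_similarity(t2, t1)
            if t1 == t2:
                assert s == 1.0


def _random_dag(seed=0):
    bundle = generate(
        SyntheticSpec(n_genes=60, n_normal=4, n_tumor=4, n_pathways=8,
                      pathway_size_range=(4, 7), n_planted=1, seed=seed)
    )
    return bundle.ontology, bundle


class TestGeneSimilarity:
    def test_identical_annotations_score_one(self, sibling_dag):
        ann = AnnotationMap({"BP": {"g1": {"A", "B"}, "g2": {"A", "B"}}, "MF": {}, "CC": {}})
        assert gene_similarity("g1", "g1", ann, sibling_dag) == 1.0

    def test_disjoint_namespaces_score_zero(self, sibling_dag):
        ann = AnnotationMap({"BP": {"g1": {"A"}}, "MF": {"g2": {"A"}}, "CC": {}})
        assert gene_similarity("g1", "g2", ann, sibling_dag) == 0.0

    def test_bma_worked_example(self, sibling_dag):
        # 2x1 term sets with sims 0.4 / 0.6:
        # BMA = (mean row maxima + mean column maxima)/2 = (0.5 + 0.6)/2 = 0.55
        ann = AnnotationMap({"BP": {"g1": {"a", "b"}, "g2": {"c"}}, "MF": {}, "CC": {}})
        gs = GeneSimilarity(ann, sibling_dag)
        fixed = {("a", "c"): 0.4, ("b", "c"): 0.6}
        gs.wang.term_similarity = lambda t1, t2: fixed[tuple(sorted((t1, t2)))]
        assert gs("g1", "g2") == pytest.approx(0.55, abs=1e-12)

    def test_symmetry(self):
        dag, bundle = _random_dag(seed=5)
        gs = GeneSimilarity(bundle.annotations, dag)
        genes = sorted(bundle.annotations.by_namespace["BP"])[:10]
        for g1 in genes[:5]:
            for g2 in genes[5:]:
                assert gs(g1, g2) == gs(g2, g1)
                assert 0.0 <= gs(g1, g2) <= 1.0


class TestPathwaySimilarity:
    def test_identical_singletons_give_half(self):
        assert pathway_similarity(["g"], ["g"], lambda a, b: 1.0) == 0.5

    def test_all_zero_pairs(self):
        assert pathway_similarity(["a", "b"], ["c"], lambda a, b: 0.0) == 0.0

    def test_worked_two_by_one(self):
        sims = {("g1", "g3"): 0.4, ("g2", "g3"): 0.6}
        f = lambda a, b: sims[(a, b)]
        assert pathway_similarity(["g1", "g2"], ["g3"], f) == pytest.approx(1.0 / 3, abs=1e-12)

    def test_upper_bound_attained_at_all_ones(self):
        for m, n in [(1, 1), (2, 3), (5, 4)]:
            gi, gj = [f"a{i}" for i in range(m)], [f"b{j}" for j in range(n)]
            s = pathway_similarity(gi, gj, lambda a, b: 1.0)
            assert s == pytest.approx(m * n / (m + n), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        table = {}
        def f(a, b):
            key = tuple(sorted((a, b)))
            if key not in table:
                table[key] = float(rng.random())
            return table[key]
        gi, gj = ["a", "b", "c"], ["d", "e"]
        assert pathway_similarity(gi, gj, f) == pytest.approx(pathway_similarity(gj, gi, f), abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            pathway_similarity([], ["a"], lambda a, b: 1.0)


class TestSimilarityMatrix:
    def test_matches_uncached_pairwise_recomputation(self):
        dag, bundle = _random_dag(seed=1)
        names = bundle.pathways.names[:5]
        pcm = PathwayCandidateMap(
            {n: list(bundle.pathways[n]) for n in names},
            {n: len(bundle.pathways[n]) for n in names},
        )
        sim, _ = similarity_matrix(pcm, bundle.annotations, dag)
        assert np.allclose(sim, sim.T)
        for i, ni in enumerate(names):
            for j, nj in enumerate(names):
                if i < j:
                    fresh = GeneSimilarity(bundle.annotations, dag)  # no shared cache
                    expect = pathway_similarity(pcm[ni], pcm[nj], fresh)
                    assert sim[i, j] == pytest.approx(expect, abs=1e-12)

    def test_permutation_equivariance(self):
        dag, bundle = _random_dag(seed=2)
        names = bundle.pathways.names[:4]
        pcm1 = PathwayCandidateMap({n: list(bundle.pathways[n]) for n in names},
                                   {n: len(bundle.pathways[n]) for n in names})
        rev = list(reversed(names))
        pcm2 = PathwayCandidateMap({n: list(bundle.pathways[n]) for n in rev},
                                   {n: len(bundle.pathways[n]) for n in rev})
        s1, _ = similarity_matrix(pcm1, bundle.annotations, dag)
        s2, _ = similarity_matrix(pcm2, bundle.annotations, dag)
        perm = [names.index(n) for n in rev]
        assert np.allclose(s2, s1[np.ix_(perm, perm)])


class TestBuildNetwork:
    def test_threshold_tie_includes_edge(self):
        sim = np.array([[0.0, 0.5], [0.5, 0.0]])
        net = build_network(sim, 0.5)
        assert net.w[0, 1] == 1.0 and net.n_edges == 1

    def test_just_below_threshold_excludes_edge(self):
        sim = np.array([[0.0, 0.4999], [0.4999, 0.0]])
        assert build_network(sim, 0.5).n_edges == 0

    def test_complete_graph_degrees(self):
        sim = np.full((4, 4), 0.9)
        net = build_network(sim, 0.5)
        assert np.array_equal(net.deg, [3, 3, 3, 3])
        assert np.all(np.diag(net.w) == 0)

    def test_edge_count_monotone_in_theta(self):
        rng = np.random.default_rng(6)
        sim = rng.random((10, 10))
        sim = (sim + sim.T) / 2
        counts = [build_network(sim, th).n_edges for th in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_weighted_mode_carries_similarity(self):
        sim = np.array([[0.0, 0.7], [0.7, 0.0]])
        net = build_network(sim, 0.5, weighted=True)
        assert net.w[0, 1] == 0.7

    def test_percentile_threshold_uses_off_diagonal(self):
        sim = np.array([[9.0, 1.0], [1.0, 9.0]])
        assert percentile_threshold(sim, 50.0) == 1.0
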