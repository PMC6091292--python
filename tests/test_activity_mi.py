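import numpy as np
import pytest

from conftest import mi_bruteforce
from pathnet.activity_mi import (
    activity_scores,
    discretize,
    mutual_information,
    phenotype_scores,
    profile_from_candidates,
    sturges_bins,
)
from pathnet.candidate_genes import PathwayCandidateMap
from pathnet.io_formats import ExpressionMatrix, PhenotypeVector


def _expr(values, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(genes, [f"s{j}" for j in range(values.shape[1])], values)


class TestActivityScores:
    def test_mean_of_two(self):
        expr = _expr([[2.0], [4.0]])
        pcm = PathwayCandidateMap({"P": ["g0", "g1"]}, {"P": 2})
        assert activity_scores(pcm, expr)[0, 0] == 3.0

    def test_single_gene_identity(self):
        expr = _expr([[1.0, 7.0], [9.9, 0.1]])
        pcm = PathwayCandidateMap({"P": ["g1"]}, {"P": 1})
        assert np.array_equal(activity_scores(pcm, expr)[0], expr.values[1])

    def test_three_genes_two_samples(self):
        expr = _expr([[1, 2], [3, 4], [5, 6]])
        pcm = PathwayCandidateMap({"P": ["g0", "g1", "g2"]}, {"P": 3})
        assert np.allclose(activity_scores(pcm, expr), [[3.0, 4.0]])

    def test_empty_pathway_rejected(self):
        expr = _expr([[1.0, 2.0]])
        pcm = PathwayCandidateMap({"P": []}, {"P": 0})
        with pytest.raises(ValueError):
            activity_scores(pcm, expr)


class TestDiscretize:
    @pytest.mark.parametrize("m, b", [(8, 4), (100, 7), (2, 2), (63, 6), (64, 7)])
    def test_sturges_bin_count(self, m, b):
        assert sturges_bins(m) == b

    def test_bins_cover_range_max_in_top_bin(self):
        a = np.linspace(0, 1, 8)
        d = discretize(a, 8)
        assert d.min() == 0 and d.max() == 3
        assert d[-1] == 3  # right-closed top bin

    def test_constant_vector_all_zero(self):
        assert np.array_equal(discretize(np.full(10, 3.3), 10), np.zeros(10, int))

    def test_affine_transform_preserves_bins(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=32)
        for alpha, beta in [(2.0, 0.0), (0.5, 3.0), (4.0, -1.0)]:
            assert np.array_equal(discretize(a, 32), discretize(alpha * a + beta, 32))


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        c = np.array([0, 1] * 4)
        assert mutual_information(c, c) == pytest.approx(1.0, abs=1e-12)

    def test_constant_vector_is_independent(self):
        c = np.array([0, 1] * 4)
        assert mutual_information(np.zeros(8, int), c) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m = int(rng.integers(4, 64))
            a = rng.integers(0, 4, m)
            c = rng.integers(0, 2, m)
            assert mutual_information(a, c) == pytest.approx(mi_bruteforce(a, c), abs=1e-12)

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = int(rng.integers(6, 50))
            a = rng.integers(0, 5, m)
            c = rng.integers(0, 2, m)
            mi = mutual_information(a, c)
            h = lambda v: -sum(p * np.log2(p) for p in np.bincount(v) / len(v) if p > 0)
            assert -1e-12 <= mi <= min(h(a), h(c)) + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, 40)
        c = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        assert mutual_information(a, c) == pytest.approx(mutual_information(a[perm], c[perm]), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3, int), np.zeros(4, int))


class TestPhenotypeScores:
    def test_deterministic_pathway_has_maximal_mi(self):
        rng = np.random.default_rng(3)
        labels = np.array([0] * 8 + [1] * 8)
        pheno = PhenotypeVector([f"s{i}" for i in range(16)], labels)
        act = np.vstack([labels * 5.0, rng.normal(size=16), rng.normal(size=16)])
        prof = phenotype_scores(["det", "n1", "n2"], act, pheno)
        assert prof.mi[0] == max(prof.mi)

    def test_identical_rows_identical_mi(self):
        labels = np.array([0] * 5 + [1] * 5)
        pheno = PhenotypeVector([f"s{i}" for i in range(10)], labels)
        row = np.arange(10.0)
        prof = phenotype_scores(["a", "b"], np.vstack([row, row]), pheno)
        assert prof.mi[0] == prof.mi[1]

    def test_misaligned_sample_ids_rejected(self):
        pheno = PhenotypeVector(["s0", "s1"], np.array([0, 1]))
        with pytest.raises(ValueError):
            phenotype_scores(["p"], np.zeros((1, 2)), pheno, sample_ids=["s1", "s0"])

    def test_affine_activity_transform_leaves_mi_unchanged(self):
        rng = np.random.default_rng(4)
        labels = np.array([0] * 10 + [1] * 10)
        pheno = PhenotypeVector([f"s{i}" for i in range(20)], labels)
        act = rng.normal(size=(3, 20))
        base = phenotype_scores(["a", "b", "c"], act, pheno)
        scaled = phenotype_scores(["a", "b", "c"], 2.5 * act + 1.0, pheno)
        assert np.array_equal(base.discretized, scaled.discretized)
        assert np.allclose(base.mi, scaled.mi, atol=1e-12)

    def test_planted_pathways_score_above_background(self, default_bundle):
        # full-member activity (no DEG filter): planted mean MI > background mean
        b = default_bundle
        names = b.pathways.names
        pcm = PathwayCandidateMap(
            {n: [g for g in b.pathways[n] if g in b.expression] for n in names},
            {n: len(b.pathways[n]) for n in names},
        )
        prof = profile_from_candidates(pcm, b.expression, b.phenotype)
        planted = [prof.mi[i] for i, n in enumerate(names) if n in b.truth_pathways]
        background = [prof.mi[i] for i, n in enumerate(names) if n not in b.truth_pathways]
        assert np.mean(planted) > np.mean(background)
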