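from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oriscan import align


def brute_force_score(a, b, d):
    """Exhaustive minimum over all monotone partial matchings.

    Enumerates every pairing of k sorted indices of A with k sorted indices
    of B (order-preserving because both selections are taken in order) and
    charges d per unpaired element; independent of the DP.
    """
    a, b = list(a), list(b)
    best = (len(a) + len(b)) * d
    for k in range(1, min(len(a), len(b)) + 1):
        for ia in combinations(range(len(a)), k):
            for ib in combinations(range(len(b)), k):
                cost = sum(abs(a[i] - b[j]) for i, j in zip(ia, ib))
                cost += d * (len(a) + len(b) - 2 * k)
                best = min(best, cost)
    return best


sorted_vec = st.lists(st.integers(0, 10_000), min_size=0, max_size=6,
                      unique=True).map(sorted).map(np.array)


class TestNva:
    def test_worked_example_pair_and_gap(self):
        aln = align.nva(np.array([100.0, 500.0]), np.array([120.0]), 1e6)
        assert aln.pairs == [(0, 0)]
        assert aln.gaps_a == [1]
        assert aln.score == pytest.approx(1_000_020.0)
        np.testing.assert_allclose(aln.consensus, [110.0, 500.0])

    def test_identical_vectors_score_zero(self):
        v = np.array([10.0, 20.0, 800.0])
        aln = align.nva(v, v, 1e6)
        assert aln.score == 0.0
        assert aln.gaps_a == aln.gaps_b == []
        np.testing.assert_allclose(aln.consensus, v)

    def test_small_gap_penalty_prefers_gaps(self):
        aln = align.nva(np.array([0.0, 10.0]), np.array([1000.0]), 5)
        assert aln.pairs == []
        assert aln.score == pytest.approx(15.0)

    def test_empty_vector_all_gaps(self):
        aln = align.nva(np.empty(0), np.array([5.0, 10.0]), 100)
        assert aln.score == 200.0
        np.testing.assert_allclose(aln.consensus, [5.0, 10.0])

    def test_chromosome_mismatch_rejected(self):
        a = align.PositionVector("chr1", [1.0])
        b = align.PositionVector("chr2", [1.0])
        with pytest.raises(ValueError):
            align.nva(a, b)

    @given(a=sorted_vec, b=sorted_vec, d=st.sampled_from([5, 100, 10**6]))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_dp_matches_exhaustive_oracle(self, a, b, d):
        assert align.nva(a, b, d).score == pytest.approx(
            brute_force_score(a, b, d))

    @given(a=sorted_vec, b=sorted_vec)
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_score_symmetry_and_nonnegativity(self, a, b):
        s_ab = align.nva(a, b, 1000).score
        s_ba = align.nva(b, a, 1000).score
        assert s_ab == pytest.approx(s_ba)
        assert s_ab >= 0.0

    @given(a=sorted_vec, b=sorted_vec)
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_gap_count_monotone_in_penalty(self, a, b):
        counts = []
        for d in (10, 1000, 100_000):
            aln = align.nva(a, b, d)
            counts.append(len(aln.gaps_a) + len(aln.gaps_b))
        assert counts[0] >= counts[1] >= counts[2]

    def test_consensus_sorted(self, rng):
        for _ in range(20):
            a = np.sort(rng.choice(5000, size=5, replace=False)).astype(float)
            b = np.sort(rng.choice(5000, size=4, replace=False)).astype(float)
            cons = align.nva(a, b, 500).consensus
            assert np.all(np.diff(cons) >= 0)


class TestNvaGenome:
    def test_identical_sets_total_zero(self):
        s = {"chr1": np.array([1.0, 2.0]), "chr2": np.array([5.0])}
        assert align.nva_genome(s, s).total_score == 0.0

    def test_empty_set_all_gaps(self):
        s = {"chr1": np.array([1.0, 2.0, 3.0])}
        res = align.nva_genome(s, {}, d=1e6)
        assert res.total_score == pytest.approx(3e6)

    def test_chromosome_in_one_set_only(self):
        a = {"chr1": np.array([100.0]), "chr2": np.array([50.0])}
        b = {"chr1": np.array([100.0])}
        res = align.nva_genome(a, b, d=1e6)
        assert res.total_score == pytest.approx(1e6)

    def test_total_is_sum_of_per_chromosome_oracles(self, rng):
        a = {"chr1": np.sort(rng.choice(999, 3, replace=False)).astype(float),
             "chr2": np.sort(rng.choice(999, 4, replace=False)).astype(float)}
        b = {"chr1": np.sort(rng.choice(999, 4, replace=False)).astype(float),
             "chr2": np.sort(rng.choice(999, 2, replace=False)).astype(float)}
        d = 300
        expect = sum(brute_force_score(a[c], b[c], d) for c in ("chr1", "chr2"))
        assert align.nva_genome(a, b, d).total_score == pytest.approx(expect)


class TestMnva:
    def test_identical_sets_gap_free(self):
        s = {"chr1": np.array([100.0, 500.0, 900.0])}
        m = align.mnva([s, s, s], 1e6)
        assert m.n_columns == 3
        assert np.all(m.column_fraction == 1.0)
        np.testing.assert_allclose(m.column_consensus, [100, 500, 900])

    def test_three_singletons_large_penalty_pairs_everything(self):
        # with d = 1e6 pairing 900 to the running consensus costs ~800,
        # far below two gap penalties, so minimization yields one column
        sets = [{"chr1": np.array([100.0])}, {"chr1": np.array([105.0])},
                {"chr1": np.array([900.0])}]
        m = align.mnva(sets, 1e6)
        assert m.n_columns == 1
        assert m.column_fraction[0] == 1.0

    def test_three_singletons_small_penalty_splits(self):
        # 2d = 600 < 797.5: gapping 900 is now cheaper than pairing it
        sets = [{"chr1": np.array([100.0])}, {"chr1": np.array([105.0])},
                {"chr1": np.array([900.0])}]
        m = align.mnva(sets, d=300)
        assert m.n_columns == 2
        fr = sorted(m.column_fraction)
        assert fr == pytest.approx([1 / 3, 2 / 3])
        near = m.column_consensus[np.argmax(m.column_fraction)]
        assert near == pytest.approx(102.5)

    def test_row_recovery_random_instances(self, rng):
        for trial in range(50):
            n_sets = int(rng.integers(3, 7))
            sets = []
            for _ in range(n_sets):
                k = int(rng.integers(0, 6))
                pos = np.sort(rng.choice(100_000, size=k, replace=False))
                sets.append({"chr1": pos.astype(float)})
            m = align.mnva(sets, d=5000)
            for r, s in enumerate(sets):
                row = m.matrix[r]
                np.testing.assert_allclose(row[~np.isnan(row)], s["chr1"])

    def test_column_count_bounded_by_total_elements(self, rng):
        sets = [{"chr1": np.sort(rng.choice(9999, 5, replace=False)).astype(float)}
                for _ in range(4)]
        m = align.mnva(sets, d=1000)
        assert 0 < m.n_columns <= 20

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            align.mnva([{"chr1": np.array([1.0])}])

    def test_multi_chromosome_concatenation(self):
        a = {"chr1": np.array([10.0]), "chr2": np.array([20.0])}
        b = {"chr1": np.array([12.0])}
        m = align.mnva([a, b], d=100)
        assert m.chroms == ["chr1", "chr2"]
        assert m.n_columns == 2


class TestSelectByAgreement:
    def _matrix(self):
        mat = np.array([[1.0, 2.0, np.nan],
                        [1.0, np.nan, np.nan],
                        [1.0, 2.2, 3.0]])
        return align.MnvaMatrix(["a", "b", "c"], ["chr1"] * 3, mat)

    def test_inclusive_threshold(self):
        out = align.select_by_agreement(self._matrix(), 0.5)
        assert len(out) == 2

    def test_strict_threshold(self):
        m = self._matrix()
        assert len(align.select_by_agreement(m, 0.9, strict=True)) == 1
        assert len(align.select_by_agreement(m, 1.0)) == 1

    def test_empty_matrix(self):
        m = align.MnvaMatrix(["a", "b"], [], np.empty((2, 0)))
        assert align.select_by_agreement(m, 0.5) == []


class TestPairwiseSimilarity:
    def test_identical_sets_zero(self):
        s = {"chr1": np.array([1.0, 500.0])}
        m = align.pairwise_similarity([s, s], d=1e6)
        assert np.all(m.to_numpy() == 0.0)

    def test_all_gap_case_equals_penalty(self):
        a = {"chr1": np.array([0.0])}
        b = {"chr2": np.array([10.0])}
        m = align.pairwise_similarity([a, b], d=1e6)
        assert m.iloc[0, 1] == pytest.approx(1e6)

    def test_symmetric(self, rng):
        sets = [{"chr1": np.sort(rng.choice(9999, 4, replace=False)).astype(float)}
                for _ in range(3)]
        m = align.pairwise_similarity(sets, d=1000).to_numpy()
        np.testing.assert_allclose(m, m.T)
        assert np.all(np.diag(m) == 0.0)
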