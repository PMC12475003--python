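"""ANOSIM statistic, permutation enumeration, p-values and the R cutoff."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

import fracshift as fs
from fracshift.anosim import (
    NullDistribution,
    n_distinct_assignments,
    permuted_r_values,
)
from conftest import distance_matrix_from, separated_3v3_matrix


class TestRankDissimilarities:
    @pytest.mark.parametrize(
        "values, expected",
        [
            # midranks for ties: distances [1,2,2,3,...] -> ranks [1,2.5,2.5,4,...]
            ([1, 2, 2, 3, 5, 6], [1, 2.5, 2.5, 4, 5, 6]),
            ([5, 5, 5, 5, 5, 5], [3.5] * 6),  # all equal -> (m+1)/2
            ([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], [1, 2, 3, 4, 5, 6]),
        ],
    )
    def test_midranking(self, values, expected):
        # embed the 6 condensed values in a 2v2 (n=4) distance matrix
        mat = distance_matrix_from(values, [True, True, False, False])
        np.testing.assert_allclose(fs.rank_dissimilarities(mat), expected)


class TestAnosimR:
    def test_perfect_separation_is_one(self):
        assert fs.anosim_r(separated_3v3_matrix()) == pytest.approx(1.0)

    def test_all_equal_distances_zero(self):
        mat = distance_matrix_from([0.3] * 15, [True] * 3 + [False] * 3)
        assert fs.anosim_r(mat) == pytest.approx(0.0)

    def test_hand_rank_arithmetic(self):
        """Within ranks {1,2,3,7,8,9}, between ranks {4,5,6,10..15} -> R = 5/7.5."""
        labels = np.array([True, True, True, False, False, False])
        i, j = np.tril_indices(6, k=-1)
        between = labels[i] != labels[j]
        cond = np.empty(15)
        cond[~between] = np.array([1, 2, 3, 7, 8, 9]) / 100.0
        cond[between] = np.array([4, 5, 6, 10, 11, 12, 13, 14, 15]) / 100.0
        mat = distance_matrix_from(cond, labels)
        assert fs.anosim_r(mat) == pytest.approx((10 - 5) / 7.5)

    def test_matches_skbio_oracle(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        for _ in range(25):
            n_t, n_c = rng.integers(2, 5, size=2)
            n = int(n_t + n_c)
            labels = np.array([True] * n_t + [False] * (n - n_t))
            vals = rng.uniform(0, 1, n * (n - 1) // 2)
            mat = distance_matrix_from(vals, labels)
            expected = skbio_anosim(
                SkbioDM(mat.matrix),
                ["a" if x else "b" for x in labels],
                permutations=0,
            )["test statistic"]
            assert fs.anosim_r(mat) == pytest.approx(float(expected), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        for _ in range(20):
            labels = np.array([True] * 3 + [False] * 3)
            vals = rng.uniform(0, 1, 15)
            m1 = distance_matrix_from(vals, labels)
            m2 = distance_matrix_from(np.exp(3 * vals) - 0.5, labels)
            assert fs.anosim_r(m1) == pytest.approx(fs.anosim_r(m2), abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(100):
            labels = np.array([True] * 3 + [False] * 3)
            mat = distance_matrix_from(rng.uniform(0, 1, 15), labels)
            assert -1.0 - 1e-12 <= fs.anosim_r(mat) <= 1.0 + 1e-12

    def test_small_group_rejected(self):
        mat = distance_matrix_from([0.1, 0.2, 0.3], [True, False, False])
        with pytest.raises(ValueError, match=">= 2"):
            fs.anosim_r(mat)


class TestEnumeration:
    @pytest.mark.parametrize(
        "n_t, n_c, expected",
        [(3, 3, 10), (2, 2, 3), (3, 2, 10), (4, 4, 35), (2, 3, 10), (4, 2, 15)],
    )
    def test_counts_match_closed_forms(self, n_t, n_c, expected):
        assignments = fs.enumerate_label_assignments(n_t, n_c)
        assert len(assignments) == expected
        assert n_distinct_assignments(n_t, n_c) == expected
        # identity (treatment samples first) leads the list
        assert assignments[0, :n_t].all() and not assignments[0, n_t:].any()
        # all rows distinct and with correct group sizes
        assert len({tuple(a) for a in assignments}) == expected
        assert (assignments.sum(axis=1) == n_t).all()

    def test_balanced_collapses_group_swap(self):
        assignments = fs.enumerate_label_assignments(3, 3)
        seen = {tuple(a) for a in assignments}
        for a in assignments:
            assert tuple(~a) not in seen


class TestLocalPvalue:
    def test_strictly_largest_r_gives_min_p(self):
        mat = separated_3v3_matrix()
        r_obs, p, n = fs.local_permutation_pvalue(mat)
        assert (r_obs, n) == (pytest.approx(1.0), 10)
        assert p == pytest.approx(0.1)

    def test_all_assignments_tied_gives_one(self):
        mat = distance_matrix_from([0.5] * 15, [True] * 3 + [False] * 3)
        _, p, _ = fs.local_permutation_pvalue(mat)
        assert p == pytest.approx(1.0)

    def test_three_replicates_cannot_reach_significance(self, rng):
        """The exact 3v3 p-value floor is 1/10, above alpha = 0.05."""
        for _ in range(20):
            mat = distance_matrix_from(
                rng.uniform(0, 1, 15), [True] * 3 + [False] * 3
            )
            _, p, _ = fs.local_permutation_pvalue(mat)
            assert p >= 0.1 > 0.05

    def test_monte_carlo_mode_close_to_exact(self, rng):
        mat = distance_matrix_from(
            rng.uniform(0, 1, 15), [True] * 3 + [False] * 3
        )
        _, p_exact, _ = fs.local_permutation_pvalue(mat)
        _, p_mc, n = fs.local_permutation_pvalue(
            mat, mode="monte_carlo", n_monte_carlo=2000,
            rng=np.random.default_rng(1),
        )
        assert n == 2001
        assert p_mc == pytest.approx(p_exact, abs=0.05)


class TestGlobalNull:
    def make_matrices(self, rng, n_prot=2, n_t=3, n_c=3):
        n = n_t + n_c
        return {
            f"P{i}": distance_matrix_from(
                rng.uniform(0, 1, n * (n - 1) // 2), [True] * n_t + [False] * n_c
            )
            for i in range(n_prot)
        }

    def test_pool_sizes(self, rng):
        mats = self.make_matrices(rng)
        assert fs.global_null_distribution(mats).size == 18  # 2 x (10-1)
        assert (
            fs.global_null_distribution(mats, include_identity=True).size == 20
        )

    def test_complete_enumeration_mean_zero(self, rng):
        """Mean R over the full enumeration (identity included) is 0."""
        for _ in range(10):
            mats = self.make_matrices(rng, n_prot=3)
            null = fs.global_null_distribution(mats, include_identity=True)
            assert abs(null.values.mean()) < 1e-12

    def test_monte_carlo_is_seeded(self, rng):
        mats = self.make_matrices(rng, n_t=4, n_c=4)
        a = fs.global_null_distribution(mats, exact_limit=5, seed=7)
        b = fs.global_null_distribution(mats, exact_limit=5, seed=7)
        assert a.mode == "monte_carlo"
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no testable"):
            fs.global_null_distribution({})


class TestGlobalPvalues:
    def test_add_one_estimator(self):
        null = NullDistribution(values=np.linspace(-0.9, 0.8, 18), mode="exact")
        p, _ = fs.global_pvalues(np.array([0.99]), null)
        assert p[0] == pytest.approx(1 / 19)

    def test_r_below_all_null_gives_one(self):
        null = NullDistribution(values=np.linspace(-0.5, 0.9, 18), mode="exact")
        p, _ = fs.global_pvalues(np.array([-0.9]), null)
        assert p[0] == pytest.approx(1.0)

    def test_bh_adjustment_hand_example(self):
        # choose null so p-values come out exactly [0.005, 0.01, 0.03, 0.04]
        null = NullDistribution(values=np.arange(1, 200) / 200.0, mode="exact")
        r = np.array([1.0, 0.992, 0.972, 0.962])
        p, p_adj = fs.global_pvalues(r, null)
        np.testing.assert_allclose(p, [0.005, 0.01, 0.03, 0.04], atol=1e-12)
        np.testing.assert_allclose(p_adj, [0.02, 0.02, 0.04, 0.04], atol=1e-12)

    def test_untestable_nan_excluded_from_bh(self):
        null = NullDistribution(values=np.linspace(-1, 1, 99), mode="exact")
        p, p_adj = fs.global_pvalues(np.array([0.9, np.nan]), null)
        assert np.isnan(p[1]) and np.isnan(p_adj[1])
        assert 0 < p[0] <= 1

    def test_pvalues_in_unit_interval(self, rng):
        null = NullDistribution(values=rng.uniform(-1, 1, 500), mode="exact")
        p, p_adj = fs.global_pvalues(rng.uniform(-1, 1, 100), null)
        assert ((p > 0) & (p <= 1)).all()
        assert ((p_adj > 0) & (p_adj <= 1)).all()


class TestRCutoff:
    def test_maximum_at_percentile_100(self):
        null = NullDistribution(values=np.array([-1, 0, 0, 0, 1.0]), mode="exact")
        assert fs.r_cutoff(null, 100) == 1.0

    def test_interpolated_percentile(self):
        null = NullDistribution(values=np.linspace(-0.9, 0.9, 19), mode="exact")
        assert fs.r_cutoff(null, 95) == pytest.approx(0.81)

    def test_monotone_in_percentile(self, rng):
        null = NullDistribution(values=rng.uniform(-1, 1, 200), mode="exact")
        cuts = [fs.r_cutoff(null, q) for q in np.linspace(1, 100, 25)]
        assert all(b >= a for a, b in zip(cuts, cuts[1:]))


class TestBruteForceOracles:
    def brute_force_r(self, mat):
        """Independent R computation: explicit rank loop over pairs."""
        n = mat.n_samples
        pairs = list(itertools.combinations(range(n), 2))
        dists = [mat.matrix[a, b] for a, b in pairs]
        ranks = rankdata(dists)
        rb = np.mean(
            [r for r, (a, b) in zip(ranks, pairs)
             if mat.is_treatment[a] != mat.is_treatment[b]]
        )
        rw = np.mean(
            [r for r, (a, b) in zip(ranks, pairs)
             if mat.is_treatment[a] == mat.is_treatment[b]]
        )
        return (rb - rw) / ((n * (n - 1) / 2) / 2)

    def test_r_matches_brute_force(self, rng):
        for _ in range(100):
            n_t, n_c = rng.integers(2, 5, size=2)
            n = int(n_t + n_c)
            mat = distance_matrix_from(
                rng.uniform(0, 1, n * (n - 1) // 2),
                [True] * n_t + [False] * (n - n_t),
            )
            assert fs.anosim_r(mat) == pytest.approx(
                self.brute_force_r(mat), abs=1e-12
            )

    def test_permuted_values_match_per_assignment_recompute(self, rng):
        labels = np.array([True] * 3 + [False] * 3)
        mat = distance_matrix_from(rng.uniform(0, 1, 15), labels)
        assignments = fs.enumerate_label_assignments(3, 3)
        fast = permuted_r_values(mat, assignments)
        for k, a in enumerate(assignments):
            relabeled = fs.DistanceMatrix(
                protein="p", matrix=mat.matrix, is_treatment=a
            )
            assert fast[k] == pytest.approx(self.brute_force_r(relabeled), abs=1e-12)
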