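"""Permutation test, activity patterns and differential-region building."""

import numpy as np
import pandas as pd
import pytest

from enhancerkit.dynamics import (
    DifferentialRegion,
    PairTest,
    ProbabilityMatrix,
    all_pair_tests,
    assign_patterns,
    build_regions,
    condition_pairs,
    enumerate_patterns,
    permutation_pvalues,
)
from enhancerkit.dynamics import test_statistic as weighted_diff_statistic


def matrix_from(A, n_per_cond=(2, 2), conditions=("c1", "c2")):
    samples, condition_of = [], {}
    for cond, n in zip(conditions, n_per_cond):
        for r in range(n):
            s = f"{cond}_r{r}"
            samples.append(s)
            condition_of[s] = cond
    meta = pd.DataFrame(
        {"chrom": "chr1", "bin": range(len(A)), "start": 100 * np.arange(len(A))}
    )
    return ProbabilityMatrix(np.asarray(A, float), samples, condition_of, meta)


class TestStatistic:
    def test_simple_substitution(self):
        # constructed so the pooled SD is exactly 1: var = 2 in each group of 2
        row = np.array([1 - 1, 1 + 1, 0 - 1, 0 + 1], dtype=float)
        t = weighted_diff_statistic(row, (np.array([0, 1]), np.array([2, 3])), w0=0.5)
        # mu1=1? no: row = (0,2,-1,1): mu1=1, mu2=0, s_pooled=sqrt(2*(1/2+1/2))...
        assert t == pytest.approx((1 - 0 - 0.5) / np.sqrt(2.0))

    def test_identical_groups_zero(self):
        row = np.array([0.2, 0.4, 0.2, 0.4])
        assert weighted_diff_statistic(row, (np.array([0, 1]), np.array([2, 3])), 0.0) == 0.0

    def test_hand_evaluated_small_groups(self):
        row = np.array([0.9, 1.0, 0.1, 0.2])
        t = weighted_diff_statistic(row, (np.array([0, 1]), np.array([2, 3])), 0.5)
        assert t == pytest.approx(4.242640687, abs=1e-6)

    def test_single_member_group_uses_epsilon(self):
        row = np.array([1.0, 0.0, 0.0])
        t = weighted_diff_statistic(row, (np.array([0]), np.array([1, 2])), 0.5)
        assert t > 1e6  # |diff| > w0 with eps-scaled denominator

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            weighted_diff_statistic(np.array([1.0, 0.0]), (np.array([], int), np.array([1])), 0.5)


class TestPermutationPvalues:
    def test_p_floor_and_range(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 0.2, size=(500, 4))
        A[10] = [0.99, 0.98, 0.01, 0.02]  # one strongly differential bin
        pt = permutation_pvalues(matrix_from(A), ("c1", "c2"), w0=0.5, seed=1)
        floor = 1.0 / (1.0 + pt.n_null)
        assert pt.p.min() >= floor
        assert pt.p[10] == pytest.approx(floor, rel=0.5)
        assert np.all((pt.p > 0) & (pt.p <= 1))

    def test_constant_matrix_all_p_one(self):
        A = np.full((50, 4), 0.3)
        pt = permutation_pvalues(matrix_from(A), ("c1", "c2"), w0=0.0, seed=1)
        np.testing.assert_allclose(pt.p, 1.0)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(size=(100, 4))
        m = matrix_from(A)
        a = permutation_pvalues(m, ("c1", "c2"), seed=7)
        b = permutation_pvalues(m, ("c1", "c2"), seed=7)
        np.testing.assert_array_equal(a.p, b.p)

    def test_fewer_than_two_bins_raises(self):
        with pytest.raises(ValueError):
            permutation_pvalues(matrix_from([[0.1, 0.2, 0.3, 0.4]]), ("c1", "c2"))

    def test_type_one_error_controlled_under_null(self):
        """Fraction of bins with p <= alpha stays near alpha on null data."""
        rng = np.random.default_rng(5)
        A = rng.uniform(0, 1, size=(5000, 4))
        pt = permutation_pvalues(matrix_from(A), ("c1", "c2"), w0=0.0, seed=3)
        for alpha in (0.01, 0.05):
            margin = 3 * np.sqrt(alpha * (1 - alpha) / A.shape[0])
            assert (pt.p <= alpha).mean() <= alpha + margin

    def test_w0_monotonicity(self, predictions, sim_test):
        """Raising w0 can only shrink the significant-bin set."""
        matrix = ProbabilityMatrix.from_tracks(predictions, sim_test.cfg.condition_of)
        pair = tuple(sim_test.cfg.conditions[:2])
        hi = permutation_pvalues(matrix, pair, w0=0.5, seed=9)
        lo = permutation_pvalues(matrix, pair, w0=0.1, seed=9)
        sig_hi = (hi.p <= 0.05) | (hi.p_rev <= 0.05)
        sig_lo = (lo.p <= 0.05) | (lo.p_rev <= 0.05)
        assert not np.any(sig_hi & ~sig_lo)
        assert sig_lo.sum() > sig_hi.sum()

    def test_pattern_symmetry_under_label_swap(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(size=(300, 4))
        A[:50, :2] += 0.6  # more active in c1
        A = np.clip(A, 0, 1)
        m = matrix_from(A)
        fwd = permutation_pvalues(m, ("c1", "c2"), w0=0.3, seed=4)
        rev = permutation_pvalues(m, ("c2", "c1"), w0=0.3, seed=4)
        np.testing.assert_array_equal(fwd.p, rev.p_rev)
        np.testing.assert_array_equal(fwd.p_rev, rev.p)
        np.testing.assert_allclose(fwd.mean_diff, -rev.mean_diff)


class TestEnumeratePatterns:
    @pytest.mark.parametrize("n,expected", [(2, 2), (3, 26), (4, 728)])
    def test_pattern_counts(self, n, expected):
        pats = enumerate_patterns(n)
        assert len(pats) == expected
        assert len(set(pats)) == expected
        assert all(any(s != (0, 0) for s in p) for p in pats)

    def test_single_condition_raises(self):
        with pytest.raises(ValueError):
            enumerate_patterns(1)

    def test_pair_count_three_conditions(self):
        assert len(condition_pairs(["a", "b", "c"])) == 3


def make_pair_test(p, p_rev, diff, pair=("c1", "c2")):
    p = np.asarray(p, float)
    return PairTest(pair, 0.5, np.zeros_like(p), np.asarray(diff, float),
                    p, np.asarray(p_rev, float), len(p))


def meta_for(n, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "bin": range(n), "start": 100 * np.arange(n)})


class TestAssignPatterns:
    def test_five_low_pvalues_and_positive_diff(self):
        p = np.array([1, 1, 0.01, 0.01, 0.01, 0.01, 0.01, 1, 1])
        t = make_pair_test(p, np.ones_like(p), np.full(9, 0.8))
        codes = assign_patterns([t], meta_for(9), pstar=0.05)
        assert codes[4, 0] == 1  # center of the five-bin run
        assert codes[2, 0] == 0  # run truncated on the left

    def test_one_high_neighbor_blocks(self):
        p = np.array([0.01, 0.01, 0.01, 0.2, 0.01, 0.01, 0.01])
        t = make_pair_test(p, np.ones_like(p), np.full(7, 0.8))
        codes = assign_patterns([t], meta_for(7), pstar=0.05)
        assert np.all(codes[:, 0] == 0)

    def test_negative_diff_uses_reverse_direction(self):
        p_rev = np.full(7, 0.01)
        t = make_pair_test(np.ones(7), p_rev, np.full(7, -0.8))
        codes = assign_patterns([t], meta_for(7), pstar=0.05)
        assert codes[3, 0] == 2

    def test_chromosome_edges_fail_window(self):
        p = np.full(5, 0.01)
        t = make_pair_test(p, np.ones_like(p), np.full(5, 0.8))
        codes = assign_patterns([t], meta_for(5), pstar=0.05)
        assert codes[0, 0] == 0 and codes[1, 0] == 0
        assert codes[2, 0] == 1
        assert codes[3, 0] == 0 and codes[4, 0] == 0


class TestBuildRegions:
    def run(self, sig_bins_p, n=100, gap_bins=None):
        """sig_bins_p: {bin: (code, p)} on one chromosome."""
        p = np.ones(n)
        p_rev = np.ones(n)
        diff = np.zeros(n)
        codes = np.zeros((n, 1), dtype=np.int8)
        for b, (code, pv) in sig_bins_p.items():
            codes[b, 0] = code
            if code == 1:
                p[b] = pv
                diff[b] = 0.8
            else:
                p_rev[b] = pv
                diff[b] = -0.8
        t = make_pair_test(p, p_rev, diff)
        return build_regions([t], meta_for(n), codes, merge_gap=2000)

    def test_bins_within_2kb_merge(self):
        regions = self.run({10: (1, 1e-3), 25: (1, 1e-4)})  # 1.5 kb apart
        assert len(regions) == 1
        assert regions[0].peak_bin == 25  # lower p wins
        assert (regions[0].start, regions[0].end) == (1000, 2600)

    def test_bins_beyond_2kb_split(self):
        regions = self.run({10: (1, 1e-3), 41: (1, 1e-4)})  # 3 kb apart
        assert len(regions) == 2

    def test_overlapping_patterns_lowest_peak_p_wins(self):
        # pattern (1,) bins at 10 and 29 merge across the gap (1.8 kb) and
        # span the pattern (2,) bin at 20; the lower peak p labels the union
        regions = self.run({10: (1, 1e-4), 29: (1, 2e-4), 20: (2, 1e-2)})
        assert len(regions) == 1
        assert regions[0].pattern == (1,)
        assert regions[0].peak_p == pytest.approx(1e-4)
        assert (regions[0].start, regions[0].end) == (1000, 3000)

    def test_no_patterned_bins_empty(self):
        assert self.run({}) == []


def test_planted_condition_specific_recovery(predictions, sim_test):
    """Differential calling recovers planted condition-specific enhancers."""
    from enhancerkit.synthetic import match_differential_regions

    matrix = ProbabilityMatrix.from_tracks(predictions, sim_test.cfg.condition_of)
    tests = all_pair_tests(matrix, w0=0.5, seed=5)
    codes = assign_patterns(tests, matrix.bins_meta, pstar=0.05)
    regions = build_regions(tests, matrix.bins_meta, codes)
    sens = match_differential_regions(regions, sim_test.truth, sim_test.cfg)
    assert sens >= 0.9
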