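import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macscreen import stat_core
from macscreen.stat_core import (
    bh_adjust,
    fisher_exact_2x2,
    one_way_anova,
    permutation_null,
    spearman,
    spearman_matrix,
    storey_qvalues,
    student_t_two_sample,
)


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 5.0, 8.0]
        assert spearman(x, x).statistic == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_p_matches_full_enumeration_at_n7(self, rng):
        # oracle: all 5040 rank permutations, computed here independently
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        res = spearman(x, y, exact=True)
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        rhos = []
        for perm in itertools.permutations(ry):
            rhos.append(np.corrcoef(rx, perm)[0, 1])
        p_oracle = np.mean(np.abs(rhos) >= abs(res.statistic) - 1e-12)
        assert res.p_value == pytest.approx(p_oracle)

    def test_matrix_agrees_with_pairwise(self, rng):
        X = rng.normal(size=(12, 20))
        y = rng.normal(size=20)
        rho, p = spearman_matrix(X, y)
        for i in range(12):
            res = spearman(X[i], y)
            assert rho[i] == pytest.approx(res.statistic)
            assert p[i] == pytest.approx(res.p_value)

    def test_matrix_handles_ties_by_midrank(self):
        X = np.array([[1.0, 1.0, 2.0, 3.0, 3.0]])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        rho, _ = spearman_matrix(X, y)
        from scipy.stats import spearmanr

        assert rho[0] == pytest.approx(spearmanr(X[0], y).statistic)

    def test_null_rho_variance_matches_theory(self, rng):
        # under independence Var(rho) = 1/(n-1)
        n, reps = 12, 4000
        rhos = [
            np.corrcoef(rng.permutation(n), np.arange(n))[0, 1]
            for _ in range(reps)
        ]
        assert np.var(rhos) == pytest.approx(1 / (n - 1), rel=0.1)


# ---------------------------------------------------------------------------
# Fisher exact


def _fisher_oracle(a, b, c, d, tail):
    """Exact-integer hypergeometric enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    if tail == "one_greater":
        num = sum(w for k, w in weights.items() if k >= a)
    else:
        w_obs = weights[a]
        num = sum(w for w in weights.values() if w <= w_obs)
    return num / total


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, tail, bound",
        [
            ((8, 2, 2, 7), "one_greater", 0.05),   # 8/10 vs 2/9 success rates
            ((6, 4, 1, 8), "one_greater", 0.05),   # 6/10 vs 1/9 allelic effects
        ],
    )
    def test_reported_contrasts_are_significant(self, table, tail, bound):
        assert fisher_exact_2x2(*table, tail=tail).p_value <= bound

    def test_balanced_table_one_tailed_above_half(self):
        assert fisher_exact_2x2(5, 5, 5, 5, tail="one_greater").p_value > 0.5

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(0, 5, 0, 7)

    @given(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        for tail in ("one_greater", "two"):
            p = fisher_exact_2x2(a, b, c, d, tail=tail).p_value
            assert p == pytest.approx(_fisher_oracle(a, b, c, d, tail), abs=1e-10)


# ---------------------------------------------------------------------------
# t-test / ANOVA


class TestTTestAnova:
    def test_identical_groups(self):
        res = student_t_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_formula_small_groups(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = student_t_two_sample(a, b)
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4  # pooled variance
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.statistic == pytest.approx(t_hand)
        assert res.df == 4

    def test_swap_antisymmetry(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        r1 = student_t_two_sample(a, b)
        r2 = student_t_two_sample(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            student_t_two_sample([1.0, 1.0], [1.0, 1.0])

    def test_equal_mean_groups_give_small_f(self, rng):
        g = [rng.normal(0, 1, 40), rng.normal(0, 1, 40)]
        res = one_way_anova(g)
        assert res.p_value > 0.05 or res.statistic < 4

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=6), rng.normal(1, 1, size=9)
        f = one_way_anova([a, b])
        t = student_t_two_sample(a, b)
        assert f.statistic == pytest.approx(t.statistic**2)
        assert f.p_value == pytest.approx(t.p_value)

    def test_three_groups_match_sum_of_squares_oracle(self):
        groups = [[1.0, 2.0], [2.0, 4.0], [5.0, 7.0]]
        res = one_way_anova(groups)
        flat = np.concatenate(groups)
        grand = flat.mean()
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum(((np.array(g) - np.mean(g)) ** 2).sum() for g in groups)
        f_hand = (ss_between / 2) / (ss_within / 3)
        assert res.statistic == pytest.approx(f_hand)


# ---------------------------------------------------------------------------
# multiple testing


class TestFdr:
    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0] * 5), 1.0)
        np.testing.assert_allclose(storey_qvalues([1.0] * 5, pi0=1.0), 1.0)

    def test_bh_matches_manual_step_up(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
        m = len(p)
        manual = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(bh_adjust(p), manual)

    def test_storey_with_pi0_one_equals_bh(self, rng):
        p = rng.uniform(size=50)
        np.testing.assert_allclose(storey_qvalues(p, pi0=1.0), bh_adjust(p))

    def test_q_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(size=100))
        for q in (bh_adjust(p), storey_qvalues(p)):
            assert (np.diff(q) >= -1e-12).all()
            assert ((q >= 0) & (q <= 1)).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            storey_qvalues([-0.1, 0.5])


# ---------------------------------------------------------------------------
# permutation machinery


class TestPermutationNull:
    @staticmethod
    def _stat(data, resp):
        return data @ resp  # simple per-row statistic

    def test_seed_reproducibility(self, rng):
        data = rng.normal(size=(4, 10))
        resp = rng.normal(size=10)
        a = permutation_null(self._stat, resp, data, n_perm=25, seed=7)
        b = permutation_null(self._stat, resp, data, n_perm=25, seed=7)
        np.testing.assert_array_equal(a.null, b.null)
        assert not np.array_equal(
            a.null, permutation_null(self._stat, resp, data, 25, seed=8).null
        )

    def test_identity_permutation_not_excluded(self):
        # with n=2 and many draws, both permutations (incl. identity) appear
        data = np.array([[1.0, 0.0]])
        resp = np.array([0.0, 1.0])
        res = permutation_null(self._stat, resp, data, n_perm=64, seed=1)
        vals = set(np.round(res.null.ravel(), 6))
        assert vals == {0.0, 1.0}

    def test_type_i_error_calibration_of_screen_p(self, rng):
        # under the null, per-gene Spearman p at 0.05 rejects ~5% of the time
        X = rng.normal(size=(10000, 48))
        y = rng.normal(size=48)
        _, p = spearman_matrix(X, y)
        rate = (p < 0.05).mean()
        # binomial 99% band around 0.05 at 10000 reps
        half = 2.576 * math.sqrt(0.05 * 0.95 / 10000)
        assert abs(rate - 0.05) < half + 0.003  # slack for rank discreteness
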