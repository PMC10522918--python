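"""Unit and property tests for the survival statistics primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from prognoscore.survival import (
    EstimationError,
    fisher_exact,
    fit_cox,
    km_estimate,
    logrank_test,
    mann_whitney,
    optimal_cutoff,
    select_cutoff_index,
    td_roc,
)

import pandas as pd


# ======================================================================
# Kaplan-Meier
# ======================================================================
class TestKaplanMeier:
    def test_two_events_by_hand(self):
        km = km_estimate([1, 2], [1, 1])
        assert km.survival_at(1) == pytest.approx(0.5)
        assert km.survival_at(2) == pytest.approx(0.0)

    def test_all_censored_flat_median_not_reached(self):
        km = km_estimate([3, 5, 7], [0, 0, 0])
        assert km.survival_at(7) == 1.0
        assert not km.median_reached

    def test_mixed_case_matches_hand_product_limit(self):
        # times 1(ev) 2(cens) 3(ev) 4(ev) 5(cens) 6(ev)
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 0, 1, 1, 0, 1]
        km = km_estimate(t, e)
        # hand product-limit: S(1)=5/6, S(3)=5/6*3/4, S(4)=...*2/3, S(6)=...*0
        assert km.survival_at(1) == pytest.approx(5 / 6)
        assert km.survival_at(3) == pytest.approx(5 / 6 * 3 / 4)
        assert km.survival_at(4) == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert km.survival_at(6) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 40).round(1)
        km = km_estimate(t, np.ones_like(t))
        for q in [2, 5, 8, 15]:
            assert km.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_zero_risk_time_errors(self):
        with pytest.raises(EstimationError):
            km_estimate([0, 0], [0, 0])


# ======================================================================
# Log-rank
# ======================================================================
class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 3, 5, 7, 9]
        e = [1, 0, 1, 1, 0]
        chi2, df, p = logrank_test([0] * 5 + [1] * 5, t + t, e + e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_significant(self):
        # direct O-E oracle: group 0 dies first, far earlier than group 1
        t = list(range(1, 11)) + list(range(100, 110))
        e = [1] * 20
        g = [0] * 10 + [1] * 10
        chi2, df, p = logrank_test(g, t, e)
        assert df == 1
        assert p < 0.01

    def test_three_groups_df_two(self, rng):
        t = rng.exponential(5, 30)
        g = np.repeat([0, 1, 2], 10)
        _, df, _ = logrank_test(g, t, np.ones(30))
        assert df == 2

    def test_single_group_errors(self):
        with pytest.raises(EstimationError):
            logrank_test([1, 1, 1], [1, 2, 3], [1, 1, 1])

    def test_zero_events_errors(self):
        with pytest.raises(EstimationError):
            logrank_test([0, 0, 1, 1], [1, 2, 3, 4], [0, 0, 0, 0])


# ======================================================================
# Time-dependent ROC
# ======================================================================
class TestTdRoc:
    def test_perfect_separation_no_censoring(self):
        r = td_roc([1, 2, 3, 4], [5, 6, 1, 2], [1, 1, 1, 1], horizon=3)
        assert r.auc == pytest.approx(1.0)
        assert r.n_cases == pytest.approx(2.0)
        assert r.n_controls == pytest.approx(2.0)

    def test_equals_mann_whitney_auc_without_censoring(self, rng):
        """With no censoring before the horizon the survival ROC reduces to
        the classical empirical ROC on status-at-horizon."""
        checked = 0
        while checked < 20:
            n = int(rng.integers(5, 13))
            x = rng.normal(size=n)
            t = rng.exponential(5, n)
            h = float(np.median(t))
            status = (t <= h).astype(int)
            if status.sum() in (0, n):
                continue
            r = td_roc(x, t, np.ones(n), h)
            u = mannwhitneyu(x[status == 1], x[status == 0]).statistic
            assert r.auc == pytest.approx(
                u / (status.sum() * (n - status.sum())), abs=1e-12
            )
            checked += 1

    def test_invariant_under_monotone_marker_transform(self, rng):
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(30, n)
        c = rng.uniform(0, 60, n)
        obs, e = np.minimum(t, c), (t <= c).astype(int)
        r1 = td_roc(x, obs, e, 20)
        r2 = td_roc(np.exp(2 * x), obs, e, 20)
        assert r2.auc == pytest.approx(r1.auc, abs=1e-12)
        np.testing.assert_allclose(r1.sensitivity, r2.sensitivity, atol=1e-12)
        np.testing.assert_allclose(r1.specificity, r2.specificity, atol=1e-12)

    def test_null_marker_auc_near_half(self, rng):
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(40, n)
        c = rng.uniform(0, 100, n)
        r = td_roc(x, np.minimum(t, c), (t <= c).astype(int), 30)
        assert abs(r.auc - 0.5) < 0.05

    def test_constant_marker_errors(self):
        with pytest.raises(EstimationError, match="[Uu]ninformative"):
            td_roc([2, 2, 2, 2], [1, 2, 3, 4], [1, 1, 0, 0], 2)

    def test_no_cases_at_horizon_errors(self):
        with pytest.raises(EstimationError):
            td_roc([1, 2, 3], [10, 11, 12], [1, 1, 1], 5)


# ======================================================================
# Constrained optimal cutoff
# ======================================================================
def _exhaustive_cutoff_oracle(x, t, e, horizon, frac):
    """Brute force: evaluate J at every feasible midpoint cutoff via the
    ROC itself, then apply the constraint and tie rules independently."""
    import math

    r = td_roc(x, t, e, horizon)
    n = len(x)
    min_n = math.ceil(frac * n)
    best = None
    med = np.median(x)
    for k, c in enumerate(r.cutoffs):
        n_low = int(np.sum(x <= c))
        if n_low < min_n or n - n_low < min_n:
            continue
        j = r.sensitivity[k] + r.specificity[k] - 1
        key = (-j, abs(c - med), c)
        if best is None or key < best[0]:
            best = (key, c)
    return best[1] if best else None


class TestOptimalCutoff:
    def test_perfect_marker_takes_separating_cutoff(self):
        x = np.array([1, 2, 3, 4, 11, 12, 13, 14], dtype=float)
        t = np.array([50, 60, 55, 65, 1, 2, 3, 4], dtype=float)
        choice = optimal_cutoff(x, t, np.ones(8), horizon=10, min_group_frac=0.2)
        assert choice.youden == pytest.approx(1.0)
        assert 4 < choice.cutoff < 11

    def test_constraint_overrides_unconstrained_maximizer(self):
        # 10 samples; the single highest-marker sample dies immediately, so
        # the unconstrained Youden maximizer isolates it (10% < 20%)
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 20.0])
        t = np.array([40, 45, 50, 42, 47, 52, 44, 8, 9, 1.0])
        e = np.ones(10)
        choice = optimal_cutoff(x, t, e, horizon=10, min_group_frac=0.2)
        assert min(choice.group_sizes) >= 2
        oracle = _exhaustive_cutoff_oracle(x, t, e, 10, 0.2)
        assert choice.cutoff == pytest.approx(oracle)

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(15, 40))
            x = rng.normal(size=n)
            t = rng.exponential(20, n)
            c = rng.uniform(0, 40, n)
            obs, e = np.minimum(t, c), (t <= c).astype(int)
            h = 15.0
            try:
                choice = optimal_cutoff(x, obs, e, h, 0.2)
            except EstimationError:
                continue
            oracle = _exhaustive_cutoff_oracle(x, obs, e, h, 0.2)
            assert choice.cutoff == pytest.approx(oracle)
            assert min(choice.group_sizes) >= int(np.ceil(0.2 * n))

    def test_tie_broken_toward_median(self):
        # two cutoffs with identical J: distance 0.1 vs 0.7 from the median
        cutoffs = np.array([1.3, 1.9, 2.7])
        j = np.array([0.4, 0.4, 0.2])
        idx, tied = select_cutoff_index(
            cutoffs, j, np.ones(3, bool), median=2.0
        )
        assert cutoffs[idx] == pytest.approx(1.9)
        assert tied

    def test_tie_on_distance_takes_smaller_cutoff(self):
        cutoffs = np.array([1.5, 2.5])
        j = np.array([0.3, 0.3])
        idx, tied = select_cutoff_index(
            cutoffs, j, np.ones(2, bool), median=2.0
        )
        assert cutoffs[idx] == pytest.approx(1.5)
        assert tied

    def test_unconstrained_j_never_below_constrained(self, rng):
        for _ in range(10):
            n = 30
            x = rng.normal(size=n)
            t = rng.exponential(20, n)
            e = np.ones(n)
            h = float(np.median(t))
            tight = optimal_cutoff(x, t, e, h, 0.4)
            loose = optimal_cutoff(x, t, e, h, 1.0 / n)
            assert loose.youden >= tight.youden - 1e-12


# ======================================================================
# Cox fitting
# ======================================================================
def _efron_grid_oracle(x, t, e, lo=-4.0, hi=4.0, step=1e-4):
    """Grid-search maximizer of the Efron partial likelihood for a single
    binary covariate."""
    grid = np.arange(lo, hi + step, step)
    loglik = np.zeros_like(grid)
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        dead = (t == ut) & (e == 1)
        d = dead.sum()
        n1_risk = (x[at_risk] == 1).sum()
        n0_risk = at_risk.sum() - n1_risk
        n1_dead = (x[dead] == 1).sum()
        n0_dead = d - n1_dead
        sum_dead_x = n1_dead
        loglik += grid * sum_dead_x
        risk_term = n0_risk + n1_risk * np.exp(grid)
        dead_term = n0_dead + n1_dead * np.exp(grid)
        for j in range(d):
            loglik -= np.log(risk_term - (j / d) * dead_term)
    return grid[np.argmax(loglik)]


class TestCoxFit:
    def test_exchangeable_groups_beta_zero(self):
        t = [2, 4, 6, 8]
        e = [1, 1, 0, 1]
        design = pd.DataFrame({"g": [0, 0, 0, 0, 1, 1, 1, 1]}, dtype=float)
        fit = fit_cox(design, t + t, e + e)
        assert fit.beta["g"] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr["g"] == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_grid_search_partial_likelihood(self, ties):
        # 6 subjects with a tie, single binary covariate
        t = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 1, 0, 1, 1])
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        design = pd.DataFrame({"x": x})
        fit = fit_cox(design, t, e, ties=ties)
        if ties == "efron":
            oracle = _efron_grid_oracle(x, t, e)
            assert fit.beta["x"] == pytest.approx(oracle, abs=1e-4)
        else:
            assert np.isfinite(fit.beta["x"])

    def test_constant_column_errors(self):
        design = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(EstimationError, match="constant"):
            fit_cox(design, [1, 2, 3, 4], [1, 1, 0, 1])

    def test_duplicated_data_same_beta_smaller_se(self, rng):
        # exact under Breslow ties (duplication shifts the partial
        # likelihood by a constant); Efron handles the created ties
        # differently so only approximate agreement is expected there
        n = 60
        x = (rng.uniform(size=n) > 0.5).astype(float)
        t = rng.exponential(10 * np.exp(-0.5 * x))
        e = np.ones(n)
        f1 = fit_cox(pd.DataFrame({"x": x}), t, e, ties="breslow")
        f2 = fit_cox(
            pd.DataFrame({"x": np.concatenate([x, x])}),
            np.concatenate([t, t]),
            np.concatenate([e, e]),
            ties="breslow",
        )
        assert f2.beta["x"] == pytest.approx(f1.beta["x"], abs=1e-5)
        assert f2.se["x"] == pytest.approx(f1.se["x"] / np.sqrt(2), rel=0.05)
        fe = fit_cox(
            pd.DataFrame({"x": np.concatenate([x, x])}),
            np.concatenate([t, t]),
            np.concatenate([e, e]),
        )
        assert fe.beta["x"] == pytest.approx(f1.beta["x"], rel=0.05)

    def test_separation_flagged_not_silent(self):
        # complete separation: all events in group 1, long censoring in 0
        t = [1, 2, 3, 50, 60, 70]
        e = [1, 1, 1, 0, 0, 0]
        design = pd.DataFrame({"x": [1.0, 1, 1, 0, 0, 0]})
        fit = fit_cox(design, t, e)
        assert (not fit.converged) or fit.flags

    def test_ci_consistent_with_p(self, rng):
        n = 100
        x = (rng.uniform(size=n) > 0.5).astype(float)
        t = rng.exponential(10 * np.exp(-0.8 * x))
        fit = fit_cox(pd.DataFrame({"x": x}), t, np.ones(n))
        excludes_one = (fit.ci95.loc["x", "lower"] > 1) or (
            fit.ci95.loc["x", "upper"] < 1
        )
        assert excludes_one == (fit.p["x"] < 0.05)


# ======================================================================
# Plain tests
# ======================================================================
class TestPlainTests:
    def test_mann_whitney_identical_groups(self, rng):
        x = rng.normal(size=20)
        u, p = mann_whitney(x, x.copy())
        assert u == pytest.approx(200.0)
        assert p > 0.95

    def test_fisher_diagonal_table(self):
        odds, p = fisher_exact([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_fisher_flat_table(self):
        odds, p = fisher_exact([[2, 2], [2, 2]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(EstimationError):
            mann_whitney([], [1, 2])


# ======================================================================
# Hypothesis properties
# ======================================================================
@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_roc_auc_strictly_increasing_transform_property(seed):
    rng = np.random.default_rng(seed)
    n = 30
    x = rng.normal(size=n)
    t = rng.exponential(10, n)
    h = float(np.median(t))
    r1 = td_roc(x, t, np.ones(n), h)
    r2 = td_roc(3 * x + 7, t, np.ones(n), h)
    assert r2.auc == pytest.approx(r1.auc, abs=1e-12)
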