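import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from compositemr.mr import (MROptions, association_stats, evalue, evalue_summary, ivw,
                            mr_egger, penalized_ivw, run_mr, run_mr_stats,
                            weighted_median, weighted_median_point)
from compositemr.scenarios import simulate_summary_stats

from conftest import make_derived_cohort, make_genotypes


def stats_frame(theta, se=None, beta_x=None):
    theta = np.asarray(theta, dtype=float)
    beta_x = np.ones_like(theta) if beta_x is None else np.asarray(beta_x, dtype=float)
    se = np.full_like(theta, 0.1) if se is None else np.asarray(se, dtype=float)
    return pd.DataFrame({
        "iv": [f"iv{i}" for i in range(len(theta))],
        "beta_x": beta_x, "se_x": 0.05,
        "beta_y": theta * beta_x, "se_y": se * np.abs(beta_x),
        "n_used": 1000,
    })


class TestIVW:
    def test_single_iv_is_the_exact_ratio(self):
        s = stats_frame([0.37], beta_x=[0.81])
        assert ivw(s).estimate == s.loc[0, "beta_y"] / s.loc[0, "beta_x"]

    def test_equal_weights_average(self):
        assert ivw(stats_frame([0.1, 0.3])).estimate == pytest.approx(0.2)

    def test_equals_weighted_least_squares_through_origin(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = simulate_summary_stats(rng, 20, theta=0.2)
            wls = sm.WLS(s["beta_y"], s[["beta_x"]], weights=1.0 / s["se_y"] ** 2).fit()
            assert ivw(s).estimate == pytest.approx(wls.params.iloc[0], abs=1e-10)

    def test_zero_beta_x_excluded_with_warning(self):
        s = stats_frame([0.2, 0.2, 0.2])
        s.loc[0, "beta_x"] = 0.0
        with pytest.warns(UserWarning, match="beta_x = 0"):
            r = ivw(s)
        assert r.n_ivs == 2

    def test_ci_contains_estimate(self):
        r = ivw(stats_frame([0.1, 0.2, 0.4]))
        assert r.ci95[0] < r.estimate < r.ci95[1]


class TestPenalizedIVW:
    def test_homogeneous_ratios_leave_ivw_unchanged(self):
        s = stats_frame([0.25] * 5)
        assert penalized_ivw(s).estimate == pytest.approx(ivw(s).estimate, abs=1e-12)

    def test_gross_outlier_is_downweighted(self):
        theta = [0.2] * 19 + [5.0]
        se = [0.1] * 19 + [0.05]
        s = stats_frame(theta, se=se)
        est_ivw = ivw(s).estimate
        est_pen = penalized_ivw(s).estimate
        assert abs(est_pen - 0.2) < abs(est_ivw - 0.2)

    def test_infinite_penalty_factor_recovers_ivw(self):
        rng = np.random.default_rng(1)
        s = simulate_summary_stats(rng, 15, theta=0.3, se_y=0.2)
        assert penalized_ivw(s, penalty_factor=np.inf).estimate == pytest.approx(
            ivw(s).estimate, abs=1e-10)


def median_oracle(theta, w):
    """Independent direct transcription of the interpolation formula."""
    order = np.argsort(theta)
    t = np.asarray(theta, float)[order]
    w = np.asarray(w, float)[order] / np.sum(w)
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return t[0]
    if 0.5 >= s[-1]:
        return t[-1]
    j = int(np.max(np.where(s <= 0.5)))
    return t[j] + (t[j + 1] - t[j]) * (0.5 - s[j]) / (s[j + 1] - s[j])


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_plain_median(self):
        assert weighted_median(stats_frame([0.1, 0.2, 0.9])).estimate == pytest.approx(0.2)

    def test_constant_ratios_return_the_constant(self):
        assert weighted_median(stats_frame([0.4] * 5)).estimate == pytest.approx(0.4)

    def test_matches_independent_interpolation_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = simulate_summary_stats(rng, 5, theta=0.2, se_y=0.3)
            theta = s["beta_y"] / s["beta_x"]
            w = (s["beta_x"] / s["se_y"]) ** 2
            assert weighted_median_point(theta.to_numpy(), w.to_numpy()) == pytest.approx(
                median_oracle(theta, w), abs=1e-12)

    def test_invariant_to_splitting_a_tail_iv_in_half(self):
        # halving a tail IV's weight across two copies leaves the crossing
        # segment, and hence the estimate, untouched
        theta = np.array([0.1, 0.25, 0.4, 0.6])
        w = np.array([1.0, 2.0, 1.5, 0.5])
        split_theta = np.concatenate([theta, [0.6]])
        split_w = np.concatenate([w, [0.25]])
        split_w[3] = 0.25
        assert weighted_median_point(theta, w) == pytest.approx(
            weighted_median_point(split_theta, split_w), abs=1e-12)

    def test_bootstrap_se_is_seeded(self):
        s = stats_frame([0.1, 0.3, 0.5, 0.2])
        a = weighted_median(s, n_boot=200, seed=7)
        b = weighted_median(s, n_boot=200, seed=7)
        assert a.se == b.se

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            weighted_median_point(np.array([0.1, 0.2]), np.array([0.0, 0.0]))

    def test_resists_contamination_better_than_ivw(self):
        rng = np.random.default_rng(3)
        bias_med, bias_ivw = [], []
        for _ in range(200):
            s = simulate_summary_stats(rng, 20, theta=0.2, se_y=0.05)
            k = 8  # 40% of IVs pick up a +0.5 pleiotropic offset
            s.loc[:k - 1, "beta_y"] += 0.5
            bias_med.append(weighted_median(s, n_boot=0 or 10, seed=1).estimate - 0.2)
            bias_ivw.append(ivw(s).estimate - 0.2)
        assert abs(np.mean(bias_med)) < 0.5 * abs(np.mean(bias_ivw))


class TestMREgger:
    def test_exact_line_reproduced(self):
        s = stats_frame([0.0, 0.0, 0.0], beta_x=[0.1, 0.2, 0.4])
        s["beta_y"] = 0.05 + 0.3 * s["beta_x"]
        slope, intercept = mr_egger(s)
        assert slope.estimate == pytest.approx(0.3, abs=1e-12)
        assert intercept.estimate == pytest.approx(0.05, abs=1e-12)

    def test_equivariant_under_joint_sign_flip(self):
        rng = np.random.default_rng(4)
        s = simulate_summary_stats(rng, 10, theta=0.2, pleiotropy=0.05)
        flipped = s.copy()
        flipped.loc[::2, ["beta_x", "beta_y"]] *= -1.0
        for f in (ivw, lambda x: mr_egger(x)[0], lambda x: mr_egger(x)[1]):
            assert f(s).estimate == pytest.approx(f(flipped).estimate, abs=1e-10)
        assert weighted_median(s, seed=5).estimate == pytest.approx(
            weighted_median(flipped, seed=5).estimate, abs=1e-10)

    def test_fewer_than_three_ivs_rejected(self):
        with pytest.raises(ValueError, match="three"):
            mr_egger(stats_frame([0.1, 0.2]))


class TestEValue:
    def test_closed_form(self):
        assert evalue(1.0) == 1.0
        assert evalue(4.0) == pytest.approx(4 + np.sqrt(12))

    def test_inversion_symmetry(self):
        assert evalue(0.25) == pytest.approx(evalue(4.0), abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            evalue(0.0)

    def test_summary_null_is_ones(self):
        assert evalue_summary(stats_frame([0.0, 0.0, 0.0])) == (1.0, 1.0, 1.0)

    def test_summary_single_iv_collapses(self):
        avg, lo, hi = evalue_summary(stats_frame([0.3]))
        assert avg == lo == hi

    def test_summary_matches_hand_chain(self):
        theta = np.array([0.2, -0.4, 0.0])
        s = stats_frame(theta)
        expected = []
        for t in theta:
            rr = np.sqrt(np.exp(t))
            rr = max(rr, 1 / rr)
            expected.append(rr + np.sqrt(rr * (rr - 1)))
        avg, lo, hi = evalue_summary(s, "common_outcome_sqrt")
        assert avg == pytest.approx(np.mean(expected), abs=1e-12)
        assert (lo, hi) == (pytest.approx(min(expected), abs=1e-12),
                            pytest.approx(max(expected), abs=1e-12))

    def test_rare_outcome_conversion_uses_or_directly(self):
        s = stats_frame([np.log(4.0)])
        avg, _, _ = evalue_summary(s, "rare_outcome")
        assert avg == pytest.approx(4 + np.sqrt(12))


def irls_logit_oracle(y, X, tol=1e-12):
    """Independent iteratively-reweighted-least-squares logistic solver."""
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-X @ beta))
        W = p * (1 - p)
        z = X @ beta + (y - p) / W
        new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    cov = np.linalg.inv(X.T @ (W[:, None] * X))
    return beta, np.sqrt(np.diag(cov))


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(5)
    n = 50_000
    d = rng.binomial(2, 0.3, n).astype(float)
    x = (rng.random(n) < 1 / (1 + np.exp(-(-0.2 + 0.3 * d)))).astype(float)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.1 + 0.4 * x)))).astype(float)
    g = make_genotypes(d[:, None], ids=["iv0"])
    return g, make_derived_cohort(x, y), d, x, y


class TestAssociationStats:
    def test_matches_independent_irls_solver(self, planted):
        g, cohort, d, x, y = planted
        s = association_stats(g, cohort).iloc[0]
        beta, se = irls_logit_oracle(x, np.column_stack([np.ones_like(d), d]))
        assert s["beta_x"] == pytest.approx(beta[1], abs=1e-6)
        assert s["se_x"] == pytest.approx(se[1], abs=1e-6)

    def test_recovers_planted_exposure_effect(self, planted):
        g, cohort, *_ = planted
        s = association_stats(g, cohort).iloc[0]
        assert s["beta_x"] == pytest.approx(0.3, abs=0.05)

    def test_null_dosage_shows_no_association(self):
        rng = np.random.default_rng(6)
        n = 20_000
        d = rng.binomial(2, 0.3, n).astype(float)
        x = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < 0.55).astype(float)
        s = association_stats(make_genotypes(d[:, None]), make_derived_cohort(x, y)).iloc[0]
        assert abs(s["beta_x"]) < 3 * s["se_x"]
        assert abs(s["beta_y"]) < 3 * s["se_y"]

    def test_separated_iv_dropped_with_warning(self):
        x = np.repeat([0.0, 1.0], 30)
        y = np.tile([0.0, 1.0], 30)
        d = 2.0 * x  # perfectly predicts exposure
        with pytest.warns(UserWarning, match="separated"):
            s = association_stats(make_genotypes(d[:, None]), make_derived_cohort(x, y))
        assert len(s) == 0


class TestRunMR:
    def test_empty_iv_set_refused(self):
        with pytest.raises(ValueError, match="empty IV set"):
            run_mr_stats(pd.DataFrame(columns=["iv", "beta_x", "se_x", "beta_y", "se_y"]))

    def test_fewer_than_three_ivs_reports_ivw_only(self):
        rs = run_mr_stats(stats_frame([0.2, 0.3]))
        assert set(rs.results) == {"ivw"}
        assert any("skipped" in m for m in rs.messages)

    def test_verdict_requires_ivw_significance_and_clean_intercept(self):
        rng = np.random.default_rng(7)
        s = simulate_summary_stats(rng, 30, theta=0.5, se_y=0.02)
        rs = run_mr_stats(s)
        assert rs.results["ivw"].p < 0.05
        lo, hi = rs.egger_intercept.ci95
        assert rs.verdict == (lo <= 0 <= hi)

    def test_penalized_flagged_when_ivw_not_significant(self):
        rng = np.random.default_rng(8)
        s = simulate_summary_stats(rng, 10, theta=0.0, se_y=0.3)
        rs = run_mr_stats(s)
        if rs.results["ivw"].p >= 0.05:
            assert any("penalized" in m for m in rs.messages)
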