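"""Survival, correlation and tabulation analyses against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cedose import trial_tables as tt
from cedose.outcomes import (
    aft_lognormal_fit,
    cohort_summary,
    correlation_screen,
    km_fit,
    logrank,
    pooled_mean,
    response_table,
)


def logrank_oracle(times, events, group):
    """Brute-force observed-minus-expected log-rank chi-square."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group, bool)
    o_minus_e, var = 0.0, 0.0
    for tj in np.unique(times[events]):
        at_risk = times >= tj
        nj = at_risk.sum()
        n1j = (at_risk & group).sum()
        dj = (events & (times == tj)).sum()
        d1j = (events & (times == tj) & group).sum()
        o_minus_e += d1j - dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_hand_product_limit_on_three_events(self):
        km = km_fit([2, 4, 6], [True, True, True], landmark_times=(3.0,))
        s = km.survival["S"]
        assert s.loc[2.0] == pytest.approx(2 / 3)
        assert s.loc[4.0] == pytest.approx(1 / 3)
        assert s.loc[6.0] == pytest.approx(0.0)
        assert km.median_months == 4.0
        # Greenwood SE at t=3: S=2/3, var = S^2 * 1/(3*2)
        s3, se3 = km.landmarks[3.0]
        assert s3 == pytest.approx(2 / 3)
        assert se3 == pytest.approx((2 / 3) * math.sqrt(1 / 6))

    def test_all_censored_median_undefined(self):
        km = km_fit([5, 6, 7], [False, False, False])
        assert (km.survival["S"] == 1.0).all()
        assert km.median_months is None

    def test_single_event_median_is_that_time(self):
        km = km_fit([8.0], [True])
        assert km.median_months == 8.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10.0, 40)
        km = km_fit(t, np.ones(40, bool))
        for ti in t:
            empirical = (t > ti).mean()
            assert km.survival["S"].loc[ti] == pytest.approx(empirical, abs=1e-12)

    def test_all_censored_at_zero_rejected(self):
        with pytest.raises(ValueError, match="censored at time 0"):
            km_fit([0.0, 0.0], [False, False])


class TestLogrank:
    TOY = dict(
        times_a=[1.0, 3.0, 5.0],
        events_a=[True, True, False],
        times_b=[2.0, 4.0, 6.0],
        events_b=[True, True, True],
    )

    def test_identical_groups_null(self):
        chi2, p = logrank([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_oracle_on_toy_set(self):
        chi2, _ = logrank(**self.TOY)
        times = self.TOY["times_a"] + self.TOY["times_b"]
        events = self.TOY["events_a"] + self.TOY["events_b"]
        group = [True] * 3 + [False] * 3
        assert chi2 == pytest.approx(logrank_oracle(times, events, group), rel=1e-10)

    def test_label_swap_symmetry(self):
        chi2_ab, p_ab = logrank(**self.TOY)
        chi2_ba, p_ba = logrank(
            self.TOY["times_b"], self.TOY["events_b"], self.TOY["times_a"], self.TOY["events_a"]
        )
        assert chi2_ab == pytest.approx(chi2_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_chi2_p_consistent_with_exhaustive_permutation(self):
        """On a 10-subject toy set the chi-square(1) p-value agrees with the
        exhaustive label-permutation p-value to within the accuracy of the
        asymptotic approximation at this n."""
        times = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10.0])
        events = np.ones(10, bool)
        observed = logrank_oracle(times, events, np.arange(10) < 5)
        perm_stats = [
            logrank_oracle(times, events, np.isin(np.arange(10), combo))
            for combo in itertools.combinations(range(10), 5)
        ]
        p_perm = np.mean([s >= observed - 1e-12 for s in perm_stats])
        p_chi2 = stats.chi2.sf(observed, df=1)
        assert abs(p_chi2 - p_perm) < 0.1

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([0.0], [False], [1.0, 2.0], [True, True])


class TestAFT:
    def test_censorless_single_covariate_matches_ols(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.normal(size=n)
        log_t = 0.8 + 0.4 * x + 0.5 * rng.standard_normal(n)
        df = pd.DataFrame({"os_months": np.exp(log_t), "os_event": True, "x": x})
        fit = aft_lognormal_fit(df, ["x"], endpoint="OS")
        slope, intercept, *_ = stats.linregress(x, log_t)
        assert fit.coefficients["x"] == pytest.approx(slope, abs=1e-6)

    def test_fold_change_is_exponentiated_coefficient(self, simulated_records):
        fit = aft_lognormal_fit(
            simulated_records,
            ["tvt_percent", "absorbed_dose_Gy"],
            endpoint="OS",
            increments={"tvt_percent": 10.0, "absorbed_dose_Gy": 100.0},
        )
        fc = fit.fold_changes
        assert fc.loc["tvt_percent", "fold_change"] == pytest.approx(
            math.exp(10.0 * fit.coefficients["tvt_percent"])
        )
        assert fc.loc["absorbed_dose_Gy", "fold_change"] == pytest.approx(
            math.exp(100.0 * fit.coefficients["absorbed_dose_Gy"])
        )
        assert (fc["lo"] <= fc["fold_change"]).all()
        assert (fc["fold_change"] <= fc["hi"]).all()

    def test_fitted_params_are_local_likelihood_maximum(self, simulated_records):
        """The fit maximizes an independently coded right-censored lognormal
        log-likelihood: perturbing any coefficient lowers it."""
        covs = ["tvt_percent", "absorbed_dose_Gy", "age_y"]
        fit = aft_lognormal_fit(simulated_records, covs, endpoint="OS")

        t = simulated_records["os_months"].to_numpy()
        e = simulated_records["os_event"].to_numpy(bool)
        X = simulated_records[covs].to_numpy()

        def loglik(beta, intercept, sigma):
            mu = intercept + X @ beta
            z = (np.log(t) - mu) / sigma
            ll_event = stats.norm.logpdf(z[e]) - np.log(sigma * t[e])
            ll_cens = stats.norm.logsf(z[~e])
            return ll_event.sum() + ll_cens.sum()

        beta_hat = fit.coefficients[covs].to_numpy()
        intercept_hat = float(fit.fitter.params_.loc[("mu_", "Intercept")])
        ll_hat = loglik(beta_hat, intercept_hat, fit.sigma)
        rng = np.random.default_rng(0)
        for _ in range(8):
            delta = rng.normal(scale=0.02, size=beta_hat.size) * (np.abs(beta_hat) + 1e-3)
            assert loglik(beta_hat + delta, intercept_hat, fit.sigma) <= ll_hat + 1e-9

    def test_null_effect_ci_covers_one_at_nominal_rate(self):
        """With a truly null covariate the 95% Wald CI for the fold change
        contains 1 at ~95% over 200 simulated datasets."""
        rng = np.random.default_rng(11)
        covered = 0
        reps = 200
        for _ in range(reps):
            n = 60
            x = rng.normal(size=n)
            t = np.exp(1.0 + 0.8 * rng.standard_normal(n))
            cens = 12.0
            df = pd.DataFrame(
                {"os_months": np.minimum(t, cens), "os_event": t <= cens, "x": x}
            )
            fit = aft_lognormal_fit(df, ["x"], endpoint="OS")
            lo, hi = fit.fold_changes.loc["x", ["lo", "hi"]]
            covered += lo <= 1.0 <= hi
        assert 0.90 <= covered / reps <= 0.99

    def test_too_few_events_rejected(self):
        df = pd.DataFrame(
            {"os_months": [1.0, 2, 3, 4, 5, 6], "os_event": [True] + [False] * 5,
             "x": [0.0, 1, 2, 3, 4, 5]}
        )
        with pytest.raises(ValueError, match="events"):
            aft_lognormal_fit(df, ["x"], endpoint="OS")


class TestCorrelationScreen:
    def test_perfect_correlations(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "up": [2.0, 4, 6, 8], "down": [4.0, 3, 2, 1]})
        out = correlation_screen(df, [("x", "up"), ("x", "down")]).set_index("y")
        assert out.loc["up", "r"] == pytest.approx(1.0)
        assert out.loc["down", "r"] == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        x = np.array([2.0, 4.0, 5.0, 9.0, 11.0])
        y = np.array([1.0, 3.0, 2.0, 8.0, 7.0])
        df = pd.DataFrame({"x": x, "y": y})
        out = correlation_screen(df, [("x", "y")])
        r_direct = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out.loc[0, "r"] == pytest.approx(r_direct, rel=1e-12)
        t_stat = r_direct * math.sqrt(3 / (1 - r_direct**2))
        assert out.loc[0, "p"] == pytest.approx(2 * stats.t.sf(abs(t_stat), df=3), rel=1e-9)

    def test_zero_variance_flagged_not_computed(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        out = correlation_screen(df, [("x", "y")])
        assert math.isnan(out.loc[0, "r"])
        assert out.loc[0, "note"] == "zero variance"

    def test_pairwise_missing_dropped(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, np.nan], "y": [2.0, 4, 7, 9]})
        out = correlation_screen(df, [("x", "y")])
        assert out.loc[0, "n"] == 3


def _records_from_counts() -> pd.DataFrame:
    rows = []
    for cohort, row in tt.BEST_RESPONSE_COUNTS.iterrows():
        for cat, k in row.items():
            rows += [{"cohort": cohort, "best_response": cat}] * int(k)
    return pd.DataFrame(rows)


class TestResponseTable:
    def test_published_counts_reproduce_summary(self):
        out = response_table(_records_from_counts())
        assert out["n"] == 21
        assert out["overall_counts"]["SD"] == 12
        assert out["overall_percent"]["SD"] == 57.1
        assert out["overall_percent"]["PD"] == 38.1
        assert out["orr_percent"] == 4.8  # one PR of 21

    def test_all_progressive_zero_orr(self):
        df = pd.DataFrame({"cohort": [1] * 4, "best_response": ["PD"] * 4})
        assert response_table(df)["orr_percent"] == 0.0

    def test_unknown_category_rejected(self):
        df = pd.DataFrame({"cohort": [1], "best_response": ["MR"]})
        with pytest.raises(ValueError, match="unknown best-response"):
            response_table(df)


class TestCohortSummary:
    def test_pooled_age_from_published_cohort_means(self):
        ages = tt.COHORT_AGE_STATS
        pooled = pooled_mean(ages["mean_y"], ages["n"])
        assert round(pooled, 1) == 53.1

    def test_pooled_mean_invariant_to_ordering(self):
        means, ns = [52.0, 60.0, 49.3], [3, 6, 12]
        assert pooled_mean(means, ns) == pytest.approx(pooled_mean(means[::-1], ns[::-1]))

    def test_single_cohort_pooled_equals_cohort(self):
        df = pd.DataFrame(
            {"cohort": [1, 1, 1], "age_y": [40.0, 50.0, 60.0], "baseline_tumor_mL": [1.0, 2.0, 3.0],
             "ecog": [0, 1, 2]}
        )
        out = cohort_summary(df)
        assert out["continuous"]["age_y"]["pooled"]["mean"] == pytest.approx(50.0)
        assert out["continuous"]["age_y"]["by_cohort"].loc[1, "mean"] == pytest.approx(50.0)

    def test_summary_on_simulated_cohort(self, simulated_records):
        simulated_records = simulated_records.assign(cohort=1 + np.arange(len(simulated_records)) % 6)
        out = cohort_summary(simulated_records)
        weighted = pooled_mean(
            out["continuous"]["age_y"]["by_cohort"]["mean"],
            out["continuous"]["age_y"]["by_cohort"]["n"],
        )
        assert weighted == pytest.approx(out["continuous"]["age_y"]["pooled"]["mean"])
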