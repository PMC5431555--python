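import numpy as np
import pandas as pd
import pytest

from petradiomics.association import (
    ContingencyTable2x2,
    DegenerateOutcomeError,
    cox_fit,
    km_logrank,
    logistic_fit,
    odds_ratio_2x2,
    proportions_test,
)


class TestOddsRatio2x2:
    def test_published_tc2_vs_others_table(self):
        """Counts reconstructed from cluster sizes (10, 25, 37) and pCR
        rates (20.0%, 48.0%, 5.4%)."""
        res = odds_ratio_2x2(ContingencyTable2x2(a=12, b=13, c=4, d=43))
        assert res.odds_ratio == pytest.approx(9.923, abs=5e-4)
        assert res.ci_low == pytest.approx(2.730, abs=5e-4)
        assert res.ci_high == pytest.approx(36.066, abs=5e-4)
        assert res.p_value < 0.001
        assert res.method == "2x2"

    def test_published_tc2_vs_tc3_table(self):
        res = odds_ratio_2x2(ContingencyTable2x2(a=12, b=13, c=2, d=35))
        assert res.odds_ratio == pytest.approx(16.154, abs=5e-4)

    def test_unit_table(self):
        res = odds_ratio_2x2(ContingencyTable2x2(a=1, b=1, c=1, d=1))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_takes_continuity_correction(self):
        res = odds_ratio_2x2(ContingencyTable2x2(a=5, b=0, c=3, d=7))
        assert res.method == "2x2+0.5"
        assert np.isfinite(res.odds_ratio)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio_2x2(ContingencyTable2x2(a=0, b=0, c=3, d=7))


class TestLogisticFit:
    def _cohort_from_table(self, a, b, c, d):
        return pd.DataFrame(
            {
                "x": [1] * (a + b) + [0] * (c + d),
                "pcr": [1] * a + [0] * b + [1] * c + [0] * d,
            }
        )

    @pytest.mark.parametrize("table", [(12, 13, 4, 43), (5, 9, 3, 14), (2, 8, 2, 35)])
    def test_single_binary_covariate_matches_closed_form(self, table):
        cohort = self._cohort_from_table(*table)
        closed = odds_ratio_2x2(ContingencyTable2x2(*table))
        fit = logistic_fit(cohort, outcome="pcr", covariates=["x"])[0]
        assert fit.odds_ratio == pytest.approx(closed.odds_ratio, abs=1e-6)
        assert fit.method == "logistic"

    def test_constant_outcome_rejected(self):
        cohort = pd.DataFrame({"x": [0, 1, 0, 1], "pcr": [1, 1, 1, 1]})
        with pytest.raises(DegenerateOutcomeError):
            logistic_fit(cohort, covariates=["x"])

    def test_complete_separation_flagged(self):
        cohort = pd.DataFrame({"x": [0] * 10 + [1] * 10, "pcr": [0] * 10 + [1] * 10})
        fit = logistic_fit(cohort, covariates=["x"])[0]
        assert fit.method == "logistic:separation"

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(0)
        ors = []
        for _ in range(50):
            cohort = pd.DataFrame(
                {"x": rng.integers(0, 2, 200), "pcr": rng.integers(0, 2, 200)}
            )
            ors.append(logistic_fit(cohort, covariates=["x"])[0].odds_ratio)
        assert np.mean(np.log(ors)) == pytest.approx(0.0, abs=0.1)

    def test_multivariate_mode_returns_joint_model(self):
        rng = np.random.default_rng(1)
        n = 300
        x1 = rng.integers(0, 2, n)
        x2 = rng.integers(0, 2, n)
        logit = -1.0 + 1.2 * x1 + 0.5 * x2
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        cohort = pd.DataFrame({"x1": x1, "x2": x2, "pcr": y.astype(int)})
        fits = logistic_fit(cohort, covariates=["x1", "x2"], mode="multivariate")
        assert [f.term for f in fits] == ["x1", "x2"]
        assert fits[0].odds_ratio == pytest.approx(np.exp(1.2), rel=0.5)


class TestProportionsTest:
    def test_identical_proportions_zero_statistic(self):
        cohort = pd.DataFrame(
            {"cluster": [1] * 10 + [2] * 10, "trait": [0, 1] * 10}
        )
        res = proportions_test(cohort, group="cluster", trait="trait")
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_2x2_statistic(self):
        cohort = pd.DataFrame(
            {
                "cluster": [1] * 20 + [2] * 20,
                "trait": [1] * 10 + [0] * 10 + [1] * 20,
            }
        )
        res = proportions_test(cohort, group="cluster", trait="trait")
        assert res.statistic == pytest.approx(40 * (10 * 0 - 10 * 20) ** 2 / (20 * 20 * 30 * 10))
        assert res.df == 1

    def test_ki67_like_counts_significant(self):
        rows = (
            [(1, 1)] * 8 + [(1, 0)] * 2
            + [(2, 1)] * 16 + [(2, 0)] * 9
            + [(3, 1)] * 12 + [(3, 0)] * 25
        )
        cohort = pd.DataFrame(rows, columns=["cluster", "ki67_high"])
        res = proportions_test(cohort, group="cluster", trait="ki67_high")
        assert res.p_value < 0.013  # the per-table Bonferroni threshold


class TestSurvival:
    def test_no_events_explicit_result(self):
        cohort = pd.DataFrame(
            {"cluster": [1, 1, 2, 2], "dfs_months": [10.0, 20, 15, 25], "event": 0}
        )
        fit = km_logrank(cohort)
        assert fit.logrank_p is None
        assert "no events" in fit.note
        for km in fit.curves.values():
            assert np.all(km.survival_function_.to_numpy() == 1.0)

    def test_hand_computed_product_limit(self):
        cohort = pd.DataFrame(
            {"cluster": 1, "dfs_months": [5.0, 10.0, 15.0, 20.0], "event": 1}
        )
        fit = km_logrank(cohort)
        km = fit.curves[1]
        assert km.predict(4.9) == pytest.approx(1.0)
        assert km.predict(5.0) == pytest.approx(0.75)
        assert km.predict(10.0) == pytest.approx(0.50)
        assert km.predict(20.0) == pytest.approx(0.0)

    def test_km_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(20, size=40)
        cohort = pd.DataFrame({"cluster": 1, "dfs_months": times, "event": 1})
        km = km_logrank(cohort).curves[1]
        for t in np.percentile(times, [10, 50, 90]):
            assert km.predict(t) == pytest.approx((times > t).mean(), abs=1e-10)

    def test_strong_group_difference_detected(self):
        rng = np.random.default_rng(4)
        n = 100
        t1 = rng.exponential(10, n)
        t2 = rng.exponential(50, n)
        cohort = pd.DataFrame(
            {
                "cluster": [1] * n + [2] * n,
                "dfs_months": np.concatenate([t1, t2]),
                "event": 1,
            }
        )
        fit = km_logrank(cohort)
        assert fit.logrank_p < 1e-6


class TestCox:
    def test_zero_events_rejected(self):
        cohort = pd.DataFrame({"x": [0, 1], "dfs_months": [5.0, 6.0], "event": [0, 0]})
        with pytest.raises(DegenerateOutcomeError):
            cox_fit(cohort, ["x"])

    def test_two_group_exponential_hr_matches_rate_ratio(self):
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.integers(0, 2, n)
        lam = np.where(x == 1, 0.05, 0.01)
        cohort = pd.DataFrame(
            {"x": x, "dfs_months": rng.exponential(1 / lam), "event": 1}
        )
        hr = cox_fit(cohort, ["x"])[0]
        assert hr.hazard_ratio == pytest.approx(5.0, rel=0.15)
        assert not hr.flagged

    def test_no_event_stratum_flagged(self):
        rng = np.random.default_rng(6)
        n = 60
        x = np.repeat([0, 1], n // 2)
        t = rng.exponential(20, n)
        event = np.where(x == 1, 0, (t < 30).astype(int))  # no events in x=1
        cohort = pd.DataFrame({"x": x, "dfs_months": t, "event": event})
        hr = cox_fit(cohort, ["x"])[0]
        assert hr.flagged
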