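"""Survival engine: KM product limit, log-rank (+ permutation oracle),
log-rank trend, Cox regression, and group-association tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnahet.io_formats import PatientRecord
from cnahet.survival import (
    cox_fit,
    eligible,
    group_association_tests,
    km_estimate,
    logrank,
    logrank_trend,
    stratified_analysis,
    survival_frame,
)


def _logrank_statistic(times, events, groups):
    """Independent two-group log-rank chi-square, for the permutation null."""
    o = e = v = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & groups).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & groups).sum()
        if n <= 1:
            continue
        o += d1
        e += d * n1 / n
        v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v if v > 0 else 0.0


class TestEligibility:
    def _cohort(self, n_msi, n_r2, n_ok):
        recs = []
        for i in range(n_msi):
            recs.append(PatientRecord(f"M{i}", msi_status="MSI", r_status="R0"))
        for i in range(n_r2):
            recs.append(PatientRecord(f"R{i}", msi_status="MSS", r_status="R2"))
        for i in range(n_ok):
            recs.append(PatientRecord(f"K{i}", msi_status="MSS", r_status="R0"))
        return recs

    def test_msi_and_r2_removed_with_counts(self):
        kept, counts = eligible(self._cohort(1, 5, 165))
        assert len(kept) == 165
        assert counts == {"excluded_msi": 1, "excluded_r2": 5, "retained": 165}

    def test_fully_eligible_cohort_unchanged(self):
        kept, _ = eligible(self._cohort(0, 0, 10))
        assert len(kept) == 10

    def test_empty_cohort(self):
        kept, _ = eligible([])
        assert kept == []


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([10, 20, 30], [True, True, True])
        assert km.survival_at(10) == pytest.approx(2 / 3)
        assert km.survival_at(20) == pytest.approx(1 / 3)
        assert km.survival_at(30) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        km = km_estimate([10, 20, 30], [False, False, False])
        assert np.all(km.survival == 1.0)
        assert km.five_year_css == 1.0

    def test_textbook_censored_toy_product_limit(self):
        # events at 6 (3 of them) and 10; censored at 6+ and 9+
        # S(6) = 1 * (21-3)/21 with the classic 21-subject toy reduced:
        # use the canonical 6-subject example: times 1,2+,3,4+,5,6
        times = [1, 2, 3, 4, 5, 6]
        events = [True, False, True, False, True, True]
        km = km_estimate(times, events)
        # hand product-limit: S(1)=5/6; S(3)=5/6*3/4; S(5)=5/6*3/4*1/2; S(6)=0
        assert km.survival_at(1) == pytest.approx(5 / 6)
        assert km.survival_at(3) == pytest.approx(5 / 6 * 3 / 4)
        assert km.survival_at(5) == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)
        assert km.survival_at(6) == pytest.approx(0.0)

    def test_five_year_css_invariant_to_later_events(self):
        base = km_estimate([10, 40, 59, 80, 90], [True, True, True, True, True])
        moved = km_estimate([10, 40, 59, 70, 100], [True, True, True, True, True])
        assert base.five_year_css == pytest.approx(moved.five_year_css)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [5, 10, 15, 20]
        e = [True, True, False, True]
        res = logrank(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_early_vs_late_events_positive_statistic(self):
        res = logrank([1, 2, 3], [True] * 3, [10, 11, 12], [True] * 3)
        assert res.statistic > 0
        assert res.p_value < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], [], [1], [True])

    def test_p_matches_permutation_null_on_toy(self, rng):
        """Chi-square p agrees with a permutation null within MC error."""
        n = 20
        times = rng.exponential(20, n)
        events = rng.random(n) < 0.8
        groups = np.arange(n) < 10
        obs = _logrank_statistic(times, events, groups)
        draws = 2000
        perm = np.empty(draws)
        for b in range(draws):
            perm[b] = _logrank_statistic(times, events, rng.permutation(groups))
        p_perm = (perm >= obs - 1e-12).mean()
        res = logrank(times[groups], events[groups], times[~groups], events[~groups])
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / draws)
        assert abs(res.p_value - p_perm) < max(0.05, mc_err)


class TestLogrankTrend:
    def test_identical_groups_statistic_zero(self):
        t = np.tile([5.0, 10.0, 15.0, 20.0], 3)
        e = np.tile([True, True, False, True], 3)
        scores = np.repeat([1.0, 2.0, 3.0], 4)
        res = logrank_trend(t, e, scores)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_order_reversal_flips_sign_same_p(self, rng):
        n = 60
        scores = rng.integers(1, 4, n).astype(float)
        times = rng.exponential(30 / scores)
        events = np.ones(n, bool)
        fwd = logrank_trend(times, events, scores)
        rev = logrank_trend(times, events, 4 - scores)
        assert fwd.z == pytest.approx(-rev.z)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_two_groups_reduces_to_logrank(self, rng):
        n = 40
        groups = np.arange(n) < 20
        times = rng.exponential(np.where(groups, 10, 30))
        events = rng.random(n) < 0.9
        trend = logrank_trend(times, events, groups.astype(float) + 1)
        lr = logrank(times[groups], events[groups], times[~groups], events[~groups])
        assert trend.statistic == pytest.approx(lr.statistic, rel=1e-6)

    def test_monotone_hazard_gradient_detected(self, rng):
        n_per = 40
        scores = np.repeat([1.0, 2.0, 3.0], n_per)
        times = rng.exponential(60 / scores**2)
        events = np.ones(len(times), bool)
        res = logrank_trend(times, events, scores)
        assert res.p_value < 0.01
        assert res.z > 0  # higher score, more deaths: positive contrast


class TestCox:
    def test_null_covariate_recovers_zero_log_hr(self, rng):
        n = 400
        x = rng.random(n) < 0.5
        df = pd.DataFrame(
            {"time": rng.exponential(30, n), "event": True, "x": x.astype(float)}
        )
        res = cox_fit(df, ["x"], mode="multivariable")
        assert res.converged
        row = res.table.loc["x"]
        assert row.ci_low < 1.0 < row.ci_high

    def test_direction_agrees_with_logrank(self, rng):
        n = 200
        x = np.arange(n) < 100
        times = rng.exponential(np.where(x, 10, 40))
        df = pd.DataFrame({"time": times, "event": True, "x": x.astype(float)})
        res = cox_fit(df, ["x"], mode="multivariable")
        assert res.table.loc["x", "hr"] > 1  # x=1 dies faster
        lr = logrank(times[x], np.ones(100, bool), times[~x], np.ones(100, bool))
        assert lr.p_value < 0.05

    def test_constant_covariate_fails_gracefully(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": True, "x": 1.0})
        res = cox_fit(df, ["x"], mode="multivariable")
        assert not res.converged
        assert "constant" in res.warnings[0]

    def test_univariable_mode_returns_one_fit_per_covariate(self, rng):
        n = 100
        df = pd.DataFrame(
            {
                "time": rng.exponential(20, n),
                "event": True,
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
            }
        )
        fits = cox_fit(df, ["a", "b"], mode="univariable")
        assert len(fits) == 2
        assert all(len(f.table) == 1 for f in fits)


class TestGroupAssociation:
    def test_extreme_2x2_table_fisher(self):
        values = pd.Series(["a"] * 10 + ["b"] * 10)
        grouping = pd.Series(["g1"] * 10 + ["g2"] * 10)
        res = group_association_tests(values, grouping, kind="categorical")
        assert res.p_value < 0.001

    def test_identical_continuous_distributions_not_significant(self, rng):
        x = pd.Series(np.tile(rng.normal(size=50), 2))
        g = pd.Series(["a"] * 50 + ["b"] * 50)
        res = group_association_tests(x, g, kind="continuous")
        assert res.p_value > 0.9  # identical samples

    def test_constant_variable_undefined(self):
        x = pd.Series([1.0] * 10)
        g = pd.Series(["a"] * 5 + ["b"] * 5)
        res = group_association_tests(x, g, kind="continuous")
        assert np.isnan(res.p_value)


class TestStratifiedAnalysis:
    def _frame(self, rng, hazards):
        rows = []
        strata = []
        for i, (label, lam) in enumerate(hazards):
            n = 60
            t = rng.exponential(1 / lam, n)
            for j in range(n):
                rows.append({"time": t[j], "event": True})
                strata.append((f"s{i}_{j}", label))
        idx = [k for k, _ in strata]
        frame = pd.DataFrame(rows, index=idx)
        return frame, pd.Series(dict(strata))

    def test_three_ordered_strata_use_trend_test(self, rng):
        frame, strata = self._frame(
            rng, [("co_mut_high", 0.08), ("co_mut_low", 0.04), ("no_co_mut", 0.01)]
        )
        res = stratified_analysis(
            frame, strata, ["co_mut_high", "co_mut_low", "no_co_mut"],
            reference="no_co_mut",
        )
        assert res.test_kind == "logrank_trend"
        assert res.test.p_value < 0.01
        assert res.cox.converged
        assert res.cox.table.loc["co_mut_high", "hr"] > 1

    def test_reference_relabelling_reciprocates_hr(self, rng):
        frame, strata = self._frame(rng, [("a", 0.05), ("b", 0.02)])
        r1 = stratified_analysis(frame, strata, ["a", "b"], reference="b")
        r2 = stratified_analysis(frame, strata, ["a", "b"], reference="a")
        assert r1.test.p_value == pytest.approx(r2.test.p_value)
        hr_a = r1.cox.table.loc["a", "hr"]
        hr_b = r2.cox.table.loc["b", "hr"]
        assert hr_a == pytest.approx(1 / hr_b, rel=1e-4)

    def test_stratum_without_events_flagged(self, rng):
        frame = pd.DataFrame(
            {
                "time": np.r_[rng.exponential(10, 20), np.full(20, 50.0)],
                "event": np.r_[np.ones(20, bool), np.zeros(20, bool)],
            },
            index=[f"p{i}" for i in range(40)],
        )
        strata = pd.Series(
            ["a"] * 20 + ["b"] * 20, index=frame.index
        )
        res = stratified_analysis(frame, strata, ["a", "b"])
        assert any("no events" in f for f in res.flags)


class TestSurvivalFrame:
    def test_event_coding_and_censoring(self):
        recs = [
            PatientRecord("P1", followup_months=24, event="CRC death"),
            PatientRecord("P2", followup_months=36, event="other death"),
            PatientRecord("P3", followup_months=60, event="alive"),
        ]
        frame = survival_frame(recs)
        assert frame.loc["P1", "event"] == True  # noqa: E712
        assert frame.loc["P2", "event"] == False  # other-cause death censored
        assert frame.loc["P3", "event"] == False
        assert frame.loc["P2", "time"] == 36
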