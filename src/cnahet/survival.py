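"""Cancer-specific survival analysis conventions for the cohort.

End point is 5-year cancer-specific survival (5y-CSS): time runs from
start of treatment, deaths from other causes are censored at the death
time, and survival analyses include only patients with microsatellite-
stable tumors and R0/R1 resection status.  Kaplan-Meier estimation,
two-group log-rank tests and Cox regression are delegated to lifelines
(Efron tie handling); the 1-df log-rank trend test over >= 3 ordered
groups is implemented here, since it is the one piece the standard
Python survival stack does not ship.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

from .io_formats import PatientRecord

logger = logging.getLogger(__name__)

FIVE_YEARS_MONTHS = 60.0


@dataclass
class KMResult:
    """Kaplan-Meier step function with the 5-year survival read-out."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    five_year_css: float

    def survival_at(self, t: float) -> float:
        """Step-function value at time t (last value carried forward)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: int = 1
    z: float | None = None  # signed, for trend tests


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald confidence intervals."""

    table: pd.DataFrame  # columns: hr, ci_low, ci_high, p, coef, se
    converged: bool
    n: int
    n_events: int
    warnings: list[str] = field(default_factory=list)


def survival_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Build the (time, event) analysis frame from patient records.

    ``event`` is True for CRC deaths within follow-up; other-cause
    deaths and living patients are censored at their follow-up time.
    """
    rows = []
    for rec in records:
        if rec.followup_months is None or rec.event is None:
            continue
        rows.append(
            {
                "patient_id": rec.patient_id,
                "time": rec.followup_months,
                "event": rec.event == "CRC death",
                "msi_status": rec.msi_status,
                "r_status": rec.r_status,
                "extrahepatic_disease": rec.extrahepatic_disease,
                **rec.covariates,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def eligible(records: Sequence[PatientRecord]) -> tuple[list[PatientRecord], dict]:
    """Apply the survival-eligibility filter: MSS tumors, R0/R1 status.

    Returns the retained records and the exclusion counts.
    """
    kept = []
    n_msi = n_r2 = 0
    for rec in records:
        if rec.msi_status == "MSI":
            n_msi += 1
            continue
        if rec.r_status == "R2":
            n_r2 += 1
            continue
        kept.append(rec)
    counts = {"excluded_msi": n_msi, "excluded_r2": n_r2, "retained": len(kept)}
    logger.info("eligibility filter: %s", counts)
    return kept, counts


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMResult:
    """Product-limit survival estimate; 5y-CSS is the value at 60 months."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = kmf.survival_function_
    t = grid.index.to_numpy(dtype=float)
    s = grid.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(grid.index).to_numpy(dtype=float)
    )
    result = KMResult(times=t, survival=s, at_risk=at_risk, five_year_css=np.nan)
    result.five_year_css = result.survival_at(FIVE_YEARS_MONTHS)
    return result


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> TestResult:
    """Two-group log-rank test (chi-square, 1 df)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(float(res.test_statistic), float(res.p_value), df=1)


def _group_event_tables(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed events, expectations and covariance for k-group log-rank.

    Standard Mantel-Haenszel accumulation over distinct event times:
    at each event time t with d_t total deaths among n_t at risk,
    group g contributes expectation d_t * n_gt / n_t, and the
    covariance matrix accumulates the multivariate hypergeometric term.
    """
    labels = np.unique(groups)
    k = len(labels)
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_t = at_risk.sum()
        dying = events & (times == t)
        d_t = dying.sum()
        if n_t <= 1 or d_t == 0:
            continue
        n_gt = np.array([(at_risk & (groups == g)).sum() for g in labels], float)
        d_gt = np.array([(dying & (groups == g)).sum() for g in labels], float)
        p = n_gt / n_t
        observed += d_gt
        expected += d_t * p
        hyper = d_t * (n_t - d_t) / (n_t - 1)
        cov += hyper * (np.diag(p) - np.outer(p, p))
    return observed, expected, cov


def logrank_trend(
    times: Sequence[float],
    events: Sequence[bool],
    group_scores: Sequence[float],
) -> TestResult:
    """Log-rank test for trend across ordered groups (1 df).

    Groups are identified by their scores (equally spaced 1..k in the
    usual usage).  The statistic contrasts observed-minus-expected
    event counts weighted by the group scores; its sign follows the
    score ordering, and the chi-square is the squared standardized
    contrast.  With two groups this reduces to the ordinary log-rank.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    scores = np.asarray(group_scores, float)
    labels = np.unique(scores)
    if len(labels) < 2:
        raise ValueError("need >= 2 distinct groups")
    observed, expected, cov = _group_event_tables(times, events, scores)
    c = labels  # score vector per group
    u = float(c @ (observed - expected))
    var = float(c @ cov @ c)
    if var <= 0:
        return TestResult(0.0, 1.0, df=1, z=0.0)
    z = u / np.sqrt(var)
    chi2 = z * z
    return TestResult(chi2, float(stats.chi2.sf(chi2, 1)), df=1, z=float(z))


def cox_fit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    mode: str = "multivariable",
) -> CoxResult | list[CoxResult]:
    """Cox proportional-hazards regression (Efron tie handling).

    ``mode='univariable'`` fits one single-covariate model per listed
    covariate and returns a list; ``'multivariable'`` fits them jointly.
    Non-convergence is reported as a failed fit, never raised.
    """
    if mode == "univariable":
        return [
            _cox_single(data, [c], duration_col, event_col) for c in covariates
        ]
    if mode != "multivariable":
        raise ValueError(f"unknown mode {mode!r}")
    return _cox_single(data, list(covariates), duration_col, event_col)


def _cox_single(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str,
    event_col: str,
) -> CoxResult:
    sub = data[[duration_col, event_col] + covariates].dropna()
    for c in covariates:
        if sub[c].nunique() <= 1:
            return CoxResult(
                table=pd.DataFrame(),
                converged=False,
                n=len(sub),
                n_events=int(sub[event_col].sum()),
                warnings=[f"covariate {c} is constant"],
            )
    cph = CoxPHFitter()
    caught: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            cph.fit(sub, duration_col=duration_col, event_col=event_col)
            caught = [str(w.message) for w in wlist]
    except ConvergenceError as exc:
        return CoxResult(
            table=pd.DataFrame(),
            converged=False,
            n=len(sub),
            n_events=int(sub[event_col].sum()),
            warnings=[f"convergence failure: {exc}"],
        )
    summary = cph.summary
    table = pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
            "coef": summary["coef"],
            "se": summary["se(coef)"],
        }
    )
    separation = [w for w in caught if "complete separation" in w.lower()]
    return CoxResult(
        table=table,
        converged=True,
        n=len(sub),
        n_events=int(sub[event_col].sum()),
        warnings=separation,
    )


def group_association_tests(
    values: pd.Series, grouping: pd.Series, kind: str
) -> TestResult:
    """Two-group association tests used alongside the survival models.

    ``kind='continuous'`` runs a Wilcoxon rank-sum (Mann-Whitney) test;
    ``kind='categorical'`` runs Fisher's exact test on the 2x2 table
    (larger tables fall back to the chi-square test).  P values are
    never adjusted for multiple testing.
    """
    mask = values.notna() & grouping.notna()
    values, grouping = values[mask], grouping[mask]
    levels = grouping.unique()
    if len(levels) != 2:
        raise ValueError("grouping must have exactly two levels")
    if kind == "continuous":
        a = values[grouping == levels[0]]
        b = values[grouping == levels[1]]
        if a.nunique() <= 1 and b.nunique() <= 1 and set(a) == set(b):
            return TestResult(np.nan, np.nan, df=0)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult(float(stat), float(p))
    if kind == "categorical":
        table = pd.crosstab(values, grouping)
        if table.size == 0 or (table.sum(axis=1) == 0).any():
            return TestResult(np.nan, np.nan, df=0)
        if table.shape == (2, 2):
            _, p = stats.fisher_exact(table.to_numpy())
            return TestResult(np.nan, float(p))
        chi2, p, df, _ = stats.chi2_contingency(table.to_numpy())
        return TestResult(float(chi2), float(p), df=int(df))
    raise ValueError(f"unknown kind {kind!r}")


@dataclass
class StratifiedResult:
    km_per_stratum: dict[str, KMResult]
    test: TestResult
    test_kind: str  # "logrank" | "logrank_trend"
    cox: CoxResult
    flags: list[str] = field(default_factory=list)


def stratified_analysis(
    data: pd.DataFrame,
    strata: pd.Series,
    ordered_levels: Sequence[str],
    reference: str | None = None,
    duration_col: str = "time",
    event_col: str = "event",
) -> StratifiedResult:
    """KM + log-rank (2 strata) or log-rank trend (>= 3 ordered strata),
    plus univariable Cox with dummy coding against a reference stratum.

    ``ordered_levels`` fixes both the trend scores (1..k in that order)
    and the display order; ``reference`` defaults to the last level.
    """
    data = data.loc[strata.index]
    times = data[duration_col].to_numpy(float)
    events = data[event_col].to_numpy(bool)
    levels = [lv for lv in ordered_levels if (strata == lv).any()]
    if len(levels) < 2:
        raise ValueError("need >= 2 non-empty strata")
    flags = []
    km = {}
    for lv in levels:
        mask = (strata == lv).to_numpy()
        km[lv] = km_estimate(times[mask], events[mask])
        if events[mask].sum() == 0:
            flags.append(f"stratum {lv!r} has no events")

    if len(levels) == 2:
        m = (strata == levels[0]).to_numpy()
        test = logrank(times[m], events[m], times[~m], events[~m])
        kind = "logrank"
    else:
        score_of = {lv: i + 1 for i, lv in enumerate(levels)}
        test = logrank_trend(times, events, strata.map(score_of).to_numpy(float))
        kind = "logrank_trend"

    reference = reference if reference is not None else levels[-1]
    dummies = pd.get_dummies(strata).reindex(columns=levels).drop(columns=reference)
    dummies = dummies.astype(float)
    cox_data = pd.concat(
        [data[[duration_col, event_col]], dummies], axis=1
    )
    cox = _cox_single(cox_data, list(dummies.columns), duration_col, event_col)
    return StratifiedResult(
        km_per_stratum=km, test=test, test_kind=kind, cox=cox, flags=flags
    )
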