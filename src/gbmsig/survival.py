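"""Kaplan-Meier estimation, log-rank comparison and Cox independence tests.

Risk groups from the prognostic index are compared by the product-limit
(Kaplan-Meier) estimator with Greenwood-based pointwise intervals, the
two-group log-rank test, and a binary-covariate Cox hazard ratio; subtype
strata are analyzed one by one, and a univariate-plus-joint Cox report
checks whether the prognostic group predicts survival independently of age
and MGMT promoter methylation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times

from .cox import CoxFit, CoxFitError, cox_fit_table


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve with Greenwood 95% bounds.

    ``median`` is the smallest time with survival <= 0.5 (inf when the curve
    never reaches it); the median CI comes from inverting the pointwise
    log(-log) confidence band (Brookmeyer-Crowley style), with open ends
    reported as inf.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "at_risk": self.at_risk,
            "survival": self.survival,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        })


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p: float
    observed: dict[str, float]
    expected: dict[str, float]


@dataclass(frozen=True)
class StratumResult:
    stratum: str
    km_low: "KMCurve"
    km_high: "KMCurve"
    log_rank: LogRankResult
    median_low: float
    median_high: float


@dataclass(frozen=True)
class MultivariateReport:
    """Univariate and joint Cox fits for risk group, age and MGMT status."""

    univariate: dict[str, CoxFit]
    joint: dict[str, CoxFit]
    n: int
    n_events: int


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan-Meier estimate with 95% log(-log) pointwise intervals."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(t) == 0:
        raise ValueError("need at least one observation")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(t, e)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    ci = kmf.confidence_interval_
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(ci)
    return KMCurve(
        event_times=timeline,
        survival=surv,
        at_risk=at_risk,
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        median=median,
        median_ci=(float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])),
        n=len(t),
        n_events=int(e.sum()),
    )


def _observed_expected(t, e, labels, level) -> tuple[float, float]:
    obs = float(np.sum(e[labels == level]))
    exp = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        d = float(np.sum(e[t == ti]))
        n_i = float(np.sum(at_risk))
        n_g = float(np.sum(at_risk & (labels == level)))
        exp += d * n_g / n_i
    return obs, exp


def log_rank(time, event, group) -> LogRankResult:
    """Two-group log-rank test: chi-square = (O - E)^2 / V on 1 df."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {list(levels)}")
    if e.sum() < 1:
        raise ValueError("log-rank test undefined with no events")
    mask = g == levels[0]
    res = logrank_test(t[mask], t[~mask], e[mask], e[~mask])
    observed, expected = {}, {}
    for level in levels:
        observed[str(level)], expected[str(level)] = _observed_expected(
            t, e, g, level)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=1,
        p=float(res.p_value),
        observed=observed,
        expected=expected,
    )


def group_hazard_ratio(time, event, group,
                       reference: str = "low") -> CoxFit:
    """Cox PH hazard ratio of the non-reference vs the reference group."""
    g = pd.Series(np.asarray(group))
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among groups {levels}")
    df = pd.DataFrame({
        "high_risk": (g != reference).astype(int).to_numpy(),
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event, dtype=int),
    })
    return cox_fit_table(df, "time", "event")["high_risk"]


def stratified_survival(
    clinical: pd.DataFrame,
    risk_group: pd.Series,
    stratum_column: str = "subtype",
    time_col: str = "pfs_days",
    event_col: str = "pfs_event",
) -> tuple[list[StratumResult], list[str]]:
    """KM + log-rank per stratum; strata lacking both risk groups (or any
    event) are reported as skipped rather than failing the run."""
    samples = clinical.index.intersection(risk_group.index)
    clin = clinical.loc[samples]
    risk = risk_group.loc[samples]
    results: list[StratumResult] = []
    skipped: list[str] = []
    for stratum, sub in clin.groupby(stratum_column, sort=True):
        r = risk.loc[sub.index]
        if r.nunique() < 2 or sub[event_col].sum() < 1:
            skipped.append(str(stratum))
            continue
        low, high = sub[r == "low"], sub[r == "high"]
        km_low = kaplan_meier(low[time_col], low[event_col])
        km_high = kaplan_meier(high[time_col], high[event_col])
        lr = log_rank(sub[time_col], sub[event_col], r)
        results.append(StratumResult(
            stratum=str(stratum), km_low=km_low, km_high=km_high,
            log_rank=lr, median_low=km_low.median, median_high=km_high.median))
    if not results:
        raise ValueError("no stratum with both risk groups and >= 1 event")
    return results, skipped


def multivariate_independence(
    clinical: pd.DataFrame,
    risk_group: pd.Series,
    time_col: str = "pfs_days",
    event_col: str = "pfs_event",
    age_col: str = "age",
    mgmt_col: str = "mgmt_methylated",
) -> MultivariateReport:
    """Univariate fits plus one joint Cox model on risk, age and MGMT.

    Risk is coded 1 for high (low-risk reference); MGMT is coded 1 for
    unmethylated (methylated reference); age is continuous. Complete cases
    only; the counts are reported.
    """
    samples = clinical.index.intersection(risk_group.index)
    sub = clinical.loc[samples, [time_col, event_col, age_col, mgmt_col]].dropna()
    if len(sub) == 0 or sub[event_col].sum() < 2:
        raise CoxFitError(
            f"degenerate complete-case subset: n={len(sub)}, "
            f"events={int(sub[event_col].sum()) if len(sub) else 0}")
    design = pd.DataFrame({
        "high_risk": (risk_group.loc[sub.index] == "high").astype(int),
        "age": sub[age_col].astype(float),
        "mgmt_unmethylated": (1 - sub[mgmt_col].astype(int)),
        "time": sub[time_col].astype(float),
        "event": sub[event_col].astype(int),
    })
    univariate = {}
    for var in ("high_risk", "age", "mgmt_unmethylated"):
        univariate[var] = cox_fit_table(
            design[[var, "time", "event"]], "time", "event")[var]
    joint = cox_fit_table(design, "time", "event")
    return MultivariateReport(
        univariate=univariate,
        joint=joint,
        n=len(design),
        n_events=int(design["event"].sum()),
    )


def compare_risk_groups(
    clinical: pd.DataFrame,
    risk_group: pd.Series,
    time_col: str,
    event_col: str,
) -> dict:
    """Full two-group comparison: KM pair, medians with CI, log-rank, HR."""
    samples = clinical.index.intersection(risk_group.index)
    clin = clinical.loc[samples]
    risk = risk_group.loc[samples]
    low, high = clin[risk == "low"], clin[risk == "high"]
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both risk groups must be non-empty")
    km_low = kaplan_meier(low[time_col], low[event_col])
    km_high = kaplan_meier(high[time_col], high[event_col])
    lr = log_rank(clin[time_col], clin[event_col], risk)
    hr = group_hazard_ratio(clin[time_col], clin[event_col], risk)
    return {
        "km_low": km_low,
        "km_high": km_high,
        "median_low": km_low.median,
        "median_low_ci": km_low.median_ci,
        "median_high": km_high.median,
        "median_high_ci": km_high.median_ci,
        "log_rank": lr,
        "hazard_ratio": hr,
    }
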