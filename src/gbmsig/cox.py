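"""Prognostic-index model: per-gene Cox coefficients, PI scoring, risk groups.

The signature genes get log-hazard coefficients (beta) from univariate Cox
proportional-hazards fits on patients held out from feature selection. The
prognostic index of a sample is the linear score PI = sum(beta_g * x_g); the
median PI (or an explicit threshold) splits patients into low- and high-risk
groups. A frozen model can be transferred to an external cohort, optionally
after per-gene z-scaling to absorb platform location/scale differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError


class CoxFitError(ValueError):
    """The requested Cox fit is ill-posed (too few events, constant covariate)."""


@dataclass(frozen=True)
class CoxFit:
    beta: float
    se: float
    hr: float
    p_wald: float
    n: int
    n_events: int

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        return math.exp(self.beta - z * self.se), math.exp(self.beta + z * self.se)


@dataclass(frozen=True)
class SignatureModel:
    """Ordered gene list with fitted per-gene coefficients."""

    gene_ids: tuple[str, ...]
    betas: tuple[float, ...]
    training_cohort_id: str = ""

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.betas):
            raise ValueError("gene_ids and betas must have equal length")
        if not all(math.isfinite(b) for b in self.betas):
            raise ValueError("betas must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "beta": self.betas})


@dataclass(frozen=True)
class RiskAssignment:
    pi: pd.Series
    group: pd.Series  # "low" | "high"
    threshold: float
    standardized: bool


def hr_from_beta(beta: float) -> float:
    """Hazard ratio exp(beta) of a Cox log-hazard coefficient."""
    return math.exp(beta)


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
             ties: str = "efron") -> CoxPHFitter:
    if ties != "efron":
        raise NotImplementedError("only Efron tie handling is available")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise ArithmeticError(f"Cox fit did not converge: {exc}") from exc
    return cph


def cox_fit_table(df: pd.DataFrame, duration_col: str, event_col: str,
                  ties: str = "efron") -> dict[str, CoxFit]:
    """Cox PH fit of all non-time columns; one CoxFit per covariate."""
    events = int(df[event_col].sum())
    if events < 2:
        raise CoxFitError(f"need >= 2 events, got {events}")
    covs = [c for c in df.columns if c not in (duration_col, event_col)]
    for c in covs:
        if df[c].nunique() < 2:
            raise CoxFitError(f"covariate {c!r} is constant")
    if len(covs) > 1:
        corr = df[covs].corr().to_numpy()
        if np.any(np.abs(corr[~np.eye(len(covs), dtype=bool)]) > 0.9999):
            raise ArithmeticError("collinear covariates in Cox design")
    cph = _fit_cox(df, duration_col, event_col, ties=ties)
    summary = cph.summary
    return {
        c: CoxFit(
            beta=float(summary.loc[c, "coef"]),
            se=float(summary.loc[c, "se(coef)"]),
            hr=math.exp(float(summary.loc[c, "coef"])),
            p_wald=float(summary.loc[c, "p"]),
            n=len(df),
            n_events=events,
        )
        for c in covs
    }


def fit_univariate_cox(
    expr_gene: pd.Series | np.ndarray,
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    ties: str = "efron",
) -> CoxFit:
    """Single-covariate Cox PH fit (partial likelihood, Efron ties, Wald p)."""
    df = pd.DataFrame({
        "x": np.asarray(expr_gene, dtype=float),
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event, dtype=int),
    })
    return cox_fit_table(df, "time", "event", ties=ties)["x"]


def fit_signature_betas(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_ids: list[str],
    time_col: str = "pfs_days",
    event_col: str = "pfs_event",
    training_cohort_id: str = "",
    joint: bool = False,
) -> SignatureModel:
    """Per-gene Cox coefficients for the signature on the given patients.

    Default is one univariate fit per gene; ``joint=True`` instead fits one
    multivariable Cox model over all signature genes.
    """
    missing = [g for g in gene_ids if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    samples = [s for s in clinical.index if s in expr.columns]
    sub = clinical.loc[samples]
    if joint:
        df = expr.loc[gene_ids, samples].T.copy()
        df["time"] = sub[time_col].to_numpy(dtype=float)
        df["event"] = sub[event_col].to_numpy(dtype=int)
        fits = cox_fit_table(df, "time", "event")
        betas = tuple(fits[g].beta for g in gene_ids)
    else:
        betas = tuple(
            fit_univariate_cox(
                expr.loc[g, samples], sub[time_col], sub[event_col]).beta
            for g in gene_ids
        )
    return SignatureModel(tuple(gene_ids), betas, training_cohort_id)


def compute_pi(
    expr: pd.DataFrame,
    model: SignatureModel,
    standardize: bool = False,
) -> pd.Series:
    """Prognostic index PI = sum(beta_g * expression_g) per sample.

    With ``standardize`` the PI vector is z-scored post hoc, leaving ranks
    (and hence median-split risk groups) unchanged.
    """
    missing = [g for g in model.gene_ids if g not in expr.index]
    if missing:
        raise KeyError(f"model genes absent from expression matrix: {missing}")
    x = expr.loc[list(model.gene_ids)].to_numpy(dtype=float)
    pi = pd.Series(
        np.asarray(model.betas) @ x, index=expr.columns, name="pi")
    if standardize:
        sd = pi.std(ddof=0)
        if sd == 0:
            raise ValueError("cannot standardize a constant PI vector")
        pi = (pi - pi.mean()) / sd
    return pi


def assign_risk(
    pi: pd.Series,
    strategy: str = "median",
    threshold: float | None = None,
    standardized: bool = False,
) -> RiskAssignment:
    """Split samples into low (< threshold) and high (>= threshold) risk.

    ``strategy="median"`` uses the median PI as the threshold;
    ``strategy="explicit"`` uses the supplied value, which must leave both
    groups non-empty.
    """
    if len(pi) < 2:
        raise ValueError("need >= 2 samples to assign risk groups")
    if pi.nunique() == 1:
        raise ValueError("degenerate PI vector: all values equal")
    if strategy == "median":
        thr = float(pi.median())
    elif strategy == "explicit":
        if threshold is None:
            raise ValueError("explicit strategy requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    group = pd.Series(
        np.where(pi >= thr, "high", "low"), index=pi.index, name="group")
    if (group == "low").sum() == 0 or (group == "high").sum() == 0:
        raise ValueError(
            f"threshold {thr} leaves an empty risk group; choose a value "
            "strictly inside the PI range")
    return RiskAssignment(pi=pi, group=group, threshold=thr,
                          standardized=standardized)


def transfer_signature(
    model: SignatureModel,
    expr_external: pd.DataFrame,
    scaling: str = "z",
    allow_missing: bool = False,
) -> pd.Series:
    """Apply frozen betas to an external cohort; never refits.

    ``scaling="z"`` z-scores each gene across the external samples first,
    absorbing platform-specific location/scale shifts; ``scaling="none"``
    uses raw values. Missing model genes raise unless ``allow_missing``,
    in which case they are dropped (and the drop is reported via a warning).
    """
    if scaling not in ("z", "none"):
        raise ValueError("scaling must be 'z' or 'none'")
    present = [g for g in model.gene_ids if g in expr_external.index]
    missing = [g for g in model.gene_ids if g not in expr_external.index]
    if missing and not allow_missing:
        raise KeyError(f"model genes absent from external matrix: {missing}")
    if missing:
        warnings.warn(f"dropping {len(missing)} model genes missing from the "
                      f"external matrix: {missing}")
    betas = [b for g, b in zip(model.gene_ids, model.betas) if g in set(present)]
    sub = expr_external.loc[present].astype(float)
    if scaling == "z":
        sd = sub.std(axis=1, ddof=0).replace(0, np.nan)
        sub = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
    return pd.Series(
        np.asarray(betas) @ sub.to_numpy(), index=expr_external.columns,
        name="pi")
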