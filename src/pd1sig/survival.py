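"""Survival analysis: Kaplan-Meier estimation, log-rank testing, and Cox
proportional-hazards regression for score-stratified cohorts.

Kaplan-Meier curves and Cox fits are computed with lifelines (Efron tie
handling, Wald intervals); the log-rank statistic and the Cox score test
at beta = 0 are implemented directly from the observed-minus-expected /
hypergeometric-variance formulas so the classical identity between the two
can be checked across independent code paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .io import ClinicalTable

__all__ = [
    "KmCurve",
    "km_estimate",
    "logrank_test",
    "cox_score_test",
    "CoxFit",
    "coxph_fit",
    "survival_by_groups",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KmCurve:
    """Product-limit estimate: steps only at event times; censored times
    reduce the risk set without a step."""

    time: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def survival_at(self, t: float) -> float:
        """S(t) with the right-continuous step convention (censoring
        exactly at t counts as at-risk through t)."""
        idx = np.searchsorted(self.time, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def rate_at(self, t: float):
        """(estimate, ci_low, ci_high) of S(t); e.g. ``rate_at(12)`` for
        the 1-year rate with time in months."""
        idx = np.searchsorted(self.time, t, side="right") - 1
        if idx < 0:
            return 1.0, 1.0, 1.0
        lo = float(self.ci_low[idx]) if self.ci_low is not None else float("nan")
        hi = float(self.ci_high[idx]) if self.ci_high is not None else float("nan")
        return float(self.survival[idx]), lo, hi


def km_estimate(times, events) -> KmCurve:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be binary")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(t, event_observed=e)
    table = kmf.event_table.iloc[1:] if 0.0 not in t else kmf.event_table
    # align the survival function and CIs to the event-table times
    times_out = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(times_out).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    ci_low = ci.iloc[:, 0].reindex(times_out).to_numpy()
    ci_high = ci.iloc[:, 1].reindex(times_out).to_numpy()
    return KmCurve(
        time=times_out,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        survival=surv,
        ci_low=ci_low,
        ci_high=ci_high,
    )


# ---------------------------------------------------------------------------
# log-rank


def logrank_test(times, events, groups):
    """K-sample log-rank test.

    Observed-minus-expected event counts with the hypergeometric
    variance-covariance, summed over event times; the statistic is
    chi-square with ``k - 1`` degrees of freedom. Returns
    ``(chi2, df, p)``.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if e.sum() < 1:
        raise ValueError("need at least 1 event")
    event_times = np.unique(t[e == 1])
    o_minus_e = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        dying = (t == et) & (e == 1)
        N = int(at_risk.sum())
        D = int(dying.sum())
        if N < 1:
            continue
        n_g = np.array([(at_risk & (g == lab)).sum() for lab in labels],
                       dtype=float)
        d_g = np.array([(dying & (g == lab)).sum() for lab in labels],
                       dtype=float)
        o_minus_e += d_g - D * n_g / N
        if N > 1:
            factor = D * (N - D) / (N - 1.0)
            p_g = n_g / N
            V += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    sub = slice(0, k - 1)
    chi2 = float(
        o_minus_e[sub] @ np.linalg.pinv(V[sub, sub]) @ o_minus_e[sub]
    )
    df = k - 1
    p = float(scipy.stats.chi2.sf(chi2, df))
    return chi2, df, p


def cox_score_test(times, events, x):
    """Score test of beta = 0 in a Cox model with one covariate.

    On tie-free data with a binary covariate this equals the two-group
    log-rank chi-square (the classical identity). Returns ``(chi2, p)``.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    xv = np.asarray(x, dtype=float)
    U = 0.0
    I = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        dying = (t == et) & (e == 1)
        d = int(dying.sum())
        xr = xv[at_risk]
        xbar = xr.mean()
        U += xv[dying].sum() - d * xbar
        n_r = len(xr)
        if n_r > 1:
            # hypergeometric variance matching the log-rank convention
            I += d * (n_r - d) / (n_r - 1.0) * ((xr**2).mean() - xbar**2)
    if I <= 0:
        raise ValueError("degenerate information; score test undefined")
    chi2 = U**2 / I
    return float(chi2), float(scipy.stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """Proportional-hazards fit: log hazard ratios with Wald 95% intervals
    and p-values (Efron tie correction)."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "HR": self.hr,
                "CI2.5": self.ci_low,
                "CI97.5": self.ci_high,
                "p": self.p,
            },
            index=self.names,
        )


def _expand_covariates(covariates: pd.DataFrame,
                       reference: dict | None = None) -> pd.DataFrame:
    """Dummy-code categorical covariates against a stated reference level
    (first level by default); numeric covariates enter untransformed."""
    reference = reference or {}
    out = {}
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            out[col] = s.astype(float)
        elif pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            levels = sorted(s.dropna().unique())
            ref = reference.get(col, levels[0])
            if ref not in levels:
                raise ValueError(f"reference {ref!r} not a level of {col!r}")
            for lev in levels:
                if lev != ref:
                    out[f"{col}[{lev}]"] = (s == lev).astype(float)
    return pd.DataFrame(out, index=covariates.index)


def coxph_fit(times, events, covariates: pd.DataFrame,
              reference: dict | None = None) -> CoxFit:
    """Multivariable Cox proportional-hazards fit (partial likelihood,
    Efron ties, Wald inference) via lifelines.

    ``covariates`` may mix numeric and categorical columns; categoricals
    are expanded against a reference level. Monotone likelihood (infinite
    beta) falls back to a lightly penalized fit with a warning.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() < 2:
        raise ValueError("need at least 2 events")
    X = _expand_covariates(pd.DataFrame(covariates), reference)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    df = X.copy()
    df["_time"] = t
    df["_event"] = e
    converged = True
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except (ConvergenceError, np.linalg.LinAlgError):
        warnings.warn(
            "monotone likelihood or non-convergence; refitting with a "
            "small ridge penalty — estimates are capped"
        )
        converged = False
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    s = cph.summary
    return CoxFit(
        names=list(s.index),
        beta=s["coef"].to_numpy(),
        se=s["se(coef)"].to_numpy(),
        hr=s["exp(coef)"].to_numpy(),
        ci_low=s["exp(coef) lower 95%"].to_numpy(),
        ci_high=s["exp(coef) upper 95%"].to_numpy(),
        p=s["p"].to_numpy(),
        n=len(t),
        n_events=int(e.sum()),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# group-level analysis


def survival_by_groups(clinical: ClinicalTable, groups: pd.Series,
                       endpoint: str = "os", contrast: tuple | None = None,
                       rate_months: float = 12.0) -> dict:
    """Kaplan-Meier per group, overall log-rank, optional pairwise
    contrast (two-group log-rank plus univariate Cox HR), and the
    ``rate_months`` survival read-off per group.

    ``groups`` maps sample identifier to group label; empty groups are
    dropped with a warning.
    """
    groups = pd.Series(groups)
    t_all, e_all, mask = clinical.endpoint(endpoint)
    samples = np.asarray(clinical.samples)[mask]
    g = groups.reindex(samples)
    usable = g.notna().to_numpy()
    if not usable.all():
        warnings.warn(
            f"{(~usable).sum()} sample(s) without a group label dropped"
        )
    t, e, g = t_all[usable], e_all[usable], g[usable].to_numpy()
    if isinstance(groups.dtype, pd.CategoricalDtype):
        expected = list(groups.cat.categories)
    else:
        expected = list(pd.unique(groups.dropna()))
    labels = [lab for lab in expected if (g == lab).any()]
    dropped = set(expected) - set(labels)
    if dropped:
        warnings.warn(f"empty group(s) dropped: {sorted(map(str, dropped))}")
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    curves, rates = {}, {}
    for lab in labels:
        m = g == lab
        curve = km_estimate(t[m], e[m])
        curves[lab] = curve
        rates[lab] = curve.rate_at(rate_months)
    chi2, dfree, p = logrank_test(t, e, g)
    out = {
        "curves": curves,
        "rates": rates,
        "logrank": {"chi2": chi2, "df": dfree, "p": p},
    }
    if contrast is not None:
        a, b = contrast
        m = (g == a) | (g == b)
        if not ((g == a).any() and (g == b).any()):
            raise ValueError("contrast group missing")
        c_chi2, _, c_p = logrank_test(t[m], e[m], g[m])
        x = (g[m] == a).astype(float)
        fit = coxph_fit(t[m], e[m], pd.DataFrame({"group": x}))
        out["contrast"] = {
            "groups": (a, b),
            "logrank_chi2": c_chi2,
            "logrank_p": c_p,
            "hr": float(fit.hr[0]),
            "hr_ci": (float(fit.ci_low[0]), float(fit.ci_high[0])),
            "hr_p": float(fit.p[0]),
        }
    return out
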