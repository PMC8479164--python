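"""Response-prediction evaluation of the signature score.

ROC/AUC (rank-sum formulation with ties counted half), Youden-index
dichotomization, continuous net reclassification improvement, logistic
combination with tumor mutational burden (TMB), four-group TMB x score
stratification, the per-cancer-type response-rate correlation, the
absolute-fraction estimator, and top/bottom score-contrast grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "auc",
    "roc_curve",
    "youden_cutoff",
    "nri",
    "logistic_combine",
    "four_group_stratify",
    "pancancer_orr_correlation",
    "absolute_fraction",
    "tertile_contrast_groups",
]


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y.astype(int)


def auc(scores, labels) -> float:
    """Probability that a responder outranks a nonresponder (ties 1/2).

    Computed as the normalized rank-sum statistic, which equals the
    trapezoidal area under the ROC curve.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    r = scipy.stats.rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve(scores, labels) -> pd.DataFrame:
    """Sensitivity/specificity at every midpoint threshold (high = score
    strictly above the threshold)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    thresholds = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    rows = []
    pos, neg = (y == 1), (y == 0)
    for t in thresholds:
        pred = s > t
        rows.append(
            {
                "threshold": t,
                "sens": float(pred[pos].mean()),
                "spec": float((~pred[neg]).mean()),
            }
        )
    return pd.DataFrame(rows)


def youden_cutoff(scores, labels):
    """Threshold maximizing J = sensitivity + specificity - 1.

    Thresholds are the midpoints between adjacent distinct scores; "high"
    means strictly above the threshold. Ties in J break toward higher
    sensitivity, then toward the lower threshold. Returns
    ``(threshold, sensitivity, specificity, J)``.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("all scores identical; no threshold exists")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for t in mids:
        pred = s > t
        sens = float(pred[y == 1].mean())
        spec = float((~pred)[y == 0].mean())
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, (float(t), sens, spec, j))
    return best[1]


def _predicted_probability(score, y) -> tuple[np.ndarray, bool]:
    """Map a score to a response probability via its own univariate
    logistic fit; under separation/non-convergence, fall back to the
    score's percentile rank (preserving the given orientation: higher score
    means more likely responder)."""
    s = np.asarray(score, dtype=float)
    if s.std() > 0:
        z = (s - s.mean()) / s.std()
        X = sm.add_constant(z)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            if res.mle_retvals.get("converged", False) and np.all(
                np.isfinite(params)
            ) and np.abs(params).max() < 30:
                return np.asarray(res.predict(X)), False
        except (PerfectSeparationError, np.linalg.LinAlgError):
            pass
    warnings.warn(
        "univariate logistic fit did not converge (separation?); "
        "falling back to rank-based probabilities"
    )
    r = scipy.stats.rankdata(s)
    return (r - 1.0) / max(len(s) - 1.0, 1.0), True


def nri(score_new, score_ref, labels) -> float:
    """Continuous (category-free) net reclassification improvement.

    Each score is mapped to a predicted probability by its own univariate
    logistic fit; the NRI sums the net fraction of responders whose
    predicted risk moves up with the new score and nonresponders whose
    risk moves down. Range [-2, 2].
    """
    y = _check_binary(labels)
    s_new = np.asarray(score_new, dtype=float)
    s_ref = np.asarray(score_ref, dtype=float)
    if len(s_new) != len(s_ref) or len(s_new) != len(y):
        raise ValueError("inputs must have equal length")
    if np.array_equal(s_new, s_ref):
        return 0.0
    p_new, _ = _predicted_probability(s_new, y)
    p_ref, _ = _predicted_probability(s_ref, y)
    up = p_new > p_ref
    down = p_new < p_ref
    pos, neg = (y == 1), (y == 0)
    return float(
        (up[pos].mean() - down[pos].mean())
        + (down[neg].mean() - up[neg].mean())
    )


@dataclass
class CombinedFit:
    """A logistic combination of the signature score with TMB."""

    coef: dict
    probabilities: np.ndarray
    auc_combined: float
    converged: bool


def logistic_combine(score, tmb, labels) -> CombinedFit:
    """Maximum-likelihood logistic fit of response on the standardized
    score and TMB; returns fitted probabilities and their AUC.

    Zero-variance predictors are dropped (the fit degenerates to the other
    predictor); under perfect separation a ridge-penalized fallback still
    returns probabilities, with the coefficients flagged non-finite.
    """
    y = _check_binary(labels)
    preds = {"score": np.asarray(score, float), "tmb": np.asarray(tmb, float)}
    if any(len(v) != len(y) for v in preds.values()):
        raise ValueError("inputs must have equal length")
    if any(np.isnan(v).any() for v in preds.values()):
        raise ValueError("missing predictor values")
    kept = {k: (v - v.mean()) / v.std() for k, v in preds.items()
            if v.std() > 0}
    if not kept:
        raise ValueError("both predictors are constant")
    X = sm.add_constant(np.column_stack(list(kept.values())))
    names = ["const", *kept.keys()]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        ok = res.mle_retvals.get("converged", False) and np.all(
            np.isfinite(params)
        ) and np.abs(params).max() < 30
    except (PerfectSeparationError, np.linalg.LinAlgError):
        ok = False
    if ok:
        probs = np.asarray(res.predict(X))
        coef = dict(zip(names, params))
        converged = True
    else:
        warnings.warn(
            "logistic fit separated; returning ridge-penalized probabilities"
        )
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, solver="lbfgs").fit(X[:, 1:], y)
        probs = lr.predict_proba(X[:, 1:])[:, 1]
        coef = {n: float("nan") for n in names}
        converged = False
    return CombinedFit(
        coef=coef,
        probabilities=probs,
        auc_combined=auc(probs, y),
        converged=converged,
    )


def four_group_stratify(score, tmb, labels=None, cutoffs=None,
                        samples=None) -> pd.DataFrame:
    """Assign each sample to one of the four TMB x score groups.

    The two cutoffs come from :func:`youden_cutoff` against the response
    labels unless supplied explicitly as ``(score_cutoff, tmb_cutoff)``.
    "High" means strictly above the cutoff. Returns a DataFrame with
    columns ``sample`` and ``group``; the cutoffs are stored in
    ``df.attrs["cutoffs"]``.
    """
    s = np.asarray(score, dtype=float)
    t = np.asarray(tmb, dtype=float)
    if cutoffs is None:
        if labels is None:
            raise ValueError("need labels to derive Youden cutoffs")
        s_cut = youden_cutoff(s, labels)[0]
        t_cut = youden_cutoff(t, labels)[0]
    else:
        s_cut, t_cut = cutoffs
    if samples is None:
        samples = [f"S{i}" for i in range(len(s))]
    group = [
        f"TMB{'high' if ti > t_cut else 'low'}"
        f"Score{'high' if si > s_cut else 'low'}"
        for si, ti in zip(s, t)
    ]
    out = pd.DataFrame({"sample": list(samples), "group": group})
    out.attrs["cutoffs"] = {"score": float(s_cut), "tmb": float(t_cut)}
    return out


def pancancer_orr_correlation(score_tables: dict, orr, pct: float = 0.8):
    """Correlate the per-cancer-type fraction of high-score samples with
    the reported objective response rate.

    The high-score threshold is the ``pct`` quantile of the pooled score
    distribution across all types; per type, the fraction of samples
    strictly above it is Pearson-correlated with ORR (two-sided p via the
    t-transform with n-2 degrees of freedom). Returns
    ``(r, p, per_type_fraction)``.
    """
    if not 0.0 < pct < 1.0:
        raise ValueError("pct must lie in (0, 1)")
    orr = pd.Series(orr)
    if len(score_tables) < 3:
        raise ValueError("need at least 3 cancer types")
    missing = set(score_tables) - set(orr.index)
    if missing:
        raise ValueError(f"ORR missing for types: {sorted(missing)}")
    series = {k: pd.Series(v).astype(float) for k, v in score_tables.items()}
    pooled = np.concatenate([v.to_numpy() for v in series.values()])
    threshold = float(np.quantile(pooled, pct))
    frac = pd.Series(
        {k: float((v > threshold).mean()) for k, v in series.items()}
    )
    orr = orr.loc[frac.index]
    if np.isclose(orr.std(ddof=0), 0.0) or np.isclose(frac.std(ddof=0), 0.0):
        raise ValueError("zero variance; correlation undefined")
    r, p = scipy.stats.pearsonr(frac, orr)
    frac.attrs["threshold"] = threshold
    return float(r), float(p), frac


def absolute_fraction(relative_pd1hi_in_cd8: float,
                      cd8_fraction_in_tumor: float) -> float:
    """Absolute PD-1hi CD8+ T-cell fraction of the tumor sample: the
    relative fraction within CD8+ T cells times the CD8+ fraction of the
    tumor."""
    for v in (relative_pd1hi_in_cd8, cd8_fraction_in_tumor):
        if not 0.0 <= v <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    return relative_pd1hi_in_cd8 * cd8_fraction_in_tumor


def tertile_contrast_groups(scores: pd.Series, frac: float = 1.0 / 3.0):
    """Top and bottom ``floor(frac * n)`` samples by score (ties broken by
    sample identifier). Returns ``(top_ids, bottom_ids)``."""
    scores = pd.Series(scores)
    n = len(scores)
    if n < 6:
        raise ValueError("need at least 6 samples")
    if frac > 0.5:
        raise ValueError("frac > 0.5 makes the groups overlap")
    k = int(np.floor(frac * n))
    order_asc = sorted(scores.index, key=lambda s: (scores[s], s))
    bottom = order_asc[:k]
    top = list(reversed(order_asc[-k:]))
    return top, bottom
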