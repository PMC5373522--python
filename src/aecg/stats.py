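"""Cohort-level statistics: univariate screening, ROC, Kaplan-Meier, Cox PH.

The screening step Welch-tests every numeric variable between outcome
groups and applies both the nominal (p < alpha) and the Bonferroni
(p < alpha/m) significance rules. ROC analysis uses the rank (Mann-Whitney)
AUC with tie correction, a Youden-index optimal cutoff (ties broken toward
higher sensitivity) and a DeLong confidence interval. Survival methods wrap
lifelines (product-limit estimator, log-rank test, Cox partial likelihood
with Efron tie handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import FitError
from .io import CohortTable


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# univariate screening
# ---------------------------------------------------------------------------

def univariate_screen(table: CohortTable, group_col: str,
                      alpha: float = 0.05, m: int | None = None,
                      equal_var: bool = False,
                      variables: list[str] | None = None) -> pd.DataFrame:
    """Two-sample t-test of every numeric variable between the two groups.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled version). Returns one row per variable with group means/SDs, the
    t statistic, p-value, ``nominal_significant`` (p < alpha) and
    ``bonferroni_significant`` (p < alpha/m, m defaulting to the number of
    testable variables). Constant or under-sampled variables are flagged
    ``testable=False`` rather than raising.
    """
    frame = table.data
    groups = frame[group_col]
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise FitError(f"group column {group_col!r} must have exactly 2 levels, got {levels}")
    candidates = variables if variables is not None else [
        c for c in table.numeric_columns() if c != group_col]
    rows = []
    for col in candidates:
        a = frame.loc[groups == levels[0], col].dropna().to_numpy(dtype=float)
        b = frame.loc[groups == levels[1], col].dropna().to_numpy(dtype=float)
        row = {
            "variable": col,
            "mean_0": a.mean() if len(a) else np.nan,
            "sd_0": a.std(ddof=1) if len(a) > 1 else np.nan,
            "mean_1": b.mean() if len(b) else np.nan,
            "sd_1": b.std(ddof=1) if len(b) > 1 else np.nan,
            "n_0": len(a), "n_1": len(b),
        }
        constant = (len(a) < 2 or len(b) < 2
                    or (np.ptp(a) == 0.0 and np.ptp(b) == 0.0))
        if constant:
            row.update(testable=False, t=np.nan, p=np.nan)
        else:
            t, p = sstats.ttest_ind(a, b, equal_var=equal_var)
            row.update(testable=True, t=float(t), p=float(p))
        rows.append(row)
    result = pd.DataFrame(rows).set_index("variable")
    m_eff = m if m is not None else max(int(result["testable"].sum()), 1)
    threshold = bonferroni_threshold(alpha, m_eff)
    result["nominal_significant"] = result["p"] < alpha
    result["bonferroni_significant"] = result["p"] < threshold
    result.attrs["bonferroni_threshold"] = threshold
    result.attrs["m"] = m_eff
    return result


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    optimal_cutoff: float
    sensitivity: float  # percent, at the optimal cutoff
    specificity: float  # percent
    direction: str = "greater"
    n_positive: int = 0
    n_negative: int = 0


def rank_auc(score: np.ndarray, label: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction (probability score_pos > score_neg)."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label, dtype=int)
    n1 = int(label.sum())
    n0 = len(label) - n1
    if n0 == 0 or n1 == 0:
        raise FitError("both classes must be present for ROC analysis")
    ranks = sstats.rankdata(score)
    u = ranks[label == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC via midrank placements."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tx = sstats.rankdata(pos)
    ty = sstats.rankdata(neg)
    tz = sstats.rankdata(all_scores)
    v01 = (tz[:m] - tx) / n                # placements of positives
    v10 = 1.0 - (tz[m:] - ty) / m          # placements of negatives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return s01 / m + s10 / n


def roc_analysis(score, label, direction: str = "greater") -> RocResult:
    """ROC AUC, DeLong 95% CI, and the Youden-optimal cutoff.

    ``direction="greater"`` means larger scores predict the positive label;
    the reported cutoff is applied as ``score > cutoff`` (or ``<`` for
    ``direction="less"``) and sits at the midpoint between adjacent observed
    values. Ties in the Youden index are broken toward higher sensitivity.
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label, dtype=int)
    mask = np.isfinite(score) & np.isfinite(label.astype(float))
    score, label = score[mask], label[mask]
    s = score if direction == "greater" else -score
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    auc = rank_auc(s, label)
    var = _delong_variance(s[label == 1], s[label == 0])
    half = 1.96 * np.sqrt(var)
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)

    uniq = np.unique(s)
    edges = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    pos, neg = s[label == 1], s[label == 0]
    # sens/spec for the rule s > cutoff, vectorised over candidate cutoffs
    sens = 1.0 - np.searchsorted(np.sort(pos), edges, side="right") / len(pos)
    spec = np.searchsorted(np.sort(neg), edges, side="right") / len(neg)
    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    pick = best[np.argmax(sens[best])]
    cutoff = edges[pick] if direction == "greater" else -edges[pick]
    return RocResult(auc=auc, ci_low=ci_low, ci_high=ci_high,
                     optimal_cutoff=float(cutoff),
                     sensitivity=float(100.0 * sens[pick]),
                     specificity=float(100.0 * spec[pick]),
                     direction=direction,
                     n_positive=len(pos), n_negative=len(neg))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    """Per-group product-limit curves plus the log-rank comparison."""

    groups: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_statistic: float = np.nan
    logrank_p: float = np.nan


def km_curve(time, event, group=None) -> KmCurve:
    """Kaplan-Meier estimate per group with a log-rank test across groups."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise FitError("empty group")
    if (time < 0).any():
        raise FitError("negative event/censoring times")
    if group is None:
        group = np.zeros(len(time), dtype=int)
    group = np.asarray(group)
    result = KmCurve()
    for level in pd.unique(group):
        mask = group == level
        if mask.sum() == 0:
            raise FitError(f"empty group {level!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        tbl = kmf.event_table
        curve = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": tbl["at_risk"].to_numpy(),
        })
        result.groups[str(level)] = curve
    if len(result.groups) > 1:
        lr = multivariate_logrank_test(time, group, event)
        result.logrank_statistic = float(lr.test_statistic)
        result.logrank_p = float(lr.p_value)
    return result


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs and the log partial likelihood."""

    summary: pd.DataFrame  # index: covariate; hr, ci_low, ci_high, coef, p
    log_likelihood: float

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(table: CohortTable | pd.DataFrame, covariates: list[str],
            time_col: str = "time_days", event_col: str = "event") -> CoxResult:
    """Cox PH fit by maximum partial likelihood (Efron tie handling).

    Raises :class:`FitError` on degenerate inputs (no events, constant
    covariates) or non-convergence/separation.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    frame = table.data if isinstance(table, CohortTable) else table
    cols = covariates + [time_col, event_col]
    data = frame[cols].dropna().astype(float)
    if data[event_col].sum() < 1:
        raise FitError("no events in the data")
    for cov in covariates:
        if np.ptp(data[cov].to_numpy()) == 0.0:
            raise FitError(f"constant covariate: {cov}")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=time_col, event_col=event_col)
    except (ConvergenceError, ValueError) as exc:
        raise FitError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxResult(summary=summary, log_likelihood=float(cph.log_likelihood_))
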