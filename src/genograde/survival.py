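"""Fixed-horizon prognostic evaluation and survival analysis.

Markers are evaluated against the 10-year distant-metastasis endpoint in
two complementary ways:

* a binary-outcome design at a fixed horizon (default 120 months):
  patients with an event on or before the horizon are positives, patients
  followed event-free to the horizon are negatives, and patients censored
  earlier are excluded (their 10-year status is unknown).  Discrimination
  is summarized by the Mann-Whitney AUC with Hanley-McNeil confidence
  intervals, and two AUCs measured on the same patients are compared with
  the correlated z-test;
* full time-to-event analysis: Kaplan-Meier curves, log-rank tests and
  Cox proportional-hazards fits (Efron tie handling, Newton-Raphson via
  lifelines).

All p-values are two-sided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .errors import SurvivalError

__all__ = [
    "ROCResult",
    "CoxFit",
    "KMCurve",
    "horizon_labels",
    "auc",
    "hanley_ci",
    "hanley_compare",
    "within_class_rank_correlation",
    "km_curve",
    "logrank",
    "cox_fit",
]


def horizon_labels(times, events, horizon: float = 120.0) -> pd.Series:
    """Label each sample positive / negative / excluded at a fixed horizon.

    Positive: event on or before the horizon.  Negative: followed at least
    to the horizon without an event by then.  Excluded: censored before the
    horizon (outcome unknowable).
    """
    if horizon <= 0:
        raise SurvivalError("horizon must be > 0")
    t = pd.Series(times, dtype=float)
    e = pd.Series(events).reindex(t.index).astype(bool)
    out = pd.Series("excluded", index=t.index, dtype=object)
    out[e & (t <= horizon)] = "positive"
    out[t >= horizon] = "negative"
    # an event exactly at the horizon counts as positive, not negative
    out[e & (t <= horizon)] = "positive"
    return out


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple
    n_pos: int
    n_neg: int
    se: float


def hanley_ci(auc_value: float, n_pos: int, n_neg: int):
    """Hanley-McNeil standard error and 95% CI for one AUC.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A); the interval is A +- 1.96 SE
    clipped to [0, 1].
    """
    a = float(auc_value)
    if not 0.0 <= a <= 1.0:
        raise SurvivalError("AUC must be in [0, 1]")
    if a in (0.0, 1.0):
        warnings.warn("degenerate AUC; confidence interval collapses", stacklevel=2)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    se2 = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    se = math.sqrt(max(se2, 0.0))
    lo = max(0.0, a - 1.96 * se)
    hi = min(1.0, a + 1.96 * se)
    return (lo, hi), se


def auc(values, labels) -> ROCResult:
    """Mann-Whitney AUC (ties count 1/2), i.e. the trapezoidal ROC area.

    ``labels`` may be booleans or the strings from :func:`horizon_labels`
    ("excluded" samples are dropped first).
    """
    v = pd.Series(values, dtype=float)
    lab = pd.Series(labels).reindex(v.index)
    if lab.dtype == object:
        keep = lab.isin(["positive", "negative"])
        v, lab = v[keep], lab[keep] == "positive"
    lab = lab.astype(bool)
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise SurvivalError("AUC needs at least one positive and one negative")
    ranks = rankdata(v.to_numpy(), method="average")
    a = (ranks[lab.to_numpy()].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    ci, se = hanley_ci(a, n_pos, n_neg)
    return ROCResult(auc=float(a), ci95=ci, n_pos=n_pos, n_neg=n_neg, se=se)


def within_class_rank_correlation(values_a, values_b, labels) -> float:
    """Mean Spearman rank correlation of two markers within each outcome class.

    This average within-class correlation drives the correlated-AUC
    comparison; it closely tracks the tabulated mapping from rating
    correlation to AUC correlation and is used as its smooth stand-in
    (see docs/methods.md).
    """
    va = pd.Series(values_a, dtype=float)
    vb = pd.Series(values_b, dtype=float).reindex(va.index)
    lab = pd.Series(labels).reindex(va.index)
    if lab.dtype == object:
        keep = lab.isin(["positive", "negative"])
        va, vb, lab = va[keep], vb[keep], lab[keep] == "positive"
    lab = lab.astype(bool)
    rs = []
    for cls in (True, False):
        x, y = va[lab == cls], vb[lab == cls]
        if len(x) >= 3 and x.nunique() > 1 and y.nunique() > 1:
            rs.append(stats.spearmanr(x, y).statistic)
    if not rs:
        raise SurvivalError("cannot estimate within-class correlation")
    return float(np.mean(rs))


def hanley_compare(roc_a: ROCResult, roc_b: ROCResult, r: float):
    """Correlated two-AUC z-test on the same samples.

    z = (A_a - A_b) / sqrt(SE_a^2 + SE_b^2 - 2 r SE_a SE_b); with r = 0 it
    reduces to the independent-AUC z-test.  Returns ``(z, p)`` (two-sided).
    """
    if (roc_a.n_pos, roc_a.n_neg) != (roc_b.n_pos, roc_b.n_neg):
        raise SurvivalError("the two ROC results must come from the same samples")
    if not -1.0 <= r <= 1.0:
        raise SurvivalError("correlation r must be in [-1, 1]")
    denom2 = roc_a.se**2 + roc_b.se**2 - 2.0 * r * roc_a.se * roc_b.se
    if denom2 <= 0:
        if roc_a.auc == roc_b.auc:
            return 0.0, 1.0
        raise SurvivalError("non-positive variance of the AUC difference")
    z = (roc_a.auc - roc_b.auc) / math.sqrt(denom2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class KMCurve:
    """Kaplan-Meier estimate with its event/at-risk tallies."""

    timeline: np.ndarray
    survival: np.ndarray
    event_table: pd.DataFrame

    def survival_at(self, t: float) -> float:
        """Right-continuous step evaluation of S(t); S(t) = 1 before any event."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events) -> KMCurve:
    """Product-limit survival estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.any(t <= 0):
        raise SurvivalError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return KMCurve(
        timeline=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        event_table=kmf.event_table,
    )


def logrank(groups, times, events):
    """Log-rank test across >= 2 groups; returns ``(chi2, df, p)``."""
    g = pd.Series(groups).astype(str)
    t = pd.Series(times, dtype=float)
    e = pd.Series(events).astype(bool)
    n_groups = g.nunique()
    if n_groups < 2:
        raise SurvivalError("log-rank needs at least two groups")
    if int(e.sum()) < 1:
        raise SurvivalError("log-rank needs at least one event")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), n_groups - 1, float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (partial likelihood, Efron ties)."""

    coefficients: pd.Series  # log hazard ratios
    hr: pd.Series
    coef_ci95: pd.DataFrame  # columns lo, hi on the log scale
    hr_ci95: pd.DataFrame
    wald_p: pd.Series
    log_partial_likelihood: float
    n: int
    n_events: int
    converged: bool


def cox_fit(data: pd.DataFrame, duration_col: str = "time",
            event_col: str = "event",
            covariates: Optional[Sequence[str]] = None) -> CoxFit:
    """Fit a Cox model by partial-likelihood Newton-Raphson (Efron ties).

    Categorical covariates must be reference-coded by the caller
    (``pd.get_dummies(..., drop_first=True)``).  Constant covariates and
    complete separation raise :class:`SurvivalError`.
    """
    covariates = list(covariates) if covariates is not None else [
        c for c in data.columns if c not in (duration_col, event_col)
    ]
    if not covariates:
        raise SurvivalError("no covariates specified")
    df = data[[duration_col, event_col] + covariates].copy()
    df[event_col] = df[event_col].astype(bool)
    for c in covariates:
        col = pd.to_numeric(df[c])
        if col.nunique() <= 1:
            raise SurvivalError(f"covariate {c!r} is constant")
        df[c] = col
    n_events = int(df[event_col].sum())
    if n_events < len(covariates) + 1:
        raise SurvivalError(
            f"too few events ({n_events}) for {len(covariates)} covariate(s)"
        )
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col,
                    fit_options={"precision": 1e-11, "r_precision": 1e-16,
                                 "step_size": 1.0, "max_steps": 500})
    except ConvergenceError as exc:
        raise SurvivalError(f"Cox fit did not converge: {exc}") from None
    coef = cph.params_.copy()
    coef_ci = cph.confidence_intervals_.copy()
    coef_ci.columns = ["lo", "hi"]
    return CoxFit(
        coefficients=coef,
        hr=np.exp(coef),
        coef_ci95=coef_ci,
        hr_ci95=np.exp(coef_ci),
        wald_p=cph.summary["p"].copy(),
        log_partial_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
        converged=True,
    )
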