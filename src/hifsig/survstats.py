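"""Survival and association statistics validating a signature score.

Kaplan–Meier curves and the log-rank test delegate to lifelines; Welch's
t-test, the chi-square test and related utilities use scipy. The
dichotomized hazard ratio is a single-covariate Cox fit (raw scale, so
exp(coef) is the high-vs-low group hazard ratio). The fold-change table
reproduces the median-split comparison of individual transcripts: per-gene
medians in the low and high score groups, back-transformed from log2 to the
linear scale, flagged up/down at a closed 1.5-fold boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .containers import ExpressionMatrix, SurvivalTable
from .exceptions import InputError
from .sigbuild import CoxFit, ScoreVector, cox_fit


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    label: str
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events_at: np.ndarray
    median_survival: float  # first time S <= 0.5; nan if never reached
    n: int

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median_survival)

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events_at,
                "group": self.label,
            }
        )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def km_estimate(surv: SurvivalTable, labels=None) -> dict[str, KMCurve]:
    """Kaplan–Meier product-limit curves, one per group label.

    Censored observations at an event time are processed after the event
    (the standard convention). Median survival is the first time at which
    S(t) <= 0.5, NaN if the curve never reaches 0.5.
    """
    if labels is None:
        labels = np.full(len(surv), "all", dtype=object)
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != len(surv):
        raise InputError("labels length must match survival table")
    curves: dict[str, KMCurve] = {}
    for lab in pd.unique(labels):
        m = labels == lab
        if m.sum() == 0:
            raise InputError(f"empty group {lab!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[m], surv.event[m])
        ev = kmf.event_table[kmf.event_table["observed"] > 0]
        times = ev.index.to_numpy(dtype=float)
        s = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(dtype=float)
        at_risk = ev["at_risk"].to_numpy(dtype=int)
        d = ev["observed"].to_numpy(dtype=int)
        below = np.flatnonzero(s <= 0.5)
        median = float(times[below[0]]) if below.size else float("nan")
        curves[str(lab)] = KMCurve(
            label=str(lab),
            event_times=times,
            survival=s,
            at_risk=at_risk,
            n_events_at=d,
            median_survival=median,
            n=int(m.sum()),
        )
    return curves


def logrank(surv: SurvivalTable, labels) -> LogRankResult:
    """Standard (unweighted) log-rank test across two or more groups."""
    labels = np.asarray(labels, dtype=object)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise InputError("log-rank test needs at least 2 groups")
    if surv.n_events == 0:
        raise InputError("log-rank test needs at least 1 event")
    res = multivariate_logrank_test(surv.time, labels, surv.event)
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p=float(res.p_value),
    )


def dichotomized_hr(surv: SurvivalTable, score: ScoreVector) -> CoxFit:
    """Hazard ratio of the high- vs low-score group (Cox on a 0/1 indicator)."""
    aligned = surv.align(score.sample_ids)
    high = score.high.astype(float)
    if high.all() or not high.any():
        raise InputError("all samples fall in one score group")
    return cox_fit(high[:, None], aligned, names=["high_score"], standardize=False)


def assoc_welch(values, covariate) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test of a score between two covariate classes.

    Accepts a :class:`ScoreVector` or a plain numeric vector. Returns
    (t, Welch–Satterthwaite df, two-sided p); the t statistic is signed as
    class 1 minus class 0.
    """
    if isinstance(values, ScoreVector):
        values = values.score
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate)
    if values.shape != covariate.shape:
        raise InputError("score and covariate lengths differ")
    a = values[covariate == 1]
    b = values[covariate == 0]
    if len(a) < 2 or len(b) < 2:
        raise InputError("each covariate class needs >= 2 samples")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(len(a) + len(b) - 2), 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(t), float(df), float(p)


@dataclass
class FoldChangeRow:
    gene: str
    median_low: float
    median_high: float
    ratio_high_over_low: float
    flag: str  # up / down / neutral


def foldchange_table(
    mat: ExpressionMatrix,
    score: ScoreVector,
    genes,
    threshold: float = 1.5,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-gene linear-scale fold change between high and low score groups.

    Expression is assumed log-scale (default log2, the scale of the cohort
    matrices this pipeline ingests); medians are back-transformed before the
    ratio. Flags use a closed boundary: up iff ratio >= threshold, down iff
    ratio <= 1/threshold.
    """
    genes = list(genes)
    mat.require(genes)
    order = {s: i for i, s in enumerate(mat.samples)}
    idx = [order[s] for s in score.sample_ids if s in order]
    if len(idx) != len(score.sample_ids):
        raise InputError("score samples missing from expression matrix")
    high = score.high
    rows = []
    for g in genes:
        v = mat.vector(g)[idx]
        med_lo = log_base ** np.median(v[~high])
        med_hi = log_base ** np.median(v[high])
        if not (np.isfinite(med_lo) and np.isfinite(med_hi)) or med_lo <= 0:
            raise InputError(f"undefined linear-scale ratio for gene {g!r}")
        ratio = med_hi / med_lo
        if ratio >= threshold:
            flag = "up"
        elif ratio <= 1.0 / threshold:
            flag = "down"
        else:
            flag = "neutral"
        rows.append((g, med_lo, med_hi, ratio, flag))
    return pd.DataFrame(
        rows, columns=["gene", "median_low", "median_high", "ratio_high_over_low", "flag"]
    )
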