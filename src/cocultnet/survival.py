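"""Signature-based survival stratification: step-threshold fitting on
composite scores, Kaplan-Meier estimation and two-group log-rank testing.

The default high/low cut is a one-step least-squares fit to the sorted
scores (the StepMiner convention): the split of the sorted vector into a
low and a high segment that minimizes the total within-segment squared
error, with the threshold at the midpoint of the two segment means. A
median split is available as a sensitivity alternative; on odd n the median
patient falls in the low group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from cocultnet.io import CohortTable, ExpressionMatrix, GeneSet
from cocultnet.signature import composite_score


@dataclass
class StepFit:
    """One-step least-squares fit to a sorted value vector."""

    threshold: float
    low_mean: float
    high_mean: float
    sse: float
    split_index: int  # number of values in the low segment
    degenerate: bool = False


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve."""

    times: np.ndarray  # sorted distinct observed times
    at_risk: np.ndarray
    survival: np.ndarray  # S(t) at each time, non-increasing, S(0)=1
    n_events: np.ndarray
    n_censored: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def fit_step_threshold(values) -> StepFit:
    """Fit a two-level step to the sorted values, minimizing total SSE.

    All n-1 splits of the sorted vector are scored; ties break toward the
    smaller split index. Threshold = midpoint of the two segment means.
    A constant (or single-value) input is degenerate: threshold equals the
    constant, flagged.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty input")
    if np.unique(v).size < 2:
        return StepFit(float(v[0]), float(v[0]), float(v[0]), 0.0, n, degenerate=True)
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    k = np.arange(1, n)  # low-segment sizes
    low_sum, low_sq = csum[k - 1], csq[k - 1]
    high_sum, high_sq = csum[-1] - low_sum, csq[-1] - low_sq
    sse = (low_sq - low_sum**2 / k) + (high_sq - high_sum**2 / (n - k))
    best = int(np.argmin(sse))  # argmin takes the first minimum: smaller split
    k_best = best + 1
    low_mean = low_sum[best] / k_best
    high_mean = high_sum[best] / (n - k_best)
    return StepFit(
        threshold=float((low_mean + high_mean) / 2.0),
        low_mean=float(low_mean),
        high_mean=float(high_mean),
        sse=float(max(sse[best], 0.0)),
        split_index=k_best,
    )


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate; censored subjects leave the risk set
    after their time."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise ValueError("times and events must align")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tab = kmf.event_table
    tab = tab[(tab["observed"] + tab["censored"]) > 0]  # drop the synthetic t=0 row
    surv = kmf.survival_function_at_times(tab.index.to_numpy()).to_numpy()
    return KMCurve(
        times=tab.index.to_numpy(dtype=float),
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        survival=surv,
        n_events=tab["observed"].to_numpy(dtype=int),
        n_censored=tab["censored"].to_numpy(dtype=int),
    )


def logrank_test(group_a: tuple, group_b: tuple) -> dict:
    """Two-group log-rank chi-square (1 df) with the hypergeometric variance
    term. Groups are (times, events) tuples."""
    (ta, ea), (tb, eb) = group_a, group_b
    ta, tb = np.asarray(ta, dtype=float), np.asarray(tb, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(ta, tb, event_observed_A=np.asarray(ea), event_observed_B=np.asarray(eb))
    return {"chi2": float(res.test_statistic), "p": float(res.p_value)}


def cohort_scores(cohort: CohortTable, sig: GeneSet) -> pd.Series:
    """Composite signature score per patient (mean of per-gene z-scores)."""
    expr = cohort.expression()
    ann = pd.DataFrame({"condition": "cohort"}, index=expr.columns)
    mat = ExpressionMatrix(expr, "log2cpm", ann)
    return composite_score(mat, sig).scores()


def stratified_survival(
    cohort: CohortTable, sig: GeneSet, method: str = "step"
) -> dict:
    """Score the cohort on the signature, split high vs low, and compare
    survival by Kaplan-Meier + log-rank.

    ``method`` 'step' uses the one-step SSE fit; 'median' puts scores <=
    median (including the median patient at odd n) in the low group.
    An empty stratum is an error naming the threshold.
    """
    scores = cohort_scores(cohort, sig)
    if method == "step":
        threshold = fit_step_threshold(scores.to_numpy()).threshold
        high = scores.to_numpy() > threshold
    elif method == "median":
        threshold = float(np.median(scores.to_numpy()))
        high = scores.to_numpy() > threshold
    else:
        raise ValueError(f"unknown stratification method {method!r}")
    if high.all() or not high.any():
        raise ValueError(f"empty stratum at threshold {threshold:.4g}")
    t, e = cohort.times, cohort.events
    groups = {"high": (t[high], e[high]), "low": (t[~high], e[~high])}
    return {
        "threshold": float(threshold),
        "method": method,
        "group_sizes": {"high": int(high.sum()), "low": int((~high).sum())},
        "labels": pd.Series(np.where(high, "high", "low"), index=scores.index),
        "scores": scores,
        "km": {name: km_estimate(*g) for name, g in groups.items()},
        "logrank": logrank_test(groups["high"], groups["low"]),
    }
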