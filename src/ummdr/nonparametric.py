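"""Kaplan-Meier median survival and the two-group log-rank statistic.

Both are written over pre-sorted arrays so the interaction scan and the
cross-validation comparators can reuse one sort of the survival outcome.
"""
from __future__ import annotations

import math

import numpy as np

from .datamodel import SurvivalData, ValidationError

__all__ = ["km_median", "logrank_statistic"]

_HALF = 0.5 + 1e-12  # guard against S(t) == 0.5 computed with rounding error


def _km_median_sorted(time_s: np.ndarray, status_s: np.ndarray) -> float:
    """Median of the product-limit estimator: the smallest observed event time
    t with S(t) <= 1/2, or +inf when the curve never reaches 1/2."""
    m = time_s.size
    if m == 0:
        raise ValidationError("Kaplan-Meier median of an empty subset is undefined")
    if status_s.sum() == 0:
        return math.inf
    new = np.empty(m, dtype=bool)
    new[0] = True
    new[1:] = time_s[1:] != time_s[:-1]
    starts = np.flatnonzero(new)
    gid = np.cumsum(new) - 1
    events = np.bincount(gid, weights=status_s)
    at_risk = m - starts
    surv = np.cumprod(1.0 - events / at_risk)
    hit = np.flatnonzero((surv <= _HALF) & (events > 0))
    if hit.size == 0:
        return math.inf
    return float(time_s[starts[hit[0]]])


def km_median(surv: SurvivalData, subset=None) -> float:
    """Kaplan-Meier median survival time of ``surv`` (optionally of a subset).

    Returns ``math.inf`` when the survival curve never drops to 0.5 (the
    median is undefined), e.g. under heavy censoring.
    """
    t, d = surv.time, surv.status
    if subset is not None:
        subset = np.asarray(subset)
        t, d = t[subset], d[subset]
        if t.size == 0:
            raise ValidationError("Kaplan-Meier median of an empty subset is undefined")
    order = np.argsort(t, kind="stable")
    return _km_median_sorted(t[order], d[order])


def _logrank_sorted(time_s: np.ndarray, status_s: np.ndarray, group_s: np.ndarray) -> float:
    """Two-group log-rank chi-square on time-ascending arrays.

    ``group_s`` is a boolean membership indicator. Returns 0.0 when the
    statistic is degenerate (a single group, or no usable event times).
    """
    m = time_s.size
    if m == 0 or status_s.sum() == 0:
        return 0.0
    if group_s.all() or not group_s.any():
        return 0.0
    new = np.empty(m, dtype=bool)
    new[0] = True
    new[1:] = time_s[1:] != time_s[:-1]
    starts = np.flatnonzero(new)
    gid = np.cumsum(new) - 1
    d_k = np.bincount(gid, weights=status_s)
    d1_k = np.bincount(gid, weights=status_s * group_s)
    n_k = (m - starts).astype(float)
    n1_k = np.cumsum(group_s[::-1])[::-1][starts].astype(float)
    use = (d_k > 0) & (n_k > 1)
    if not use.any():
        return 0.0
    frac = n1_k[use] / n_k[use]
    o_minus_e = float(np.sum(d1_k[use] - d_k[use] * frac))
    var = float(
        np.sum(d_k[use] * frac * (1 - frac) * (n_k[use] - d_k[use]) / (n_k[use] - 1))
    )
    if var <= 0:
        return 0.0
    return o_minus_e * o_minus_e / var


def logrank_statistic(surv: SurvivalData, group) -> float:
    """Two-group log-rank chi-square statistic (1 df) for ``group`` vs rest."""
    group = np.asarray(group, dtype=bool)
    if group.shape != surv.time.shape:
        raise ValidationError("group indicator length does not match survival data")
    order = np.argsort(surv.time, kind="stable")
    return _logrank_sorted(surv.time[order], surv.status[order], group[order])
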