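"""Cox proportional-hazards fitting via Newton-Raphson on the partial likelihood.

This is a small, array-oriented fitter specialised for the needs of the
exhaustive interaction scan: designs with very few columns (the high-risk
indicator plus a handful of adjusting covariates) fitted many thousands of
times against a fixed survival outcome. Ties are handled with the Breslow
approximation, and the baseline cumulative hazard is the Breslow estimator,
so in-sample martingale residuals sum to zero exactly.

The survival ordering (sort permutation, tie groups, risk-set boundaries) is
precomputed once in :class:`SurvivalOrder` and shared across fits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import CovariateMatrix, SurvivalData, ValidationError

__all__ = ["SurvivalOrder", "CoxFit", "ConvergenceError", "fit_cox", "martingale_residuals"]


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (non-convergence or flat/monotone likelihood)."""


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


class SurvivalOrder:
    """Precomputed sort/tie/risk-set structure for one survival outcome.

    Attributes are in time-ascending ("sorted") order. ``tie_first[i]`` is the
    first sorted index sharing sorted time ``i``'s value: the risk set at that
    time is ``tie_first[i]..n-1``.
    """

    def __init__(self, time: np.ndarray, status: np.ndarray):
        time = np.asarray(time, float)
        status = np.asarray(status)
        n = len(time)
        self.n = n
        self.order = np.argsort(time, kind="stable")
        self.time_s = time[self.order]
        self.status_s = status[self.order].astype(np.int8)
        # tie groups over sorted times
        new_group = np.empty(n, dtype=bool)
        new_group[0] = True
        new_group[1:] = self.time_s[1:] != self.time_s[:-1]
        self.group_id = np.cumsum(new_group) - 1
        self.group_starts = np.flatnonzero(new_group)
        self.tie_first = self.group_starts[self.group_id]
        self.group_events = np.bincount(
            self.group_id, weights=self.status_s, minlength=len(self.group_starts)
        )
        self.group_times = self.time_s[self.group_starts]
        self.event_pos = np.flatnonzero(self.status_s == 1)
        self.event_first = self.tie_first[self.event_pos]
        self.n_events = int(self.status_s.sum())

    def sort(self, a: np.ndarray) -> np.ndarray:
        """Reorder per-sample rows into time-ascending order."""
        return np.asarray(a)[self.order]

    def unsort(self, a_sorted: np.ndarray) -> np.ndarray:
        out = np.empty_like(a_sorted)
        out[self.order] = a_sorted
        return out


def _loglik(eta_s: np.ndarray, so: SurvivalOrder) -> float:
    c = eta_s.max() if len(eta_s) else 0.0
    w = np.exp(eta_s - c)
    S0 = _revcumsum(w)
    return float(np.sum(eta_s[so.event_pos] - c - np.log(S0[so.event_first])))


def _newton(
    X_s: np.ndarray,
    so: SurvivalOrder,
    beta0: np.ndarray | None = None,
    max_iter: int = 40,
    tol: float = 1e-8,
):
    """Maximize the Breslow partial likelihood. Returns
    (beta, covariance, loglik, converged, n_iter).

    Per iteration, the risk-set sums S0, S1 and the upper triangle of S2 are
    accumulated in a single reversed cumulative sum over a fused matrix.
    """
    n, q = X_s.shape
    beta = np.zeros(q) if beta0 is None else beta0.astype(float).copy()
    ef = so.event_first
    ev = so.event_pos
    iu, ju = np.triu_indices(q)
    XX = X_s[:, iu] * X_s[:, ju]  # (n, q(q+1)/2), shared across iterations
    x_event_sum = X_s[ev].sum(axis=0)
    converged = False
    cov = np.full((q, q), np.nan)
    fused = np.empty((n, 1 + q + len(iu)))
    ll = ll_prev = -np.inf
    prev_beta = beta
    step = None
    halvings = 0
    it = 0
    H = np.full((q, q), np.nan)
    while it < max_iter:
        it += 1
        eta = X_s @ beta
        c = eta.max()
        w = np.exp(eta - c)
        fused[:, 0] = w
        fused[:, 1:1 + q] = w[:, None] * X_s
        fused[:, 1 + q:] = w[:, None] * XX
        A = np.cumsum(fused[::-1], axis=0)[::-1][ef]
        S0 = A[:, 0]
        ll = float((eta[ev] - c).sum() - np.log(S0).sum())
        if step is not None and ll < ll_prev - 1e-12:
            # Newton overshoot: halve the last step and re-evaluate
            halvings += 1
            if halvings > 30:
                return beta, cov, ll, False, it
            step = 0.5 * step
            beta = prev_beta + step
            continue
        halvings = 0
        r1 = A[:, 1:1 + q] / S0[:, None]
        grad = x_event_sum - r1.sum(axis=0)
        Hu = (A[:, 1 + q:] / S0[:, None]).sum(axis=0) - (r1[:, iu] * r1[:, ju]).sum(axis=0)
        H[iu, ju] = Hu
        H[ju, iu] = Hu
        try:
            new_step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, cov, ll, False, it
        if np.abs(new_step).max() < tol:
            # a vanishing Newton step from a nonsingular information matrix:
            # accept it and stop; H changes only at O(tol) from here
            beta = beta + new_step
            converged = True
            break
        prev_beta = beta
        ll_prev = ll
        step = new_step
        beta = beta + step
    if converged:
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            converged = False
    if np.abs(beta).max() > 35:
        # effectively infinite hazard ratio: monotone likelihood
        converged = False
    return beta, cov, ll, converged, it


def _baseline_groups(eta_s: np.ndarray, so: SurvivalOrder):
    """Breslow baseline hazard increments per tie group and cumulative hazard
    evaluated at each sorted subject's observed time."""
    c = eta_s.max() if len(eta_s) else 0.0
    w = np.exp(eta_s - c)
    S0 = _revcumsum(w)
    inc = so.group_events / S0[so.group_starts]  # scaled by e^c implicitly
    cum_g = np.cumsum(inc)
    cumhaz_at_subject = cum_g[so.group_id]  # still scaled; multiply by w not e^eta
    return inc, cum_g, cumhaz_at_subject, w


def _martingale_sorted(eta_s: np.ndarray, so: SurvivalOrder) -> np.ndarray:
    _, _, cumhaz, w = _baseline_groups(eta_s, so)
    return so.status_s - cumhaz * w


@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood fit.

    ``baseline_times``/``baseline_cumhaz`` give the Breslow estimate of the
    cumulative baseline hazard as a right-continuous step function jumping at
    the distinct event times (0 before the first event).
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n_iter: int
    names: list[str] | None = None

    def cumulative_hazard_at(self, t) -> np.ndarray:
        """Evaluate the Breslow baseline cumulative hazard at times ``t``."""
        idx = np.searchsorted(self.baseline_times, np.asarray(t, float), side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz])
        return padded[idx]


def _design(X) -> np.ndarray:
    if isinstance(X, CovariateMatrix):
        return X.values
    X = np.asarray(X, float)
    return X[:, None] if X.ndim == 1 else X


def fit_cox(surv: SurvivalData, X=None, max_iter: int = 40, tol: float = 1e-9) -> CoxFit:
    """Fit a Cox model with Breslow ties; with no covariates the baseline is
    the Nelson-Aalen estimator.

    Raises
    ------
    ValidationError
        No events, dimension mismatch, or a constant (zero-information) column.
    ConvergenceError
        Newton iterations fail to converge (including monotone likelihood).
    """
    if surv.n_events < 1:
        raise ValidationError("Cox fit requires at least one observed event")
    n = len(surv)
    Xv = np.empty((n, 0)) if X is None else _design(X)
    if Xv.shape[0] != n:
        raise ValidationError(f"design has {Xv.shape[0]} rows, survival has {n}")
    so = SurvivalOrder(surv.time, surv.status)
    X_s = so.sort(Xv) if Xv.shape[1] else Xv
    if Xv.shape[1]:
        if np.any(np.ptp(Xv, axis=0) == 0):
            j = int(np.argmax(np.ptp(Xv, axis=0) == 0))
            raise ValidationError(f"covariate column {j} is constant: no information")
        beta, cov, ll, converged, it = _newton(X_s, so, max_iter=max_iter, tol=tol)
        if not converged:
            raise ConvergenceError(
                f"Cox fit did not converge after {it} iterations "
                f"(|beta|max={np.abs(beta).max():.3g}); possible monotone likelihood"
            )
        eta_s = X_s @ beta
    else:
        beta = np.zeros(0)
        cov = np.zeros((0, 0))
        eta_s = np.zeros(n)
        ll = _loglik(eta_s, so)
        it = 0
    # baseline on the true (uncentered) scale
    c = eta_s.max() if n else 0.0
    inc, cum_g, _, _ = _baseline_groups(eta_s, so)
    has_event = so.group_events > 0
    times = so.group_times[has_event]
    cumhaz = cum_g[has_event] * np.exp(-c)
    return CoxFit(beta, cov, ll, times, cumhaz, it)


def martingale_residuals(fit: CoxFit, surv: SurvivalData, X=None) -> np.ndarray:
    """Martingale residuals M_i = status_i - Lambda0(t_i) * exp(beta' x_i).

    For residuals computed on the data the fit was produced from, the Breslow
    construction guarantees sum(M) = 0 up to rounding.
    """
    n = len(surv)
    Xv = np.empty((n, 0)) if X is None else _design(X)
    if Xv.shape[1] != len(fit.coefficients):
        raise ValidationError(
            f"design has {Xv.shape[1]} columns, fit has {len(fit.coefficients)}"
        )
    eta = Xv @ fit.coefficients if Xv.shape[1] else np.zeros(n)
    return surv.status - fit.cumulative_hazard_at(surv.time) * np.exp(eta)
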