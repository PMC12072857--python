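"""Two-parameter logistic fits for partition scoring.

A partition score needs thousands of intercept+slope logistic fits of a
rare binary outcome on rSIG, one per candidate age band.  The solver is a
plain Newton/IRLS iteration on the standardized predictor (relative
log-likelihood tolerance 1e-8, at most 100 iterations).  When the band's
deaths and survivors are separated on rSIG — plausible with a handful of
deaths per band — the maximum-likelihood estimate diverges, so the fit
falls back to Firth's penalized likelihood (Jeffreys-prior score
correction), which always has a finite maximizer; the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["LogisticFit", "fit_logistic_1d"]

_TOL = 1e-8
_MAX_ITER = 100


@dataclass(frozen=True)
class LogisticFit:
    beta: tuple[float, float]  #: (intercept, slope) on the original scale
    llf: float                 #: unpenalized log-likelihood at the estimate
    penalized: bool            #: True if the Firth fallback was used
    converged: bool


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _newton(x: np.ndarray, y: np.ndarray):
    b0 = float(np.log(y.mean() / (1.0 - y.mean())))
    beta = np.array([b0, 0.0])
    ll = _loglik(np.full_like(x, b0), y)
    converged = False
    for _ in range(_MAX_ITER):
        eta = beta[0] + beta[1] * x
        p = expit(eta)
        w = p * (1.0 - p)
        # 2x2 normal equations of the IRLS step
        s0, s1, s2 = w.sum(), (w * x).sum(), (w * x * x).sum()
        r = y - p
        g0, g1 = r.sum(), (r * x).sum()
        det = s0 * s2 - s1 * s1
        if det <= 0 or not np.isfinite(det):
            return beta, ll, False
        step = np.array([(s2 * g0 - s1 * g1) / det, (s0 * g1 - s1 * g0) / det])
        new_beta = beta + step
        new_ll = _loglik(new_beta[0] + new_beta[1] * x, y)
        # step-halving keeps the iteration monotone
        halvings = 0
        while new_ll < ll and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(new_beta[0] + new_beta[1] * x, y)
            halvings += 1
        if abs(new_ll - ll) <= _TOL * (abs(ll) + _TOL):
            beta, ll = new_beta, new_ll
            converged = True
            break
        beta, ll = new_beta, new_ll
    # a diverging slope on a standardized predictor signals separation
    if converged and abs(beta[1]) > 50.0:
        converged = False
    return beta, ll, converged


def _firth(x: np.ndarray, y: np.ndarray):
    beta = np.array([float(np.log((y.mean() + 1e-6) / (1.0 - y.mean() + 1e-6))), 0.0])
    pll = -np.inf
    converged = False
    for _ in range(_MAX_ITER):
        eta = beta[0] + beta[1] * x
        p = expit(eta)
        w = p * (1.0 - p)
        s0, s1, s2 = w.sum(), (w * x).sum(), (w * x * x).sum()
        det = s0 * s2 - s1 * s1
        if det <= 0 or not np.isfinite(det):
            break
        # hat diagonal h_i = w_i * x_i' (X'WX)^{-1} x_i for X = [1, x]
        h = w * (s2 - 2.0 * x * s1 + x * x * s0) / det
        r = y - p + h * (0.5 - p)
        g0, g1 = r.sum(), (r * x).sum()
        step = np.array([(s2 * g0 - s1 * g1) / det, (s0 * g1 - s1 * g0) / det])
        # damp oversized steps for stability near the boundary
        norm = float(np.abs(step).max())
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        new_pll = _loglik(beta[0] + beta[1] * x, y) + 0.5 * np.log(det)
        if abs(new_pll - pll) <= _TOL * (abs(pll) + _TOL):
            converged = True
            pll = new_pll
            break
        pll = new_pll
    return beta, converged


def _separated(x: np.ndarray, y: np.ndarray) -> bool:
    x1, x0 = x[y == 1], x[y == 0]
    return bool(x1.max() < x0.min() or x1.min() > x0.max())


def fit_logistic_1d(x, y) -> LogisticFit:
    """Fit ``P(y=1) = expit(b0 + b1 * x)`` by maximum likelihood.

    Requires both outcome classes present.  Returns coefficients on the
    original predictor scale together with the unpenalized log-likelihood
    at the estimate (used for AIC even when the Firth fallback supplied
    the coefficients, in which case ``penalized`` is True).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D arrays")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both outcome classes must be present")

    mu, sd = float(x.mean()), float(x.std())
    if sd == 0.0:
        # constant predictor: intercept-only model
        b0 = float(np.log(y.mean() / (1.0 - y.mean())))
        return LogisticFit((b0, 0.0), _loglik(np.full_like(x, b0), y), False, True)
    z = (x - mu) / sd

    penalized = _separated(z, y)
    if not penalized:
        beta_z, ll, converged = _newton(z, y)
        if not converged:
            penalized = True
    if penalized:
        beta_z, converged = _firth(z, y)
        ll = _loglik(beta_z[0] + beta_z[1] * z, y)

    slope = beta_z[1] / sd
    intercept = beta_z[0] - beta_z[1] * mu / sd
    return LogisticFit((float(intercept), float(slope)), ll, penalized, converged)
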