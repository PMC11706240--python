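"""Cumulative-Weibull psychometric function and its least-squares fit.

Accuracy as a function of allowed response time t is modeled as

    a(t) = gamma + (1 - gamma - lam) * (1 - exp(-(t / tau) ** beta))

where ``gamma`` is the guess rate (chance accuracy, 1/16 for 16-way
categorization), ``lam`` the lapse rate (errors persisting at unlimited
time), ``tau`` the time scale in milliseconds and ``beta`` the shape.  The
function rises monotonically from gamma at t = 0 to 1 - lam as t grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["WeibullParams", "WeibullFit", "weibull_accuracy", "fit_weibull"]


@dataclass(frozen=True)
class WeibullParams:
    """Parameters of the cumulative Weibull psychometric function."""

    gamma: float = 1.0 / 16.0
    lam: float = 0.0
    tau: float = 1000.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must lie in [0, 1)")
        if not 0 <= self.lam < 0.5:
            raise ValueError("lam must lie in [0, 0.5)")
        if self.gamma + self.lam >= 1:
            raise ValueError("gamma + lam must be < 1")
        if self.tau <= 0 or self.beta <= 0:
            raise ValueError("tau and beta must be positive")


def weibull_accuracy(t_ms, p: WeibullParams):
    """Evaluate the psychometric function at time(s) ``t_ms`` (ms, > 0).

    Accepts a scalar or array; returns the same shape.  t = 0 is allowed and
    returns exactly gamma (the chance anchor).
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_ms must be nonnegative")
    out = p.gamma + (1.0 - p.gamma - p.lam) * (1.0 - np.exp(-((t / p.tau) ** p.beta)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class WeibullFit:
    """Result of fitting the psychometric function to an accuracy curve."""

    params: WeibullParams
    residual: float          # Euclidean norm of accuracy residuals
    converged: bool
    degenerate: bool         # flat curve: tau/beta not identifiable

    def __call__(self, t_ms):
        return weibull_accuracy(t_ms, self.params)


# Fixed multi-start grid: tau factors span the sampled time range, beta
# spans shallow to steep rises.
_TAU_START_FACTORS = (0.5, 1.0, 2.0)
_BETA_STARTS = (0.5, 2.0, 8.0)


def fit_weibull(
    times,
    accuracies,
    *,
    fix_gamma: bool = True,
    gamma: float = 1.0 / 16.0,
    weights=None,
) -> WeibullFit:
    """Bounded least-squares fit of the cumulative Weibull to a SAT curve.

    Parameters
    ----------
    times, accuracies : array-like
        At least three points with strictly positive times; the chance
        anchor at t = 0 must not be included.
    fix_gamma : bool
        Pin the guess rate at ``gamma`` (the task's chance level) rather
        than fitting it.  Default True: with five points per curve a free
        lower asymptote is poorly constrained.
    weights : array-like, optional
        Per-point weights applied to residuals (e.g. inverse variances).
        Default: unweighted.

    Bounds: lam in [0, 0.5], tau in [min(t)/10, 100 max(t)], beta in
    [0.05, 50].  The fit is restarted from a fixed grid of (tau, beta)
    initializations; the smallest residual wins and residual ties go to the
    smaller beta.  A flat curve (accuracy range below 1e-6) is flagged
    degenerate: tau and beta are not identifiable from it.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(accuracies, dtype=float)
    if t.ndim != 1 or t.shape != a.shape:
        raise ValueError("times and accuracies must be 1-D and equally long")
    if t.size < 3:
        raise ValueError("need at least 3 points to fit the Weibull")
    if np.any(t <= 0):
        raise ValueError("times must be positive (drop the chance anchor first)")
    w = np.ones_like(a) if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    degenerate = float(np.ptp(a)) < 1e-6
    tau_bounds = (t.min() / 10.0, 100.0 * t.max())
    beta_bounds = (0.05, 50.0)
    lam_bounds = (0.0, 0.5 - 1e-9)
    gamma_bounds = (0.0, 0.5)

    def unpack(x):
        if fix_gamma:
            lam, tau, beta = x
            g = gamma
        else:
            g, lam, tau, beta = x
        return g, lam, tau, beta

    def resid(x):
        g, lam, tau, beta = unpack(x)
        pred = g + (1.0 - g - lam) * (1.0 - np.exp(-((t / tau) ** beta)))
        return w * (pred - a)

    lo = [lam_bounds[0], tau_bounds[0], beta_bounds[0]]
    hi = [lam_bounds[1], tau_bounds[1], beta_bounds[1]]
    if not fix_gamma:
        lo = [gamma_bounds[0]] + lo
        hi = [gamma_bounds[1]] + hi

    lam0 = float(np.clip(1.0 - a.max(), *lam_bounds))
    best = None
    for tf in _TAU_START_FACTORS:
        for b0 in _BETA_STARTS:
            tau0 = float(np.clip(tf * np.median(t), *tau_bounds))
            x0 = [lam0, tau0, b0]
            if not fix_gamma:
                x0 = [gamma] + x0
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
            cost = float(np.linalg.norm(sol.fun))
            cand = (cost, unpack(sol.x)[3], sol)
            if best is None or cand[0] < best[0] - 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
            ):
                best = cand
    cost, _, sol = best
    g, lam, tau, beta = unpack(sol.x)
    params = WeibullParams(gamma=float(g), lam=float(min(lam, 0.5 - 1e-12)),
                           tau=float(tau), beta=float(beta))
    return WeibullFit(params=params, residual=cost,
                      converged=bool(sol.success), degenerate=degenerate)
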