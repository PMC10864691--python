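"""Univariate Hawkes processes: likelihood, MLE, simulation, goodness of fit.

The conditional intensity of a (marked) Hawkes process on (0, T] is

    lambda(t) = mu + alpha * sum_{i: tau_i < t} m(tau_i) exp(-beta (t - tau_i))

with background rate ``mu`` (optionally a user-supplied function of time),
excitation jump ``alpha`` per unit mark, and exponential decay rate
``beta``.  With ``0 <= alpha < beta`` the process is sub-critical and
self-exciting; ``alpha < 0`` gives self-inhibition, in which case the
likelihood is guarded against negative intensities.

The log-likelihood sum_i log lambda(tau_i) - Lambda(T) is evaluated in
O(n) via the classic recursion A_i = exp(-beta (tau_i - tau_{i-1}))
(A_{i-1} + m(tau_{i-1})), and the compensator Lambda has the closed form
mu*T + (alpha/beta) sum_i m(tau_i)(1 - exp(-beta (T - tau_i))).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np


from .fitresult import FitResult, delta_method_se, numerical_hessian, two_stage_minimize

logger = logging.getLogger(__name__)

__all__ = [
    "EventSeries",
    "HawkesParams",
    "BackgroundFn",
    "hawkes_negloglik",
    "fit_hawkes",
    "jitter_times",
    "simulate_hawkes",
    "gof_transform",
    "derived_quantities",
]


class DuplicateTimesError(ValueError):
    pass


class SupercriticalError(ValueError):
    pass


@dataclass(frozen=True)
class EventSeries:
    """Strictly increasing event times on (0, T] with optional marks."""

    times: np.ndarray
    T: float
    marks: Optional[np.ndarray] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if len(t):
            if t[0] <= 0:
                raise ValueError("event times must be > 0")
            if t[-1] > self.T:
                raise ValueError("event times must be <= T")
            d = np.diff(t)
            if np.any(d < 0):
                raise ValueError("event times must be sorted")
            if np.any(d == 0):
                raise DuplicateTimesError(
                    "tied event times; jitter them first (see jitter_times)"
                )
        if self.marks is not None:
            m = np.asarray(self.marks, dtype=float)
            object.__setattr__(self, "marks", m)
            if len(m) != len(t):
                raise ValueError("marks length must match times")
            if np.any(m <= 0):
                raise ValueError("marks must be positive")

    @property
    def n(self) -> int:
        return len(self.times)

    def mark_values(self) -> np.ndarray:
        return self.marks if self.marks is not None else np.ones(self.n)


@dataclass(frozen=True)
class HawkesParams:
    mu: float
    alpha: float
    beta: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.mu, self.alpha, self.beta])):
            raise ValueError("parameters must be finite")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def branching_ratio(self) -> float:
        return self.alpha / self.beta


@dataclass(frozen=True)
class BackgroundFn:
    """Time-varying background rate mu(t; theta) with exact antiderivative.

    ``rate(t, theta)`` must be nonnegative on [0, T]; ``integral(t, theta)``
    is its antiderivative with integral(0) = 0.  ``theta0`` are starting
    values, optimized jointly with the Hawkes parameters; ``bounds`` are
    per-component (lo, hi) pairs on theta, None for unbounded.
    """

    rate: Callable[[np.ndarray, np.ndarray], np.ndarray]
    integral: Callable[[float, np.ndarray], float]
    theta0: np.ndarray = field(default_factory=lambda: np.array([]))
    bounds: Optional[list] = None
    names: Optional[list] = None


def _excitation(times: np.ndarray, marks: np.ndarray, beta: float) -> np.ndarray:
    """A_i = sum_{j<i} m_j exp(-beta (t_i - t_j)) via the O(n) recursion."""
    from ._kernels import excitation_recursion

    return excitation_recursion(
        np.ascontiguousarray(times, dtype=np.float64),
        np.ascontiguousarray(marks, dtype=np.float64),
        float(beta),
    )


def hawkes_negloglik(
    series: EventSeries,
    params: HawkesParams,
    background: Optional[BackgroundFn] = None,
    theta: Optional[np.ndarray] = None,
) -> float:
    """Negative log-likelihood -[sum_i log lambda(tau_i) - Lambda(T)].

    Returns +inf (with a log record) if any event intensity is
    nonpositive, as can happen with inhibition (alpha < 0).
    """
    t, T = series.times, series.T
    m = series.mark_values()
    A = _excitation(t, m, params.beta)
    if background is None:
        lam = params.mu + params.alpha * A
        bg_int = params.mu * T
    else:
        th = np.asarray(theta if theta is not None else background.theta0, float)
        lam = background.rate(t, th) + params.alpha * A
        bg_int = background.integral(T, th)
    if series.n and np.any(lam <= 0):
        logger.info("nonpositive intensity at an event time; NLL set to +inf")
        return np.inf
    comp = bg_int + (params.alpha / params.beta) * np.sum(
        m * (1.0 - np.exp(-params.beta * (T - t)))
    )
    return float(comp - np.sum(np.log(lam)) if series.n else comp)


def jitter_times(times, resolution: float, seed: int) -> np.ndarray:
    """Break ties by adding Uniform(0, resolution) noise and re-sorting.

    Deterministic given the seed; guarantees strictly increasing output.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rng = np.random.default_rng(seed)
    t = np.sort(np.asarray(times, dtype=float) + rng.uniform(0, resolution, len(times)))
    # astronomically unlikely residual ties: nudge by tiny epsilons
    while np.any(np.diff(t) == 0):
        t += rng.uniform(0, resolution * 1e-12, len(t))
        t.sort()
    return t


def _pack(params: HawkesParams, allow_inhibition: bool) -> np.ndarray:
    if allow_inhibition:
        return np.array([np.log(params.mu), params.alpha, np.log(params.beta)])
    frac = params.alpha / params.beta
    frac = min(max(frac, 1e-8), 1 - 1e-8)
    return np.array([np.log(params.mu), np.log(frac / (1 - frac)), np.log(params.beta)])


def _unpack(x: np.ndarray, allow_inhibition: bool) -> HawkesParams:
    beta = np.exp(x[2])
    if allow_inhibition:
        alpha = x[1]
    else:
        alpha = beta / (1.0 + np.exp(-x[1]))
    return HawkesParams(mu=np.exp(x[0]), alpha=alpha, beta=beta)


def fit_hawkes(
    series: EventSeries,
    init: HawkesParams,
    allow_inhibition: bool = False,
    background: Optional[BackgroundFn] = None,
) -> FitResult:
    """Maximum-likelihood fit of the (marked) Hawkes process.

    Optimization runs on an unconstrained internal scale: log mu (dropped
    when a background function supplies mu(t)), logit(alpha/beta) so that
    0 < alpha < beta by construction, and log beta.  With
    ``allow_inhibition`` alpha is left free and nonpositive intensities
    are rejected by an infinite penalty.  Standard errors come from the
    observed information on the internal scale, mapped to the natural
    scale by the delta method.
    """
    if series.n == 0:
        raise ValueError("cannot fit a Hawkes process to an empty series")

    nbg = len(background.theta0) if background is not None else 0
    if background is None:
        x0 = _pack(init, allow_inhibition)

        def nll(x):
            try:
                p = _unpack(x, allow_inhibition)
            except (ValueError, FloatingPointError):
                return np.inf
            return hawkes_negloglik(series, p)

    else:
        core0 = _pack(init, allow_inhibition)
        x0 = np.concatenate([core0[1:], np.asarray(background.theta0, float)])

        def nll(x):
            try:
                p = _unpack(np.concatenate([[0.0], x[:2]]), allow_inhibition)
            except (ValueError, FloatingPointError):
                return np.inf
            th = x[2:]
            if background.bounds is not None:
                for v, (lo, hi) in zip(th, background.bounds):
                    if (lo is not None and v < lo) or (hi is not None and v > hi):
                        return np.inf
            # mu is replaced by the background function entirely
            p = HawkesParams(mu=1e-300, alpha=p.alpha, beta=p.beta)
            return hawkes_negloglik(series, p, background=background, theta=th)

    xhat, fun, nfev, converged = two_stage_minimize(nll, x0)
    H = numerical_hessian(nll, xhat)

    if background is None:
        phat = _unpack(xhat, allow_inhibition)
        names = ["mu", "alpha", "beta"]
        est = np.array([phat.mu, phat.alpha, phat.beta])

        def natural(x):
            p = _unpack(x, allow_inhibition)
            return np.array([p.mu, p.alpha, p.beta])

    else:
        phat = _unpack(np.concatenate([[0.0], xhat[:2]]), allow_inhibition)
        bnames = background.names or [f"theta{i}" for i in range(nbg)]
        names = ["alpha", "beta", *bnames]
        est = np.array([phat.alpha, phat.beta, *xhat[2:]])

        def natural(x):
            p = _unpack(np.concatenate([[0.0], x[:2]]), allow_inhibition)
            return np.array([p.alpha, p.beta, *x[2:]])

    se = delta_method_se(H, natural, xhat)
    return FitResult(
        model="hawkes",
        estimates=dict(zip(names, est)),
        std_errors=dict(zip(names, se)),
        loglik=-fun,
        converged=converged,
        n_evals=nfev,
        internal=dict(zip([f"x{i}" for i in range(len(xhat))], xhat)),
    )


def simulate_hawkes(
    params: HawkesParams,
    T: float,
    seed: int,
    background: Optional[BackgroundFn] = None,
    theta: Optional[np.ndarray] = None,
    mark_sampler: Optional[Callable] = None,
) -> EventSeries:
    """Exact simulation by Ogata thinning; reproducible given the seed."""
    if params.alpha >= params.beta and params.alpha > 0:
        raise SupercriticalError("alpha >= beta: supercritical process")
    rng = np.random.default_rng(seed)
    if background is not None:
        th = np.asarray(theta if theta is not None else background.theta0, float)
        grid = np.linspace(0, T, 4096)
        mu_max = float(np.max(background.rate(grid, th))) * 1.000001

        def mu_at(t):
            return float(background.rate(np.array([t]), th)[0])

    else:
        mu_max = params.mu

        def mu_at(t):
            return params.mu

    times, marks = [], []
    t, excite = 0.0, 0.0  # excite = sum m_j exp(-beta (t - tau_j))
    while True:
        lam_bar = mu_max + max(params.alpha, 0.0) * excite
        if lam_bar <= 0:
            break
        t_new = t + rng.exponential(1.0 / lam_bar)
        if t_new > T:
            break
        excite *= np.exp(-params.beta * (t_new - t))
        t = t_new
        lam = mu_at(t) + params.alpha * excite
        if rng.uniform() * lam_bar <= lam:
            m = float(mark_sampler(rng)) if mark_sampler is not None else 1.0
            times.append(t)
            marks.append(m)
            excite += m
    times = np.asarray(times)
    marks = np.asarray(marks) if mark_sampler is not None else None
    return EventSeries(times=times, T=T, marks=marks)


def gof_transform(
    series: EventSeries,
    params: HawkesParams,
    background: Optional[BackgroundFn] = None,
    theta: Optional[np.ndarray] = None,
):
    """Random-time-change residuals: Lambda(tau_i) and their increments.

    Under the true model the increments are i.i.d. Exp(1); a KS test of
    them against the unit exponential is the standard goodness-of-fit
    diagnostic for a fitted Hawkes process.
    """
    t = series.times
    m = series.mark_values()
    A = _excitation(t, m, params.beta)
    # Lambda(t_i) = BG(t_i) + (alpha/beta) sum_{j<i} m_j (1 - exp(-beta(t_i - t_j)))
    #             = BG(t_i) + (alpha/beta) (sum_{j<i} m_j - A_i)
    cum_m = np.concatenate([[0.0], np.cumsum(m)[:-1]])
    if background is None:
        bg = params.mu * t
    else:
        th = np.asarray(theta if theta is not None else background.theta0, float)
        bg = np.array([background.integral(ti, th) for ti in t])
    Lam = bg + (params.alpha / params.beta) * (cum_m - A)
    gaps = np.diff(np.concatenate([[0.0], Lam]))
    return Lam, gaps


def derived_quantities(fit, T: float) -> dict:
    """Interpretable summaries of a fitted self-exciting Hawkes model.

    - expected_background: mu*T, the expected number of immigrant events;
    - triggered_per_event: the branching ratio alpha/beta;
    - descendants_per_event: beta/(beta-alpha), total cluster size per
      immigrant including itself;
    - decay_time: 1/beta, the e-folding time of the self-excitation.
    """
    est = fit.estimates if isinstance(fit, FitResult) else fit
    mu, alpha, beta = est["mu"], est["alpha"], est["beta"]
    if not beta > alpha:
        raise ValueError("derived quantities require alpha < beta")
    return {
        "expected_background": mu * T,
        "triggered_per_event": alpha / beta,
        "descendants_per_event": beta / (beta - alpha),
        "decay_time": 1.0 / beta,
    }
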