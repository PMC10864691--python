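"""Hot inner loops for Hawkes-type likelihoods, JIT-compiled when possible.

All recursions here are O(n); the numba versions exist purely for speed
on long series and compute bit-identical results to the pure-Python
fallbacks (same operation order).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def excitation_recursion(times, marks, beta):
    """A_i = sum_{j<i} m_j exp(-beta (t_i - t_j))."""
    n = times.shape[0]
    A = np.zeros(n)
    for i in range(1, n):
        A[i] = np.exp(-beta * (times[i] - times[i - 1])) * (A[i - 1] + marks[i - 1])
    return A


@njit(cache=True)
def multi_excitation(times, streams, n_streams, betas):
    """A[i, j, k] collapsed: returns E of shape (n, N, N) is wasteful; instead
    returns B of shape (n, N, N) reduced to per-event contributions.

    B[i, j, k] = sum over previous events i' of stream k of
    exp(-beta_j (t_i - t_{i'})); computed by per-(j,k) recursions.
    """
    n = times.shape[0]
    N = n_streams
    B = np.zeros((n, N, N))
    state = np.zeros((N, N))  # state[j, k]
    tprev = 0.0
    for i in range(n):
        dt = times[i] - tprev
        for j in range(N):
            dec = np.exp(-betas[j] * dt)
            for k in range(N):
                state[j, k] *= dec
        for j in range(N):
            for k in range(N):
                B[i, j, k] = state[j, k]
        k_i = streams[i]
        for j in range(N):
            state[j, k_i] += 1.0
        tprev = times[i]
    return B


@njit(cache=True)
def st_log_intensities(times, x, y, mu_at_events, alpha, beta,
                       sxx, sxy, syy, time_dependent, horizon):
    """log lambda(s_i, t_i) for the spatiotemporal self-exciting model.

    The triggering kernel is a bivariate normal density in the spatial
    displacement with covariance [[sxx, sxy], [sxy, syy]], optionally
    scaled by the elapsed time.  Events further back than ``horizon`` in
    time contribute less than exp(-beta*horizon) and are skipped.
    """
    n = times.shape[0]
    out = np.empty(n)
    det0 = sxx * syy - sxy * sxy
    for i in range(n):
        lam = mu_at_events[i]
        j = i - 1
        while j >= 0 and times[i] - times[j] <= horizon:
            dt = times[i] - times[j]
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if time_dependent:
                det = det0 * dt * dt
                a = syy * dt
                b = -sxy * dt
                c = sxx * dt
            else:
                det = det0
                a = syy
                b = -sxy
                c = sxx
            quad = (a * dx * dx + 2.0 * b * dx * dy + c * dy * dy) / det
            dens = np.exp(-0.5 * quad) / (2.0 * np.pi * np.sqrt(det))
            lam += alpha * np.exp(-beta * dt) * dens
            j -= 1
        if lam <= 0.0:
            out[i] = -np.inf
        else:
            out[i] = np.log(lam)
    return out
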