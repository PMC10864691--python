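"""Shared fit-result container and curvature-based standard errors."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["FitResult", "numerical_hessian", "delta_method_se"]


@dataclass
class FitResult:
    """Parameter estimates on the natural scale plus fit metadata.

    ``std_errors`` are delta-method standard errors derived from the
    observed information (negative Hessian of the log-likelihood) on the
    unconstrained internal scale; a NaN standard error marks a parameter
    whose curvature was not numerically positive-definite.
    """

    model: str
    estimates: dict
    std_errors: dict
    loglik: float
    converged: bool
    n_evals: int = 0
    internal: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(d):
            return {k: (None if v is None or not np.isfinite(v) else float(v))
                    for k, v in d.items()}

        return {
            "model": self.model,
            "estimates": clean(self.estimates),
            "std_errors": clean(self.std_errors),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_evals": int(self.n_evals),
            "internal": clean(self.internal),
            **(
                {"extra": {k: v for k, v in self.extra.items() if not k.startswith("_")}}
                if self.extra
                else {}
            ),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def two_stage_minimize(nll: Callable, x0: np.ndarray, maxiter_nm: int = 6000):
    """Nelder-Mead polish followed by BFGS refinement.

    BFGS with numerical gradients often stops with a precision-loss flag
    when it is already at the optimum; the fit counts as converged if
    either stage succeeded and the final value is the best seen.
    """
    from scipy import optimize

    nm = optimize.minimize(nll, x0, method="Nelder-Mead",
                           options={"maxiter": maxiter_nm, "xatol": 1e-9, "fatol": 1e-9})
    bf = optimize.minimize(nll, nm.x, method="BFGS",
                           options={"gtol": 1e-8, "maxiter": 500})
    if bf.fun <= nm.fun:
        x, fun = bf.x, bf.fun
    else:
        x, fun = nm.x, nm.fun
    converged = bool((bf.success or nm.success) and np.isfinite(fun))
    return x, float(fun), int(nm.nfev + bf.nfev), converged


def numerical_hessian(f: Callable, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function.

    Step sizes scale with |x| so the same relative accuracy holds for
    log-scale parameters of very different magnitude.
    """
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def delta_method_se(
    hessian: np.ndarray,
    natural: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """SEs of natural-scale parameters eta(x) given the internal Hessian.

    cov(eta) = J cov(x) J^T with cov(x) = H^{-1} (H the observed
    information, i.e. the Hessian of the *negative* log-likelihood) and J
    the Jacobian of the internal-to-natural map.  Returns NaN for all
    components when H is not positive definite.
    """
    x = np.asarray(x, dtype=float)
    p = len(natural(x))
    try:
        cov = np.linalg.inv(hessian)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    J = np.empty((p, len(x)))
    for j in range(len(x)):
        e = np.zeros(len(x))
        e[j] = h[j]
        J[:, j] = (natural(x + e) - natural(x - e)) / (2 * h[j])
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    se = np.sqrt(np.where(var > 0, var, np.nan))
    if np.any(np.diag(cov) <= 0):
        se[:] = np.nan
    return se
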