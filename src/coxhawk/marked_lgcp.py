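"""Marked log-Gaussian Cox processes: joint model of points and marks.

The point pattern follows the LGCP of :mod:`coxhawk.lgcp`; each point
additionally carries a mark whose distribution depends on a mark-specific
linear predictor evaluated *at the point location*:

    Lambda(s) = exp(X beta + G(s))
    M(s)      = f^{-1}(X beta_m + G_m(s) + alpha_m G(s))

The loading alpha_m links the mark to the point-process field (the
preferential-sampling construction); G_m is an optional mark-specific
field capturing residual spatial structure in the marks.  Supported mark
families and links:

    normal   — identity link, fixed sd sigma_j
    poisson  — exp link
    binomial — inverse-logit link on the success probability, fixed trials
    gamma    — exp link on the shape, fixed log scale

The point process uses the binned dual-cell likelihood while the mark
likelihood is evaluated at the exact point locations through barycentric
projection of the node fields; the latent fields are integrated out by a
joint Laplace approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.special import expit, gammaln, polygamma, digamma

from .fitresult import FitResult, delta_method_se, numerical_hessian
from .lgcp import PointPattern, _logdet_sparse, bin_points
from .spde import (
    Domain,
    Mesh,
    SpdeParams,
    barycentric_projector,
    dual_mesh_weights,
    fem_matrices,
    spde_precision,
)

__all__ = ["MarkFamily", "mlgcp_joint_nll", "fit_mlgcp", "simulate_mlgcp"]

METHOD_CODES = {0: "normal", 1: "poisson", 2: "binomial", 3: "gamma"}


@dataclass(frozen=True)
class MarkFamily:
    """Mark distribution with its link and fixed auxiliary parameters."""

    name: str
    sigma: Optional[float] = None  # normal
    trials: Optional[float] = None  # binomial
    log_scale: Optional[float] = None  # gamma

    def __post_init__(self):
        if self.name not in METHOD_CODES.values():
            raise ValueError(f"unknown mark family {self.name!r}")
        if self.name == "normal" and self.sigma is None:
            raise ValueError("normal marks require the fixed sd `sigma`")
        if self.name == "binomial" and self.trials is None:
            raise ValueError("binomial marks require the fixed `trials`")
        if self.name == "gamma" and self.log_scale is None:
            raise ValueError("gamma marks require the fixed `log_scale`")

    @classmethod
    def from_code(cls, code: int, **aux) -> "MarkFamily":
        return cls(name=METHOD_CODES[int(code)], **aux)

    def nll(self, marks: np.ndarray, zeta: np.ndarray) -> float:
        """Negative log-likelihood of the marks given the predictor zeta."""
        m = marks
        z = np.clip(zeta, -500, 500)
        if self.name == "normal":
            s2 = self.sigma**2
            return float(np.sum(0.5 * np.log(2 * np.pi * s2) + (m - z) ** 2 / (2 * s2)))
        if self.name == "poisson":
            return float(np.sum(np.exp(z) - m * z + gammaln(m + 1)))
        if self.name == "binomial":
            ntr = self.trials
            # -log C(n,m) + m*softplus(-z)... stable Bernoulli/binomial NLL
            lc = gammaln(ntr + 1) - gammaln(m + 1) - gammaln(ntr - m + 1)
            return float(np.sum(-lc + ntr * np.logaddexp(0.0, z) - m * z))
        # gamma: shape = exp(z), fixed scale
        shape = np.exp(z)
        scale = np.exp(self.log_scale)
        return float(
            np.sum(
                -(shape - 1) * np.log(m)
                + m / scale
                + gammaln(shape)
                + shape * self.log_scale
            )
        )

    def d1_d2(self, marks: np.ndarray, zeta: np.ndarray):
        """First and second derivatives of the per-point NLL in zeta.

        The second derivative is floored at a small positive value so the
        inner Newton curvature stays positive definite (only the gamma
        family can produce locally nonconvex terms).
        """
        m = marks
        z = np.clip(zeta, -500, 500)
        if self.name == "normal":
            s2 = self.sigma**2
            return (z - m) / s2, np.full_like(z, 1.0 / s2)
        if self.name == "poisson":
            ez = np.exp(z)
            return ez - m, ez
        if self.name == "binomial":
            p = expit(z)
            return self.trials * p - m, np.maximum(self.trials * p * (1 - p), 1e-12)
        shape = np.exp(z)
        d1 = shape * (-np.log(m) + digamma(shape) + self.log_scale)
        d2 = d1 + shape**2 * polygamma(1, shape)
        return d1, np.maximum(d2, 1e-8)

    def mean(self, zeta: np.ndarray) -> np.ndarray:
        if self.name == "normal":
            return zeta
        if self.name == "poisson":
            return np.exp(zeta)
        if self.name == "binomial":
            return self.trials * expit(zeta)
        return np.exp(zeta) * np.exp(self.log_scale)  # shape * scale

    def sample(self, zeta: np.ndarray, rng) -> np.ndarray:
        if self.name == "normal":
            return rng.normal(zeta, self.sigma)
        if self.name == "poisson":
            return rng.poisson(np.exp(np.clip(zeta, -500, 30))).astype(float)
        if self.name == "binomial":
            return rng.binomial(int(self.trials), expit(zeta)).astype(float)
        return rng.gamma(np.exp(np.clip(zeta, -500, 30)), np.exp(self.log_scale))


def mlgcp_joint_nll(
    eta_pp: np.ndarray,
    zeta_fixed: np.ndarray,
    alpha_m: float,
    g: np.ndarray,
    gm: Optional[np.ndarray],
    counts: np.ndarray,
    weights: np.ndarray,
    marks: np.ndarray,
    family: MarkFamily,
    A: sparse.csr_matrix,
    Q: sparse.csc_matrix,
    Qm: Optional[sparse.csc_matrix] = None,
    logdets: Optional[tuple] = None,
) -> float:
    """Joint NLL of counts, marks, and the latent field(s).

    ``eta_pp`` is the point-process fixed predictor per node,
    ``zeta_fixed`` the mark fixed predictor per node; the mark predictor
    at the points is A (zeta_fixed + g_m + alpha_m g).
    """
    y = np.atleast_2d(counts).ravel()
    w = np.broadcast_to(weights, y.shape)
    eta = eta_pp + g
    with np.errstate(over="raise"):
        try:
            pois = float(np.sum(y * eta - w * np.exp(eta)))
        except FloatingPointError:
            return np.inf
    node_pred = zeta_fixed + alpha_m * g + (gm if gm is not None else 0.0)
    zeta = A @ node_pred
    mark_nll = family.nll(marks, zeta)
    ld_Q = logdets[0] if logdets else _logdet_sparse(Q)
    out = -pois + mark_nll + 0.5 * g @ (Q @ g) - 0.5 * ld_Q + 0.5 * len(g) * np.log(2 * np.pi)
    if gm is not None:
        ld_Qm = logdets[1] if logdets else _logdet_sparse(Qm)
        out += 0.5 * gm @ (Qm @ gm) - 0.5 * ld_Qm + 0.5 * len(gm) * np.log(2 * np.pi)
    return float(out)


def _inner_newton_marked(
    eta_pp, zeta_fixed, alpha_m, counts, weights, marks, family, A, Q, Qm,
    u0=None, tol: float = 1e-8, max_iter: int = 100,
):
    """Newton over the stacked latent vector u = [g, g_m]."""
    M = Q.shape[0]
    with_gm = Qm is not None
    dim = 2 * M if with_gm else M
    u = np.zeros(dim) if u0 is None else u0.copy()
    y = np.atleast_2d(counts).ravel()
    w = np.asarray(weights, dtype=float)
    At = A.T.tocsr()

    def split(u):
        return (u[:M], u[M:]) if with_gm else (u, None)

    def value(u):
        g, gm = split(u)
        eta = eta_pp + g
        zeta = A @ (zeta_fixed + alpha_m * g + (gm if gm is not None else 0.0))
        v = float(-(y @ eta) + np.sum(w * np.exp(np.clip(eta, -700, 700)))
                  + family.nll(marks, zeta) + 0.5 * g @ (Q @ g))
        if with_gm:
            v += 0.5 * gm @ (Qm @ gm)
        return v

    f = value(u)
    for _ in range(max_iter):
        g, gm = split(u)
        eta = eta_pp + g
        mu = w * np.exp(np.clip(eta, -700, 700))
        zeta = A @ (zeta_fixed + alpha_m * g + (gm if gm is not None else 0.0))
        d1, d2 = family.d1_d2(marks, zeta)
        grad_g = -(y - mu) + Q @ g + alpha_m * (At @ d1)
        AtDA = At @ sparse.diags(d2) @ A
        H_gg = Q + sparse.diags(mu) + (alpha_m**2) * AtDA
        if with_gm:
            grad_gm = Qm @ gm + At @ d1
            grad = np.concatenate([grad_g, grad_gm])
            H = sparse.bmat(
                [[H_gg, alpha_m * AtDA], [alpha_m * AtDA, Qm + AtDA]], format="csc"
            )
        else:
            grad = grad_g
            H = H_gg.tocsc()
        gnorm = float(np.linalg.norm(grad, ord=np.inf))
        if gnorm < tol:
            break
        lu = splu(H)
        step = lu.solve(grad)
        s = 1.0
        for _ in range(60):
            u_new = u - s * step
            f_new = value(u_new)
            if f_new <= f + 1e-12:
                break
            s *= 0.5
        else:
            raise RuntimeError(f"marked inner Newton line search failed (|grad|={gnorm:.2e})")
        u, f = u_new, f_new
    else:
        raise RuntimeError(f"marked inner Newton did not converge (|grad|={gnorm:.2e})")
    # curvature at the mode
    g, gm = split(u)
    eta = eta_pp + g
    mu = w * np.exp(np.clip(eta, -700, 700))
    zeta = A @ (zeta_fixed + alpha_m * g + (gm if gm is not None else 0.0))
    _, d2 = family.d1_d2(marks, zeta)
    AtDA = At @ sparse.diags(d2) @ A
    H_gg = Q + sparse.diags(mu) + (alpha_m**2) * AtDA
    if with_gm:
        H = sparse.bmat(
            [[H_gg, alpha_m * AtDA], [alpha_m * AtDA, Qm + AtDA]], format="csc"
        )
    else:
        H = H_gg.tocsc()
    return u, H


def fit_mlgcp(
    pattern: PointPattern,
    marks: np.ndarray,
    domain: Domain,
    mesh: Mesh,
    family: MarkFamily,
    init: Optional[dict] = None,
    fields: int = 1,
    covariates: Optional[np.ndarray] = None,
    pp_covariates: Optional[list] = None,
    marks_covariates: Optional[list] = None,
    shared_spde: bool = True,
) -> FitResult:
    """Joint Laplace-MLE of a marked LGCP.

    ``fields=1`` includes the mark-specific field G_m; ``fields=0`` drops
    it.  ``covariates`` is an (M, q) node-level matrix; the 1-based index
    lists ``pp_covariates`` / ``marks_covariates`` pick which columns
    enter each linear predictor (both get an intercept regardless).
    """
    marks = np.asarray(marks, dtype=float)
    if len(marks) != pattern.n:
        raise ValueError("marks must align with point locations")
    M = mesh.node_count
    w = dual_mesh_weights(mesh, domain).w
    counts = bin_points(mesh, pattern).ravel()
    A = barycentric_projector(mesh, pattern.locs)
    fem = fem_matrices(mesh)

    def design(idx):
        cols = [np.ones(M)]
        if idx and covariates is not None:
            cov = np.atleast_2d(covariates.T).T
            cols += [cov[:, i - 1] for i in idx]
        return np.column_stack(cols)

    X_pp = design(pp_covariates)
    X_m = design(marks_covariates)
    p, pm = X_pp.shape[1], X_m.shape[1]
    with_gm = fields == 1

    init = init or {}
    beta0 = init.get("beta0", np.log(max(pattern.n, 1) / domain.area))
    diam = float(np.hypot(*np.ptp(mesh.nodes, axis=0)))
    sp0 = SpdeParams.from_range_sigma(init.get("range", 0.2 * diam), init.get("sigma", 1.0))
    betam0 = init.get("beta0_m")
    if betam0 is None:
        mbar = float(np.mean(marks))
        if family.name == "poisson":
            betam0 = np.log(max(mbar, 1e-3))
        elif family.name == "binomial":
            pbar = np.clip(mbar / family.trials, 1e-3, 1 - 1e-3)
            betam0 = float(np.log(pbar / (1 - pbar)))
        elif family.name == "gamma":
            betam0 = float(np.log(max(mbar, 1e-3)) - family.log_scale)
        else:
            betam0 = mbar
    theta0 = np.concatenate(
        [
            [beta0], np.zeros(p - 1),
            [betam0], np.zeros(pm - 1),
            [init.get("alpha_m", 0.0)],
            [np.log(sp0.kappa), np.log(sp0.tau)],
            [np.log(sp0.kappa), np.log(sp0.tau)] if with_gm else [],
        ]
    )

    state = {"u": None}

    def unpack(theta):
        beta = theta[:p]
        beta_m = theta[p : p + pm]
        am = theta[p + pm]
        k1, t1 = np.exp(theta[p + pm + 1]), np.exp(theta[p + pm + 2])
        Q = spde_precision(SpdeParams(k1, t1), fem)
        Qm = None
        if with_gm:
            k2, t2 = np.exp(theta[p + pm + 3]), np.exp(theta[p + pm + 4])
            Qm = spde_precision(SpdeParams(k2, t2), fem)
        return beta, beta_m, am, Q, Qm

    def nll(theta):
        try:
            beta, beta_m, am, Q, Qm = unpack(theta)
            u, H = _inner_newton_marked(
                X_pp @ beta, X_m @ beta_m, am, counts, w, marks, family, A, Q, Qm,
                u0=state["u"],
            )
        except (RuntimeError, FloatingPointError, ValueError):
            return np.inf
        state["u"] = u
        g = u[:M]
        gm = u[M:] if with_gm else None
        joint = mlgcp_joint_nll(
            X_pp @ beta, X_m @ beta_m, am, g, gm, counts, w, marks, family, A, Q, Qm
        )
        return joint + 0.5 * _logdet_sparse(H) - 0.5 * len(u) * np.log(2 * np.pi)

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 3000, "xatol": 1e-4, "fatol": 1e-6})
    that = res.x

    names = (
        [f"beta{i}" for i in range(p)]
        + [f"beta{i}_m" for i in range(pm)]
        + ["alpha_m", "range", "sigma"]
        + (["range_m", "sigma_m"] if with_gm else [])
    )

    def natural(theta):
        s1 = SpdeParams(np.exp(theta[p + pm + 1]), np.exp(theta[p + pm + 2]))
        out = [*theta[: p + pm + 1], s1.range, s1.sigma]
        if with_gm:
            s2 = SpdeParams(np.exp(theta[p + pm + 3]), np.exp(theta[p + pm + 4]))
            out += [s2.range, s2.sigma]
        return np.array(out)

    est = natural(that)
    Hout = numerical_hessian(nll, that, rel_step=1e-3)
    se = delta_method_se(Hout, natural, that)
    beta, beta_m, am, Q, Qm = unpack(that)
    uhat, _ = _inner_newton_marked(
        X_pp @ beta, X_m @ beta_m, am, counts, w, marks, family, A, Q, Qm, u0=state["u"]
    )
    return FitResult(
        model="mlgcp",
        estimates=dict(zip(names, est)),
        std_errors=dict(zip(names, se)),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_evals=int(res.nfev),
        internal=dict(zip([f"theta{i}" for i in range(len(that))], that)),
        extra={
            "field_mode": uhat[:M].tolist(),
            "mark_field_mode": uhat[M:].tolist() if with_gm else None,
        },
    )


def simulate_mlgcp(
    spde_params: SpdeParams,
    beta: np.ndarray,
    beta_m: np.ndarray,
    alpha_m: float,
    family: MarkFamily,
    mesh: Mesh,
    domain: Domain,
    seed: int,
    spde_params_m: Optional[SpdeParams] = None,
    X_pp: Optional[np.ndarray] = None,
    X_m: Optional[np.ndarray] = None,
):
    """Simulate points from the LGCP and marks at the point locations.

    Returns (pattern, marks, g, g_m); the mark-specific field is drawn
    only when ``spde_params_m`` is given.
    """
    from scipy.linalg import solve_triangular

    rng = np.random.default_rng(seed)
    M = mesh.node_count
    fem = fem_matrices(mesh)
    Q = spde_precision(spde_params, fem)
    L = np.linalg.cholesky(Q.toarray())
    g = solve_triangular(L.T, rng.standard_normal(M), lower=False)
    gm = np.zeros(M)
    if spde_params_m is not None:
        Qm = spde_precision(spde_params_m, fem)
        Lm = np.linalg.cholesky(Qm.toarray())
        gm = solve_triangular(Lm.T, rng.standard_normal(M), lower=False)

    from .lgcp import _uniform_in_polygon
    from .spde import dual_mesh_cells

    cells = dual_mesh_cells(mesh, domain)
    w = np.array([0.0 if c is None else c.area for c in cells])
    X_pp = np.ones((M, 1)) if X_pp is None else X_pp
    X_m = np.ones((M, 1)) if X_m is None else X_m
    eta = X_pp @ np.atleast_1d(beta) + g
    counts = rng.poisson(w * np.exp(np.clip(eta, -700, 50)))
    pts = []
    for k in range(M):
        if counts[k] and cells[k] is not None:
            pts.append(_uniform_in_polygon(cells[k], counts[k], rng))
    locs = np.vstack(pts) if pts else np.empty((0, 2))
    pattern = PointPattern(locs=locs)
    A = barycentric_projector(mesh, locs) if len(locs) else None
    if A is None:
        return pattern, np.empty(0), g, gm
    zeta = A @ (X_m @ np.atleast_1d(beta_m) + gm + alpha_m * g)
    marks = family.sample(zeta, rng)
    return pattern, marks, g, gm
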