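"""Log-Gaussian Cox processes on the SPDE mesh, fitted by Laplace-MLE.

The point process intensity is Lambda(s) = exp(X beta + G(s)) with G a
Matérn GMRF on the mesh nodes.  The likelihood is discretised onto the
dual mesh: each node k carries the count y_k of points falling in its
Voronoi cell and a Poisson likelihood with mean w_k exp(eta_k), where
w_k is the cell area (clipped to the domain) and eta_k the linear
predictor at the node.  Nodes with w_k = 0 (e.g. in an outer mesh
buffer) enter only through the field prior.

The marginal likelihood of the hyperparameters integrates the latent
field out by a Laplace approximation: an inner Newton step finds the
conditional mode g-hat (the inner problem is convex in g), and the
Gaussian curvature correction 1/2 log det H(g-hat) completes the
approximation.  Spatiotemporal models couple per-knot fields through a
stationary AR(1) with coefficient rho, standardised so each knot keeps
the Matérn marginal variance; the joint precision is the Kronecker
product Q_time(rho) (x) Q_space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

from .fitresult import FitResult, delta_method_se, numerical_hessian
from .spde import (
    Domain,
    DualWeights,
    Mesh,
    SpdeParams,
    dual_mesh_cells,
    fem_matrices,
    spde_precision,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PointPattern",
    "bin_points",
    "ar1_precision",
    "lgcp_joint_nll",
    "laplace_marginal_nll",
    "fit_lgcp",
    "expected_total",
    "simulate_lgcp",
    "get_fields",
]


class InnerNewtonError(RuntimeError):
    pass


@dataclass(frozen=True)
class PointPattern:
    """2-D locations inside a domain, with optional times/knots/marks."""

    locs: np.ndarray
    times: Optional[np.ndarray] = None
    time_knot: Optional[np.ndarray] = None  # 1-based knot index per point
    marks: Optional[np.ndarray] = None

    def __post_init__(self):
        locs = np.atleast_2d(np.asarray(self.locs, dtype=float))
        object.__setattr__(self, "locs", locs)
        if locs.shape[1] != 2:
            raise ValueError("locs must be an (n, 2) array")
        for name in ("times", "time_knot", "marks"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                object.__setattr__(self, name, v)
                if len(v) != len(locs):
                    raise ValueError(f"{name} length must match locs")

    @property
    def n(self) -> int:
        return len(self.locs)

    @property
    def n_knots(self) -> int:
        return int(self.time_knot.max()) if self.time_knot is not None else 1


def bin_points(mesh: Mesh, pattern: PointPattern, n_knots: Optional[int] = None) -> np.ndarray:
    """Counts of points per mesh node (nearest node = Voronoi cell).

    Returns shape (n_knots, M); the single-knot spatial case is (1, M).
    """
    from scipy.spatial import cKDTree

    n_t = n_knots or pattern.n_knots
    tree = cKDTree(mesh.nodes)
    _, nearest = tree.query(pattern.locs)
    y = np.zeros((n_t, mesh.node_count))
    knots = (
        pattern.time_knot - 1
        if pattern.time_knot is not None
        else np.zeros(pattern.n, dtype=int)
    )
    np.add.at(y, (knots, nearest), 1.0)
    assert y.sum() == pattern.n
    return y


def ar1_precision(n_t: int, rho: float) -> sparse.csc_matrix:
    """Precision of a stationary AR(1) with unit marginal variance."""
    if not -1 < rho < 1:
        raise ValueError("rho must be in (-1, 1)")
    if n_t == 1:
        return sparse.identity(1, format="csc")
    d = np.full(n_t, 1.0 + rho**2)
    d[0] = d[-1] = 1.0
    off = np.full(n_t - 1, -rho)
    Q = sparse.diags([off, d, off], [-1, 0, 1]) / (1.0 - rho**2)
    return Q.tocsc()


def _logdet_sparse(A: sparse.csc_matrix, lu=None) -> float:
    lu = lu if lu is not None else splu(A.tocsc())
    # for SPD matrices the LU diagonal product is the (positive) determinant
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def lgcp_joint_nll(
    eta_fixed: np.ndarray,
    g: np.ndarray,
    counts: np.ndarray,
    weights: np.ndarray,
    Q: sparse.csc_matrix,
    logdet_Q: Optional[float] = None,
) -> float:
    """Joint negative log-likelihood of counts and latent field.

    ``eta_fixed`` is the fixed-effect predictor X beta per node (shape
    broadcastable to counts, (n_t, M)); ``g`` the flattened field values
    (knot-major), ``Q`` its joint precision.  The Poisson part drops the
    data-only constants y_k log w_k - log y_k!.
    """
    counts = np.atleast_2d(counts)
    n_t, M = counts.shape
    gm = g.reshape(n_t, M)
    eta = np.atleast_2d(eta_fixed) + gm
    w = np.broadcast_to(weights, counts.shape)
    with np.errstate(over="raise"):
        try:
            pois = float(np.sum(counts * eta - w * np.exp(eta)))
        except FloatingPointError:
            return np.inf
    if logdet_Q is None:
        logdet_Q = _logdet_sparse(Q)
    quad = float(g @ (Q @ g))
    prior = -0.5 * logdet_Q + 0.5 * quad + 0.5 * len(g) * np.log(2 * np.pi)
    return -pois + prior


def _inner_newton(
    eta_fixed: np.ndarray,
    counts: np.ndarray,
    weights: np.ndarray,
    Q: sparse.csc_matrix,
    g0: Optional[np.ndarray] = None,
    tol: float = 1e-9,
    max_iter: int = 100,
):
    """Newton optimisation of the field given hyperparameters.

    Returns (g_hat, H = Q + diag(w exp(eta)), its splu factorisation).
    """
    counts = np.atleast_2d(counts)
    n_t, M = counts.shape
    w = np.broadcast_to(weights, counts.shape).ravel()
    y = counts.ravel()
    eta0 = np.broadcast_to(np.atleast_2d(eta_fixed), counts.shape).ravel()
    g = np.zeros(n_t * M) if g0 is None else g0.copy()

    def value(gv):
        eta = eta0 + gv
        return float(-(y @ eta) + np.sum(w * np.exp(np.clip(eta, -700, 700)))
                     + 0.5 * gv @ (Q @ gv))

    f = value(g)
    for _ in range(max_iter):
        eta = eta0 + g
        mu = w * np.exp(np.clip(eta, -700, 700))
        grad = -(y - mu) + Q @ g
        gnorm = float(np.linalg.norm(grad, ord=np.inf))
        if gnorm < tol:
            break
        H = (Q + sparse.diags(mu)).tocsc()
        lu = splu(H)
        step = lu.solve(grad)
        # damped Newton: halve until descent
        s = 1.0
        for _ in range(50):
            g_new = g - s * step
            f_new = value(g_new)
            if f_new <= f + 1e-12:
                break
            s *= 0.5
        else:
            raise InnerNewtonError(f"line search failed at |grad|={gnorm:.2e}")
        g, f = g_new, f_new
    else:
        raise InnerNewtonError(
            f"inner Newton did not converge in {max_iter} iterations (|grad|={gnorm:.2e})"
        )
    mu = w * np.exp(np.clip(eta0 + g, -700, 700))
    H = (Q + sparse.diags(mu)).tocsc()
    return g, H, splu(H)


def _joint_precision(spde: SpdeParams, fem, n_t: int = 1, rho: float = 0.0):
    Qs = spde_precision(spde, fem)
    if n_t == 1:
        return Qs.tocsc()
    return sparse.kron(ar1_precision(n_t, rho), Qs, format="csc")


def laplace_marginal_nll(
    theta: np.ndarray,
    counts: np.ndarray,
    weights: np.ndarray,
    mesh: Mesh,
    X: Optional[np.ndarray] = None,
    fem=None,
    spatiotemporal: bool = False,
    g0: Optional[np.ndarray] = None,
    return_g: bool = False,
):
    """Laplace-approximated marginal NLL of theta = (beta, log kappa,
    log tau[, atanh rho]).

    marginal NLL = joint NLL at the conditional mode g-hat
                   + 1/2 log det H(g-hat) - dim(g)/2 log(2 pi).
    """
    counts = np.atleast_2d(counts)
    n_t, M = counts.shape
    X = np.ones((M, 1)) if X is None else np.atleast_2d(X)
    p = X.shape[1]
    beta = theta[:p]
    kappa, tau = np.exp(theta[p]), np.exp(theta[p + 1])
    rho = np.tanh(theta[p + 2]) if spatiotemporal else 0.0
    fem = fem or fem_matrices(mesh)
    Q = _joint_precision(SpdeParams(kappa, tau), fem, n_t if spatiotemporal else 1, rho)
    if not spatiotemporal and n_t > 1:
        Q = sparse.kron(sparse.identity(n_t), Q, format="csc")
    eta_fixed = X @ beta
    g, H, lu = _inner_newton(eta_fixed, counts, weights, Q, g0=g0)
    logdet_Q = _logdet_sparse(Q)
    joint = lgcp_joint_nll(eta_fixed, g, counts, weights, Q, logdet_Q=logdet_Q)
    nll = joint + 0.5 * _logdet_sparse(H, lu) - 0.5 * len(g) * np.log(2 * np.pi)
    if return_g:
        return nll, g, H
    return float(nll)


def fit_lgcp(
    pattern: PointPattern,
    domain: Domain,
    mesh: Mesh,
    init: Optional[dict] = None,
    covariates: Optional[np.ndarray] = None,
    weights: Optional[DualWeights] = None,
    spatiotemporal: bool = False,
    n_knots: Optional[int] = None,
) -> FitResult:
    """Fit a spatial (or AR(1)-spatiotemporal) LGCP by Laplace-MLE.

    ``covariates`` are node-level columns appended to the intercept.
    Reports beta, the practical range r and marginal sd sigma (and rho
    for spatiotemporal fits) with delta-method standard errors.
    """
    from .spde import dual_mesh_weights

    w = (weights or dual_mesh_weights(mesh, domain)).w
    n_t = n_knots or pattern.n_knots
    counts = bin_points(mesh, pattern, n_knots=n_t)
    M = mesh.node_count
    if covariates is not None:
        X = np.column_stack([np.ones(M), np.atleast_2d(covariates.T).T])
    else:
        X = np.ones((M, 1))
    p = X.shape[1]
    fem = fem_matrices(mesh)

    init = init or {}
    area = domain.area
    beta0 = init.get("beta0", np.log(max(pattern.n, 1) / (area * n_t)))
    diam = float(np.hypot(*(np.ptp(mesh.nodes, axis=0))))
    r0 = init.get("range", 0.2 * diam)
    sigma0 = init.get("sigma", 1.0)
    sp0 = SpdeParams.from_range_sigma(r0, sigma0)
    theta0 = np.concatenate(
        [
            [beta0],
            np.zeros(p - 1),
            [np.log(sp0.kappa), np.log(sp0.tau)],
            [np.arctanh(init.get("rho", 0.0))] if spatiotemporal else [],
        ]
    )

    state = {"g": None}

    def nll(theta):
        try:
            val, g, _ = laplace_marginal_nll(
                theta, counts, w, mesh, X=X, fem=fem,
                spatiotemporal=spatiotemporal, g0=state["g"], return_g=True,
            )
        except (InnerNewtonError, RuntimeError, FloatingPointError):
            return np.inf
        state["g"] = g
        return val

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-8})
    that = res.x

    kappa, tau = np.exp(that[p]), np.exp(that[p + 1])
    sp = SpdeParams(kappa, tau)
    _, ghat, H = laplace_marginal_nll(
        that, counts, w, mesh, X=X, fem=fem,
        spatiotemporal=spatiotemporal, g0=state["g"], return_g=True,
    )

    names = [f"beta{i}" for i in range(p)] + ["range", "sigma"]
    est = [*that[:p], sp.range, sp.sigma]
    if spatiotemporal:
        names.append("rho")
        est.append(np.tanh(that[p + 2]))

    def natural(theta):
        s = SpdeParams(np.exp(theta[p]), np.exp(theta[p + 1]))
        out = [*theta[:p], s.range, s.sigma]
        if spatiotemporal:
            out.append(np.tanh(theta[p + 2]))
        return np.array(out)

    Hout = numerical_hessian(nll, that, rel_step=1e-3)
    se = delta_method_se(Hout, natural, that)
    return FitResult(
        model="lgcp_st" if spatiotemporal else "lgcp",
        estimates=dict(zip(names, est)),
        std_errors=dict(zip(names, se)),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_evals=int(res.nfev),
        internal=dict(zip([f"theta{i}" for i in range(len(that))], that)),
        extra={
            "field_mode": ghat.tolist(),
            "eta_fixed": (X @ that[:p]).tolist(),
            "n_knots": n_t,
            "_H": H,
        },
    )


def expected_total(fit: FitResult, weights: DualWeights) -> float:
    """Expected number of events sum_k w_k exp((X beta)_k + g_k)."""
    g = np.asarray(fit.extra["field_mode"])
    eta_fixed = np.asarray(fit.extra["eta_fixed"])
    n_t = int(fit.extra.get("n_knots", 1))
    M = len(weights.w)
    eta = eta_fixed[None, :] + g.reshape(n_t, M)
    return float(np.sum(weights.w[None, :] * np.exp(eta)))


def get_fields(fit: FitResult, sd: bool = False):
    """Conditional mode of the latent field (and optional node SDs).

    SDs are sqrt of the diagonal of the inverse curvature at the mode,
    computed densely (intended for the moderate mesh sizes this package
    targets).
    """
    g = np.asarray(fit.extra["field_mode"])
    if not sd:
        return g
    H = fit.extra.get("_H")
    if H is None:
        raise ValueError("fit does not carry curvature; refit with get_fields support")
    cov = np.linalg.inv(H.toarray() if sparse.issparse(H) else np.asarray(H))
    return g, np.sqrt(np.diag(cov))


def simulate_lgcp(
    spde_params: SpdeParams,
    beta: np.ndarray,
    mesh: Mesh,
    domain: Domain,
    seed: int,
    X: Optional[np.ndarray] = None,
    rho: Optional[float] = None,
    n_t: int = 1,
) -> PointPattern:
    """Simulate an LGCP realisation on the dual mesh.

    Draws g ~ N(0, Q^{-1}), then per-cell Poisson counts with mean
    w_k exp(eta_k), placing points uniformly in each clipped Voronoi
    cell (rejection sampling within the cell's bounding box).
    """
    rng = np.random.default_rng(seed)
    M = mesh.node_count
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.ones((M, 1)) if X is None else np.atleast_2d(X)
    fem = fem_matrices(mesh)
    Q = _joint_precision(spde_params, fem, n_t, rho or 0.0)
    L = np.linalg.cholesky(Q.toarray())
    z = rng.standard_normal(n_t * M)
    from scipy.linalg import solve_triangular

    g = solve_triangular(L.T, z, lower=False)

    cells = dual_mesh_cells(mesh, domain)
    w = np.array([0.0 if c is None else c.area for c in cells])
    eta = (X @ beta)[None, :] + g.reshape(n_t, M)
    lam = w[None, :] * np.exp(eta)
    counts = rng.poisson(lam)

    pts, knots = [], []
    for i in range(n_t):
        for k in range(M):
            c = counts[i, k]
            if c == 0 or cells[k] is None:
                continue
            pts.append(_uniform_in_polygon(cells[k], c, rng))
            knots.extend([i + 1] * c)
    locs = np.vstack(pts) if pts else np.empty((0, 2))
    return PointPattern(
        locs=locs,
        time_knot=np.asarray(knots, dtype=int) if n_t > 1 else None,
    )


def _uniform_in_polygon(poly, n: int, rng) -> np.ndarray:
    import shapely

    xmin, ymin, xmax, ymax = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(4 * (n - filled), 16)
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        ok = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        take = cand[ok][: n - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out
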