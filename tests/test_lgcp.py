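"""LGCP: binning, joint NLL oracle, Laplace vs exact integration, fits."""

import numpy as np
import pytest
from scipy import sparse, stats
from scipy.linalg import solve_triangular
from scipy.sparse.linalg import splu

import coxhawk as ch
from coxhawk.fitresult import FitResult
from coxhawk.lgcp import (
    _inner_newton,
    _joint_precision,
    ar1_precision,
    laplace_marginal_nll,
    lgcp_joint_nll,
)
from coxhawk.spde import fem_matrices, spde_precision


def dense_joint_nll(eta_fixed, g, counts, w, Q):
    """Independent dense evaluation: Poisson terms + Gaussian log-density."""
    eta = np.atleast_2d(eta_fixed) + g.reshape(np.atleast_2d(counts).shape)
    pois = np.sum(np.atleast_2d(counts) * eta - w * np.exp(eta))
    mvn = stats.multivariate_normal(mean=np.zeros(len(g)), cov=np.linalg.inv(Q.toarray()))
    return -pois - mvn.logpdf(g)


class TestBinPoints:
    def test_point_at_node_counts_to_node(self, tiny_mesh):
        pat = ch.PointPattern(locs=tiny_mesh.nodes[[4]])
        y = ch.bin_points(tiny_mesh, pat)
        assert y[0, 4] == 1 and y.sum() == 1

    def test_counts_sum_to_n(self, unit_mesh):
        rng = np.random.default_rng(1)
        pat = ch.PointPattern(locs=rng.uniform(0.01, 0.99, (37, 2)))
        y = ch.bin_points(unit_mesh, pat)
        assert y.sum() == 37

    def test_matches_nearest_node_brute_force(self, tiny_mesh):
        rng = np.random.default_rng(8)
        locs = rng.uniform(0.05, 0.95, (10, 2))
        y = ch.bin_points(tiny_mesh, ch.PointPattern(locs=locs)).ravel()
        brute = np.zeros(tiny_mesh.node_count)
        for p in locs:
            brute[np.argmin(np.hypot(*(tiny_mesh.nodes - p).T))] += 1
        np.testing.assert_array_equal(y, brute)


class TestAr1Precision:
    def test_single_knot_is_identity(self):
        assert ar1_precision(1, 0.7).toarray() == pytest.approx(np.array([[1.0]]))

    def test_inverse_is_ar1_correlation(self):
        rho, n = 0.6, 5
        cov = np.linalg.inv(ar1_precision(n, rho).toarray())
        want = rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        np.testing.assert_allclose(cov, want, atol=1e-12)


class TestJointNll:
    def test_dense_oracle_tiny_mesh(self, tiny_mesh):
        rng = np.random.default_rng(5)
        Q = spde_precision(ch.SpdeParams(2.0, 0.8), fem_matrices(tiny_mesh)).tocsc()
        M = tiny_mesh.node_count
        g = rng.normal(0, 0.5, M)
        counts = rng.poisson(1.0, M).astype(float)
        w = rng.uniform(0.1, 0.4, M)
        eta0 = np.full(M, 0.3)
        got = lgcp_joint_nll(eta0, g, counts, w, Q)
        want = dense_joint_nll(eta0, g, counts[None, :], w, Q)
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_weight_nodes_enter_prior_only(self, tiny_mesh):
        Q = spde_precision(ch.SpdeParams(2.0, 0.8), fem_matrices(tiny_mesh)).tocsc()
        M = tiny_mesh.node_count
        g = np.linspace(-0.5, 0.5, M)
        counts = np.zeros(M)
        w = np.array([0.3, 0.3, 0.3, 0.3, 0.0])
        base = lgcp_joint_nll(np.zeros(M), g, counts, w, Q)
        # changing g at the zero-weight node must only move the prior term
        g2 = g.copy()
        g2[4] += 1.0
        delta = lgcp_joint_nll(np.zeros(M), g2, counts, w, Q) - base
        prior_delta = 0.5 * g2 @ (Q @ g2) - 0.5 * g @ (Q @ g)
        assert delta == pytest.approx(prior_delta, abs=1e-10)

    def test_rho_zero_prior_separates_across_knots(self, tiny_mesh):
        rng = np.random.default_rng(9)
        M = tiny_mesh.node_count
        n_t = 3
        Qs = spde_precision(ch.SpdeParams(2.0, 0.8), fem_matrices(tiny_mesh))
        Qj = sparse.kron(ar1_precision(n_t, 0.0), Qs, format="csc")
        g = rng.normal(0, 0.5, n_t * M)
        counts = rng.poisson(0.8, (n_t, M)).astype(float)
        w = rng.uniform(0.1, 0.4, M)
        eta0 = np.full(M, -0.2)
        total = lgcp_joint_nll(eta0, g, counts, w, Qj)
        parts = sum(
            lgcp_joint_nll(eta0, g[i * M : (i + 1) * M], counts[i], w, Qs.tocsc())
            for i in range(n_t)
        )
        assert total == pytest.approx(parts, rel=1e-12)


class TestLaplace:
    def _toy(self):
        """Four-node mesh (two triangles on the unit square)."""
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        mesh = ch.Mesh(nodes, np.array([[0, 1, 2], [0, 2, 3]]))
        counts = np.array([[2.0, 0.0, 1.0, 3.0]])
        w = np.array([0.25, 0.25, 0.25, 0.25])
        return mesh, counts, w

    def test_matches_gauss_hermite_integration(self):
        # counts per cell are large so the Laplace error (which decays
        # like 1/count per node) sits safely inside the tolerance
        mesh, _, w = self._toy()
        counts = np.array([[520.0, 300.0, 450.0, 640.0]])
        beta0 = float(np.log(np.mean(counts) / 0.25))
        theta = np.array([beta0, np.log(2.2), np.log(0.9)])
        got = laplace_marginal_nll(theta, counts, w, mesh)

        # oracle: adaptive tensor Gauss-Hermite around an independently
        # located mode of the dense joint density
        Q = spde_precision(ch.SpdeParams(2.2, 0.9), fem_matrices(mesh)).tocsc()
        eta0 = np.full(4, beta0)

        def joint(g):
            return dense_joint_nll(eta0, g, counts, w, Q)

        from scipy.optimize import minimize

        m = minimize(
            joint, np.zeros(4), method="Nelder-Mead",
            options=dict(xatol=1e-12, fatol=1e-14, maxiter=10000),
        ).x
        H = np.zeros((4, 4))
        h = 1e-3
        for i in range(4):
            for j in range(4):
                ei, ej = np.zeros(4), np.zeros(4)
                ei[i], ej[j] = h, h
                H[i, j] = (
                    joint(m + ei + ej) - joint(m + ei - ej)
                    - joint(m - ei + ej) + joint(m - ei - ej)
                ) / (4 * h * h)
        vals, vecs = np.linalg.eigh(H)
        B = vecs @ np.diag(1.0 / np.sqrt(vals))
        z, wq = np.polynomial.hermite_e.hermegauss(30)
        grids = np.meshgrid(*([z] * 4), indexing="ij")
        Z = np.stack([gg.ravel() for gg in grids], axis=1)
        WW = np.prod(
            np.stack(np.meshgrid(*([wq] * 4), indexing="ij"), axis=-1).reshape(-1, 4),
            axis=1,
        )
        G = m + Z @ B.T
        eta = eta0 + G
        pois = np.sum(counts.ravel() * eta - w * np.exp(eta), axis=1)
        quad = 0.5 * np.einsum("ij,jk,ik->i", G, Q.toarray(), G)
        sign, logdet_Q = np.linalg.slogdet(Q.toarray())
        logjoint = pois - quad + 0.5 * logdet_Q - 2 * np.log(2 * np.pi)
        # e^{-z^2/2} weights absorbed: integrand / N(z) kernel
        log_terms = logjoint + 0.5 * np.sum(Z**2, axis=1)
        mx = log_terms.max()
        log_integral = (
            mx + np.log(np.sum(WW * np.exp(log_terms - mx)))
            + np.log(abs(np.linalg.det(B)))
        )
        want = -log_integral
        assert got == pytest.approx(want, abs=1e-3)

    def test_inner_mode_is_stationary(self):
        mesh, counts, w = self._toy()
        Q = spde_precision(ch.SpdeParams(2.2, 0.9), fem_matrices(mesh)).tocsc()
        eta0 = np.full(4, 0.4)
        g, H, _ = _inner_newton(eta0, counts, w, Q)
        mu = w * np.exp(eta0 + g)
        grad = -(counts.ravel() - mu) + Q @ g
        assert np.abs(grad).max() < 1e-8

    def test_degenerate_prior_recovers_poisson_regression(self):
        mesh, counts, w = self._toy()
        beta0 = 0.4
        # tiny field sd: tau huge
        sp = ch.SpdeParams.from_range_sigma(1.0, 1e-4)
        theta = np.array([beta0, np.log(sp.kappa), np.log(sp.tau)])
        got = laplace_marginal_nll(theta, counts, w, mesh)
        eta = np.full(4, beta0)
        pois_nll = -np.sum(counts.ravel() * eta - w * np.exp(eta))
        assert got == pytest.approx(pois_nll, abs=1e-4)

    def test_spatiotemporal_single_knot_equals_spatial(self):
        mesh, counts, w = self._toy()
        theta_sp = np.array([0.4, np.log(2.2), np.log(0.9)])
        theta_st = np.concatenate([theta_sp, [np.arctanh(0.5)]])
        a = laplace_marginal_nll(theta_sp, counts, w, mesh)
        b = laplace_marginal_nll(theta_st, counts, w, mesh, spatiotemporal=True)
        assert a == pytest.approx(b, abs=1e-10)


class TestFitAndPredict:
    def test_homogeneous_poisson_intercept(self, unit_square, unit_mesh):
        rng = np.random.default_rng(17)
        n = 600
        pat = ch.PointPattern(locs=rng.uniform(0, 1, (n, 2)))
        fit = ch.fit_lgcp(pat, unit_square, unit_mesh, init={"sigma": 0.3})
        assert fit.estimates["beta0"] == pytest.approx(np.log(n), abs=0.25)

    def test_recovery_and_expected_total(self, big_square):
        mesh = ch.build_mesh(big_square, max_edge=1.3)
        w = ch.dual_mesh_weights(mesh, big_square)
        sp = ch.SpdeParams.from_range_sigma(3.0, 1.0)
        hits_total, zs = 0, []
        seeds = range(8)
        for seed in seeds:
            pat = ch.simulate_lgcp(sp, beta=np.array([1.0]), mesh=mesh,
                                   domain=big_square, seed=40 + seed)
            fit = ch.fit_lgcp(pat, big_square, mesh)
            zs.append((fit.estimates["beta0"] - 1.0) / fit.std_errors["beta0"])
            tot = ch.expected_total(fit, w)
            hits_total += abs(tot - pat.n) < 3 * np.sqrt(pat.n)
        assert np.median(np.abs(zs)) < 3
        assert hits_total >= 7

    def test_expected_total_identities(self, unit_mesh, unit_square):
        w = ch.dual_mesh_weights(unit_mesh, unit_square)
        M = unit_mesh.node_count
        n = 57
        fit = FitResult(
            model="lgcp", estimates={}, std_errors={}, loglik=0.0, converged=True,
            extra={
                "field_mode": [0.0] * M,
                "eta_fixed": [np.log(n / w.total)] * M,
                "n_knots": 1,
            },
        )
        assert ch.expected_total(fit, w) == pytest.approx(n, rel=1e-12)
        fit.extra["eta_fixed"] = [np.log(n / w.total) + 0.7] * M
        assert ch.expected_total(fit, w) == pytest.approx(n * np.exp(0.7), rel=1e-12)


class TestSimulate:
    def test_sigma_zero_total_count_poisson(self, unit_square, unit_mesh):
        sp = ch.SpdeParams.from_range_sigma(0.5, 1e-5)
        beta0 = np.log(200.0)
        counts = [
            ch.simulate_lgcp(sp, np.array([beta0]), unit_mesh, unit_square, seed=s).n
            for s in range(60)
        ]
        assert np.mean(counts) == pytest.approx(200, abs=3 * np.sqrt(200 / 60))

    def test_lognormal_mean_identity(self, unit_square):
        # buffered mesh keeps the field variance near its stationary
        # value sigma^2 inside the domain, which the identity assumes
        mesh = ch.build_mesh(unit_square, max_edge=0.3, buffer=0.45)
        w = ch.dual_mesh_weights(mesh, unit_square)
        sigma, beta0 = 0.8, np.log(150.0)
        sp = ch.SpdeParams.from_range_sigma(0.3, sigma)
        counts = [
            ch.simulate_lgcp(sp, np.array([beta0]), mesh, unit_square, seed=s).n
            for s in range(100)
        ]
        want = w.total * np.exp(beta0 + sigma**2 / 2)
        se = np.std(counts) / np.sqrt(len(counts))
        assert np.mean(counts) == pytest.approx(want, abs=3.5 * se)

    def test_ar1_chain_lag1_correlation(self, unit_mesh):
        rho, n_t = 0.9, 8
        sp = ch.SpdeParams.from_range_sigma(0.4, 1.0)
        Q = _joint_precision(sp, fem_matrices(unit_mesh), n_t, rho)
        L = np.linalg.cholesky(Q.toarray())
        rng = np.random.default_rng(123)
        M = unit_mesh.node_count
        cors = []
        for _ in range(40):
            g = solve_triangular(L.T, rng.standard_normal(n_t * M), lower=False)
            G = g.reshape(n_t, M)
            cors.append(np.corrcoef(G[:-1].ravel(), G[1:].ravel())[0, 1])
        assert np.mean(cors) == pytest.approx(rho, abs=0.05)


class TestGetFields:
    def test_mode_and_sds(self, unit_square, unit_mesh):
        rng = np.random.default_rng(3)
        pat = ch.PointPattern(locs=rng.uniform(0, 1, (120, 2)))
        fit = ch.fit_lgcp(pat, unit_square, unit_mesh)
        g, sds = ch.get_fields(fit, sd=True)
        assert np.all(sds > 0)
        H = fit.extra["_H"].toarray()
        np.testing.assert_allclose(sds, np.sqrt(np.diag(np.linalg.inv(H))), rtol=1e-8)
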