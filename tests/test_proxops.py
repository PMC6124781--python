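"""Proximal operators and the consensus solver against independent oracles."""

import numpy as np
import pytest
import scipy.optimize
from sklearn.linear_model import Lasso

from lnlncascade.proxops import (
    FantopeConstraint,
    L1Penalty,
    SmoothLossTerm,
    SquaredL2Penalty,
    consensus_solve,
    prox_elementwise,
    prox_fantope,
    prox_l1,
    prox_nuclear,
    prox_smooth_loss,
    project_capped_simplex,
)

RNG = np.random.default_rng(20240817)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def scalar_prox_oracle(v, phi_scalar, rho=1.0):
    """Separable prox via per-coordinate bounded scalar minimization."""
    out = np.empty_like(v, dtype=float)
    for i, vi in enumerate(v):
        res = scipy.optimize.minimize_scalar(
            lambda x: phi_scalar(x) + 0.5 * rho * (x - vi) ** 2,
            bounds=(vi - 10 - abs(vi), vi + 10 + abs(vi)), method="bounded",
            options={"xatol": 1e-10})
        out[i] = res.x
    return out


def nuclear_prox_oracle(V, gamma, rho=1.0, mu=1e-7):
    """Numeric minimizer of gamma*||X||_* + rho/2 ||X - V||_F^2.

    Uses a Huber-smoothed spectral surrogate (smoothing scale mu) so the
    objective is differentiable, then L-BFGS; independent of the
    singular-value soft-threshold formula.
    """
    shape = V.shape

    def obj(xflat):
        X = xflat.reshape(shape)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        hub = np.where(s < mu, s**2 / (2 * mu), s - mu / 2)
        dhub = np.minimum(s / mu, 1.0)
        g = gamma * (U * dhub) @ Vt + rho * (X - V)
        f = gamma * hub.sum() + 0.5 * rho * np.sum((X - V) ** 2)
        return f, g.ravel()

    res = scipy.optimize.minimize(obj, V.ravel(), jac=True, method="L-BFGS-B",
                                  options={"maxiter": 2000, "ftol": 1e-15,
                                           "gtol": 1e-12})
    return res.x.reshape(shape)


def fantope_projection_oracle(V, d, iters=3000):
    """Dykstra alternating projections onto {0<=X<=I} and {tr X = d}."""
    n = V.shape[0]
    x = V.copy()
    p = np.zeros_like(V)
    q = np.zeros_like(V)
    for _ in range(iters):
        lam, Q = np.linalg.eigh(x + p)
        y = (Q * np.clip(lam, 0.0, 1.0)) @ Q.T
        p = x + p - y
        x = y + q + (d - np.trace(y + q)) / n * np.eye(n)
        q = y + q - x
    return x


# ---------------------------------------------------------------------------
# closed-form operators
# ---------------------------------------------------------------------------

class TestProxL1:
    def test_printed_example(self):
        np.testing.assert_allclose(prox_l1(np.array([2.0, -0.5, 0.1]), 1.0),
                                   [1.0, 0.0, 0.0])

    def test_zero_threshold_is_identity(self):
        v = RNG.standard_normal(7)
        np.testing.assert_array_equal(prox_l1(v, 0.0), v)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            prox_l1(np.ones(3), -0.1)

    def test_matches_scalar_minimization_oracle(self):
        v = RNG.standard_normal(20)
        expected = scalar_prox_oracle(v, lambda x: 0.3 * abs(x))
        np.testing.assert_allclose(prox_l1(v, 0.3), expected, atol=1e-6)


class TestProxElementwise:
    def test_nonneg_clamp(self):
        np.testing.assert_array_equal(
            prox_elementwise(np.array([-1.0, 2.0]), "nonneg"), [0.0, 2.0])

    def test_l2_zero_weight_identity(self):
        v = RNG.standard_normal(5)
        np.testing.assert_array_equal(prox_elementwise(v, "l2", 0.0), v)

    def test_l2_matches_scalar_oracle(self):
        v = RNG.standard_normal(15)
        gamma = 0.7
        expected = scalar_prox_oracle(v, lambda x: 0.5 * gamma * x**2)
        np.testing.assert_allclose(prox_elementwise(v, "l2", gamma), expected,
                                   atol=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            prox_elementwise(np.ones(2), "huber")


class TestProxNuclear:
    def test_diagonal_soft_threshold(self):
        V = np.diag([3.0, 1.0, 0.2])
        np.testing.assert_allclose(prox_nuclear(V, 0.5),
                                   np.diag([2.5, 0.5, 0.0]), atol=1e-12)

    def test_zero_threshold_identity(self):
        V = RNG.standard_normal((4, 3))
        np.testing.assert_array_equal(prox_nuclear(V, 0.0), V)

    def test_nonfinite_rejected(self):
        V = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            prox_nuclear(V, 0.1)

    def test_matches_smoothed_spectral_oracle(self):
        V = RNG.standard_normal((6, 4))
        expected = nuclear_prox_oracle(V, 0.7)
        np.testing.assert_allclose(prox_nuclear(V, 0.7), expected, atol=1e-5)


class TestProxFantope:
    def test_projector_is_fixed_point(self):
        Q, _ = np.linalg.qr(RNG.standard_normal((6, 2)))
        P = Q @ Q.T
        np.testing.assert_allclose(prox_fantope(P, 2), P, atol=1e-10)

    @pytest.mark.parametrize("d", [1, 2, 4])
    def test_feasibility(self, d):
        V = RNG.standard_normal((5, 5))
        V = V + V.T
        out = prox_fantope(V, d)
        lam = np.linalg.eigvalsh(out)
        assert lam.min() >= -1e-8 and lam.max() <= 1 + 1e-8
        assert abs(np.trace(out) - d) < 1e-8

    def test_matches_dykstra_oracle(self):
        V = RNG.standard_normal((5, 5))
        V = V + V.T
        expected = fantope_projection_oracle(V, 2)
        np.testing.assert_allclose(prox_fantope(V, 2), expected, atol=1e-5)

    def test_asymmetric_rejected(self):
        V = np.eye(4)
        V[0, 1] = 0.3
        with pytest.raises(ValueError):
            prox_fantope(V, 1)

    def test_capped_simplex_constraints(self):
        lam = RNG.standard_normal(10) * 3
        x = project_capped_simplex(lam, 4)
        assert x.min() >= 0 and x.max() <= 1
        assert abs(x.sum() - 4) < 1e-9


class TestProxSmoothLoss:
    def test_quadratic_closed_form(self):
        a = RNG.standard_normal(6)
        v = RNG.standard_normal(6)
        rho = 2.0
        out = prox_smooth_loss(
            v, lambda x: 0.5 * float(np.sum((x - a) ** 2)), lambda x: x - a, rho)
        np.testing.assert_allclose(out, (rho * v + a) / (rho + 1), atol=1e-7)

    def test_large_rho_returns_start(self):
        a = np.zeros(4)
        v = RNG.standard_normal(4)
        out = prox_smooth_loss(
            v, lambda x: 0.5 * float(np.sum((x - a) ** 2)), lambda x: x - a, 1e8)
        np.testing.assert_allclose(out, v, atol=1e-6)

    def test_poisson_nll_matches_second_order_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 8))
        w_true = rng.standard_normal(8) / np.sqrt(8)
        y = rng.poisson(np.exp(X @ w_true))
        v = rng.standard_normal(8)

        def nll(w):
            eta = X @ w
            return float(np.sum(np.exp(eta)) - y @ eta)

        def grad(w):
            return X.T @ (np.exp(X @ w) - y)

        rho = 5.0
        out = prox_smooth_loss(v, nll, grad, rho, maxiter=200, gtol=1e-12)
        res = scipy.optimize.minimize(
            lambda w: nll(w) + 0.5 * rho * np.sum((w - v) ** 2),
            v, jac=lambda w: grad(w) + rho * (w - v),
            method="trust-constr", options={"gtol": 1e-12, "maxiter": 3000})
        np.testing.assert_allclose(out, res.x, atol=1e-4)


@pytest.mark.parametrize("op,size", [
    (lambda v: prox_l1(v, 0.4), 20),
    (lambda v: prox_elementwise(v, "l2", 0.8), 20),
    (lambda v: prox_elementwise(v, "nonneg"), 20),
    (lambda v: prox_nuclear(v.reshape(4, 5), 0.6).ravel(), 20),
    (lambda v: prox_fantope(0.5 * (v.reshape(5, 5) + v.reshape(5, 5).T),
                            2).ravel(), 25),
])
def test_nonexpansiveness(op, size):
    """Proximal operators of convex functions are 1-Lipschitz.

    Symmetrization (for the fantope case) is itself 1-Lipschitz, so the
    composite map must also be nonexpansive.
    """
    rng = np.random.default_rng(11)
    for _ in range(20):
        v1 = rng.standard_normal(size)
        v2 = rng.standard_normal(size)
        d_in = np.linalg.norm(v1 - v2)
        d_out = np.linalg.norm(np.ravel(op(v1)) - np.ravel(op(v2)))
        assert d_out <= d_in + 1e-9


# ---------------------------------------------------------------------------
# consensus ADMM
# ---------------------------------------------------------------------------

class TestConsensusSolve:
    def test_single_quadratic_converges_to_minimizer(self):
        a = RNG.standard_normal(5)
        term = SmoothLossTerm(loss=lambda x: 0.5 * float(np.sum((x - a) ** 2)),
                              grad=lambda x: x - a, maxiter=100)
        x, state = consensus_solve([term], np.zeros(5), tol=1e-8, max_iter=500)
        np.testing.assert_allclose(x, a, atol=1e-5)
        assert state.converged

    def test_two_quadratics_average(self):
        a = RNG.standard_normal(4)
        b = RNG.standard_normal(4)
        terms = [
            SmoothLossTerm(loss=lambda x: 0.5 * float(np.sum((x - a) ** 2)),
                           grad=lambda x: x - a, maxiter=100),
            SmoothLossTerm(loss=lambda x: 0.5 * float(np.sum((x - b) ** 2)),
                           grad=lambda x: x - b, maxiter=100),
        ]
        x, _ = consensus_solve(terms, np.zeros(4), tol=1e-8, max_iter=500)
        np.testing.assert_allclose(x, (a + b) / 2, atol=1e-5)

    def test_lasso_matches_coordinate_descent(self):
        """Least-squares + l1 against sklearn's independent solver."""
        rng = np.random.default_rng(7)
        n, p = 200, 50
        X = rng.standard_normal((n, p))
        w_true = np.zeros(p)
        w_true[:5] = rng.standard_normal(5)
        y = X @ w_true + 0.1 * rng.standard_normal(n)
        gamma = 0.1

        terms = [
            SmoothLossTerm(loss=lambda w: 0.5 * float(np.sum((X @ w - y) ** 2)),
                           grad=lambda w: X.T @ (X @ w - y), maxiter=100,
                           gtol=1e-10),
            L1Penalty(gamma),
        ]
        w_admm, state = consensus_solve(terms, np.zeros(p), rho=10.0,
                                        tol=1e-7, max_iter=2000)
        oracle = Lasso(alpha=gamma / n, fit_intercept=False, tol=1e-12,
                       max_iter=100000).fit(X, y)
        np.testing.assert_allclose(w_admm, oracle.coef_, atol=1e-4)
        obj = lambda w: 0.5 * np.sum((X @ w - y) ** 2) + gamma * np.abs(w).sum()
        assert obj(w_admm) <= obj(oracle.coef_) * (1 + 1e-4)

    def test_residuals_trend_to_tolerance(self):
        a = RNG.standard_normal(6)
        terms = [
            SmoothLossTerm(loss=lambda x: 0.5 * float(np.sum((x - a) ** 2)),
                           grad=lambda x: x - a, maxiter=50),
            SquaredL2Penalty(0.5),
        ]
        x, state = consensus_solve(terms, np.zeros(6), tol=1e-6, max_iter=500)
        assert state.converged
        first = state.history[0]
        last = state.history[-1]
        assert last["primal"] < first["primal"]
        assert last["primal"] < 1e-6 and last["dual"] < 1e-6
        # analytic minimizer of 0.5||x-a||^2 + 0.25||x||^2
        np.testing.assert_allclose(x, a / 1.5, atol=1e-4)

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            consensus_solve([], np.zeros(3))

    def test_fantope_constrained_trace_problem(self):
        """gamma=0 fantope program recovers the top-d eigenspace."""
        rng = np.random.default_rng(5)
        M = rng.standard_normal((8, 8))
        C = M @ M.T
        from lnlncascade.proxops import LinearTerm
        x, _ = consensus_solve([LinearTerm(-C), FantopeConstraint(2)],
                               np.eye(8) * (2 / 8), tol=1e-8, max_iter=500)
        lam, Q = np.linalg.eigh(C)
        top = Q[:, -2:] @ Q[:, -2:].T
        np.testing.assert_allclose(x, top, atol=1e-4)


class TestPenaltyConfig:
    def test_load_from_mapping_and_json(self, tmp_path):
        from lnlncascade.proxops import (NuclearNormPenalty,
                                         penalties_from_config)
        import json

        cfg = {"penalties": [
            {"kind": "l1", "weight": 0.1},
            {"kind": "nuclear", "weight": 0.2, "n_bars": 4, "n_lags": 3},
            {"kind": "fantope", "d": 2},
        ]}
        terms = penalties_from_config(cfg)
        assert isinstance(terms[1], NuclearNormPenalty)
        assert terms[1].n_bars == 4

        path = tmp_path / "pen.json"
        path.write_text(json.dumps(cfg))
        terms2 = penalties_from_config(path)
        assert [type(t) for t in terms2] == [type(t) for t in terms]

    def test_load_from_toml(self, tmp_path):
        from lnlncascade.proxops import L1Penalty, penalties_from_config

        path = tmp_path / "pen.toml"
        path.write_text('[[penalties]]\nkind = "l1"\nweight = 0.3\n')
        terms = penalties_from_config(path)
        assert isinstance(terms[0], L1Penalty)
        assert terms[0].weight == 0.3

    def test_unknown_kind_rejected(self):
        from lnlncascade.proxops import penalties_from_config

        with pytest.raises(ValueError):
            penalties_from_config({"penalties": [{"kind": "huber"}]})
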