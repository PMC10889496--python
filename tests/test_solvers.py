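"""Constrained ADMM solver: step semantics, fixed points, convex oracles,
baselines, and determinism."""

import numpy as np
import pytest

from cpnp import (
    NumericalFailureError,
    SolverConfig,
    cpnp_restore,
    cpnp_step,
    gaussian_psf,
    make_constraint,
    make_denoiser,
    make_operator,
    pnp_hqs_restore,
    project_residual,
    psnr,
    red_admm_restore,
    update_penalties,
)
from cpnp.denoisers import Denoiser
from cpnp.solvers import init_state

from conftest import dense_matrix


def _delta_operator(shape):
    return make_operator(gaussian_psf(1e-4, 3), shape)


class TestStep:
    def test_fixed_point_with_identity_operator_and_denoiser(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 255, (8, 8))
        op = _delta_operator(b.shape)
        constraint = make_constraint(1.0, 50.0, b.size)  # generous radius
        D = make_denoiser("identity")
        from cpnp.solvers import SolverState

        # x = v = b, r = Ax - b = 0, zero duals: a fixed point of the sweep
        zero = np.zeros_like(b)
        state = SolverState(x=b.copy(), v=b.copy(), r=zero.copy(),
                            lam_r=zero.copy(), lam_v=zero.copy(),
                            beta_r=1.0, beta_v=1.0, k=0)
        new = cpnp_step(state, op, b, constraint, D)
        np.testing.assert_allclose(new.x, b, atol=1e-8)
        np.testing.assert_allclose(new.x, new.v, atol=1e-8)
        np.testing.assert_allclose(new.lam_r, 0, atol=1e-8)
        assert new.k == state.k + 1

    def test_one_step_matches_straight_line_transcription(self):
        # independent dense transcription of one full sweep on a 4x4 instance
        rng = np.random.default_rng(1)
        b = rng.uniform(0, 255, (4, 4))
        op = make_operator(gaussian_psf(0.6, 3), b.shape)
        A = dense_matrix(op)
        constraint = make_constraint(1.0, 5.0, b.size)
        alpha = 0.7
        D = make_denoiser("tikhonov", {"alpha": alpha})
        beta_r, beta_v = 0.8, 1.3
        cfg = SolverConfig(beta_r0=beta_r, beta_v0=beta_v, gamma=1.0)
        state = init_state(b, op, constraint, cfg)

        # transcription: x0 = b, v0 = 0, duals 0, r0 = proj(Ax0 - b)
        bv_ = b.ravel()
        x0 = bv_.copy()
        v0 = np.zeros_like(bv_)
        lam_r0 = np.zeros_like(bv_)
        lam_v0 = np.zeros_like(bv_)
        r0 = project_residual((A @ x0 - bv_).reshape(4, 4), constraint.radius).ravel()
        ratio = beta_r / beta_v
        rhs = ratio * A.T @ (bv_ + r0 - lam_r0 / beta_r) + (v0 - lam_v0 / beta_v)
        x1 = np.linalg.solve(ratio * A.T @ A + np.eye(16), rhs)
        v1 = (x1 + lam_v0 / beta_v) / (1 + alpha)
        r1 = project_residual((A @ x1 - bv_ + lam_r0 / beta_r).reshape(4, 4),
                              constraint.radius).ravel()
        lam_r1 = lam_r0 + beta_r * (A @ x1 - bv_ - r1)
        lam_v1 = lam_v0 + beta_v * (x1 - v1)

        new = cpnp_step(state, op, b, constraint, D)
        np.testing.assert_allclose(new.x.ravel(), x1, atol=1e-9)
        np.testing.assert_allclose(new.v.ravel(), v1, atol=1e-9)
        np.testing.assert_allclose(new.r.ravel(), r1, atol=1e-9)
        np.testing.assert_allclose(new.lam_r.ravel(), lam_r1, atol=1e-9)
        np.testing.assert_allclose(new.lam_v.ravel(), lam_v1, atol=1e-9)

    def test_numerical_failure_names_offending_step(self):
        b = np.ones((8, 8))
        op = _delta_operator(b.shape)
        constraint = make_constraint(1.0, 1.0, b.size)
        bad = Denoiser(name="bad", strength=0.0,
                       fn=lambda u, s: np.full_like(u, np.inf))
        cfg = SolverConfig()
        state = init_state(b, op, constraint, cfg)
        with pytest.raises(NumericalFailureError, match="v-update"):
            cpnp_step(state, op, b, constraint, bad)


class TestPenalties:
    def test_gamma_one_is_noop(self):
        b = np.ones((4, 4))
        op = _delta_operator(b.shape)
        cfg = SolverConfig(beta_r0=0.2, beta_v0=0.8)
        state = init_state(b, op, make_constraint(1, 1, 16), cfg)
        new = update_penalties(state, 1.0)
        assert new.beta_r == 0.2 and new.beta_v == 0.8

    def test_geometric_growth(self):
        b = np.ones((4, 4))
        op = _delta_operator(b.shape)
        cfg = SolverConfig(beta_r0=0.2, beta_v0=0.8)
        state = init_state(b, op, make_constraint(1, 1, 16), cfg)
        new = update_penalties(state, 1.05)
        assert abs(new.beta_r - 0.21) < 1e-12 and abs(new.beta_v - 0.84) < 1e-12
        beta = 1.0
        for _ in range(100):
            beta *= 1.01
        assert abs(beta - 1.01**100) < 1e-9  # ~2.7048

    def test_shrinking_gamma_rejected(self):
        b = np.ones((4, 4))
        op = _delta_operator(b.shape)
        state = init_state(b, op, make_constraint(1, 1, 16), SolverConfig())
        with pytest.raises(ValueError):
            update_penalties(state, 0.9)


class TestCPnPRestore:
    def test_zero_radius_converges_to_exact_fit(self, checkers32):
        # radius 0 forces r = 0: on a well-conditioned operator the solver
        # must drive ||Ax - b|| to zero, i.e. solve the linear system
        x_true = checkers32[:16, :16]
        op = make_operator(gaussian_psf(0.5, 5), x_true.shape)
        b = op.apply(x_true)
        constraint = make_constraint(0.0, 15.0, b.size)
        D = make_denoiser("identity")
        cfg = SolverConfig(gamma=1.05, tol=1e-12, max_iter=400)
        res = cpnp_restore(b, op, constraint, D, cfg)
        rel_resid = np.linalg.norm(op.apply(res.x_star) - b) / np.linalg.norm(b)
        assert rel_resid < 1e-4
        A = dense_matrix(op)
        x_ls = np.linalg.solve(A, b.ravel())
        assert np.linalg.norm(res.x_star.ravel() - x_ls) / np.linalg.norm(x_ls) < 1e-3

    def test_tikhonov_limit_matches_discrepancy_oracle(self):
        # CPnP with the quadratic prox solves min (alpha/2)||x||^2 subject to
        # the residual ball; the oracle bisects the Lagrange multiplier with
        # dense linear algebra until the residual hits the radius
        rng = np.random.default_rng(12)
        x_true = np.zeros((24, 24))
        x_true[6:18, 6:18] = 200.0
        op = make_operator(gaussian_psf(1.0), x_true.shape)
        b = op.apply(x_true) + rng.normal(0, 10.0, x_true.shape)
        constraint = make_constraint(1.0, 10.0, b.size)
        alpha = 1.0
        A = dense_matrix(op)
        bv = b.ravel()
        AtA, Atb = A.T @ A, A.T @ bv
        eye = np.eye(b.size)

        def residual_at(nu):
            xs = np.linalg.solve(alpha * eye + nu * AtA, nu * Atb)
            return np.linalg.norm(A @ xs - bv), xs

        lo, hi = 1e-8, 1e8
        for _ in range(120):
            mid = np.sqrt(lo * hi)
            rn, _ = residual_at(mid)
            if rn > constraint.radius:
                lo = mid
            else:
                hi = mid
        _, x_oracle = residual_at(np.sqrt(lo * hi))

        D = make_denoiser("tikhonov", {"alpha": alpha})
        cfg = SolverConfig(gamma=1.0, tol=1e-12, max_iter=3000)
        res = cpnp_restore(b, op, constraint, D, cfg)
        rel = np.linalg.norm(res.x_star.ravel() - x_oracle) / np.linalg.norm(x_oracle)
        assert rel <= 1e-3

    def test_single_iteration_contract(self, deblur_task_64):
        D = make_denoiser("tv", {"strength": 8.0})
        constraint = make_constraint(1.0, deblur_task_64["sigma_eta"],
                                     deblur_task_64["b"].size)
        res = cpnp_restore(deblur_task_64["b"], deblur_task_64["op"], constraint,
                           D, SolverConfig(max_iter=1))
        assert res.iterations == 1 and len(res.history) == 1
        assert not res.converged

    def test_history_records_diagnostics(self, deblur_task_64):
        D = make_denoiser("tv", {"strength": 8.0})
        constraint = make_constraint(1.0, deblur_task_64["sigma_eta"],
                                     deblur_task_64["b"].size)
        res = cpnp_restore(deblur_task_64["b"], deblur_task_64["op"], constraint,
                           D, SolverConfig(max_iter=5))
        for rec in res.history:
            assert set(rec) == {"rel_change", "residual_norm", "sigma_x",
                                "beta_r", "beta_v"}
        assert res.history[1]["beta_r"] == pytest.approx(1.01)
        assert res.sigma_x_star == res.history[-1]["sigma_x"]

    def test_bit_identical_determinism(self, deblur_task_64):
        D = make_denoiser("tv", {"strength": 8.0})
        constraint = make_constraint(1.0, deblur_task_64["sigma_eta"],
                                     deblur_task_64["b"].size)
        cfg = SolverConfig(max_iter=10)
        res1 = cpnp_restore(deblur_task_64["b"], deblur_task_64["op"], constraint, D, cfg)
        res2 = cpnp_restore(deblur_task_64["b"], deblur_task_64["op"], constraint, D, cfg)
        np.testing.assert_array_equal(res1.x_star, res2.x_star)
        assert res1.history == res2.history

    def test_feasibility_and_activity_at_convergence(self, deblur_task_64):
        # active constraint: the restored residual lands on the ball boundary
        constraint = make_constraint(1.0, deblur_task_64["sigma_eta"],
                                     deblur_task_64["b"].size)
        D = make_denoiser("tv", {"strength": 8.0})
        res = cpnp_restore(deblur_task_64["b"], deblur_task_64["op"], constraint, D)
        resid = np.linalg.norm(
            deblur_task_64["op"].apply(res.x_star) - deblur_task_64["b"])
        assert resid <= constraint.radius * 1.01
        assert resid >= constraint.radius * 0.98


class TestHQSBaseline:
    def test_identity_problem_converges_to_data(self):
        rng = np.random.default_rng(3)
        b = rng.uniform(0, 255, (16, 16))
        op = _delta_operator(b.shape)
        D = make_denoiser("identity")
        res = pnp_hqs_restore(b, op, D, 1.0, SolverConfig(tol=1e-10, max_iter=50))
        np.testing.assert_allclose(res.x_star, b, atol=1e-6)

    def test_quadratic_prox_matches_tikhonov_closed_form(self):
        # HQS with D = tikhonov(alpha) at fixed mu has fixed point
        # (A^T A + w I)^{-1} A^T b with w = mu*alpha/(1+alpha)
        rng = np.random.default_rng(4)
        b = rng.uniform(0, 255, (16, 16))
        op = make_operator(gaussian_psf(1.0), b.shape)
        alpha, mu = 0.5, 2.0
        D = make_denoiser("tikhonov", {"alpha": alpha})
        res = pnp_hqs_restore(b, op, D, mu, SolverConfig(tol=1e-14, max_iter=2000))
        A = dense_matrix(op)
        w = mu * alpha / (1 + alpha)
        x_closed = np.linalg.solve(A.T @ A + w * np.eye(b.size), A.T @ b.ravel())
        rel = np.linalg.norm(res.x_star.ravel() - x_closed) / np.linalg.norm(x_closed)
        assert rel <= 1e-6

    def test_grid_tuned_hqs_within_one_db_of_cpnp(self, deblur_task_64):
        D = make_denoiser("tv", {"strength": 8.0})
        constraint = make_constraint(1.0, deblur_task_64["sigma_eta"],
                                     deblur_task_64["b"].size)
        cpnp_res = cpnp_restore(deblur_task_64["b"], deblur_task_64["op"], constraint, D)
        cpnp_psnr = psnr(cpnp_res.x_star, deblur_task_64["x_true"])
        best = -np.inf
        for mu in (0.05, 0.1, 0.2, 0.5, 1.0, 2.0):
            res = pnp_hqs_restore(deblur_task_64["b"], deblur_task_64["op"], D, mu)
            best = max(best, psnr(res.x_star, deblur_task_64["x_true"]))
        assert best >= cpnp_psnr - 1.0

    def test_nonpositive_penalty_rejected(self):
        b = np.ones((8, 8))
        op = _delta_operator(b.shape)
        with pytest.raises(ValueError):
            pnp_hqs_restore(b, op, make_denoiser("identity"), 0.0)


class TestREDBaseline:
    def test_identity_denoiser_reduces_to_least_squares(self):
        # D = identity makes the RED prior vanish: solution is the LS fit
        rng = np.random.default_rng(5)
        x_true = rng.uniform(0, 255, (16, 16))
        op = make_operator(gaussian_psf(0.3, 3), x_true.shape)
        b = op.apply(x_true)
        D = make_denoiser("identity")
        res = red_admm_restore(b, op, D, mu=0.7,
                               cfg=SolverConfig(beta_v0=1.3, gamma=1.0,
                                                tol=1e-13, max_iter=3000))
        A = dense_matrix(op)
        x_ls = np.linalg.solve(A, b.ravel())
        rel = np.linalg.norm(res.x_star.ravel() - x_ls) / np.linalg.norm(x_ls)
        assert rel < 1e-5

    def test_quadratic_red_matches_closed_form(self):
        # with D = tikhonov(alpha) the RED objective is quadratic:
        # 1/2||Ax-b||^2 + (mu alpha)/(2(1+alpha)) ||x||^2
        rng = np.random.default_rng(6)
        b = rng.uniform(0, 255, (16, 16))
        op = make_operator(gaussian_psf(1.0), b.shape)
        alpha, mu = 0.8, 3.0
        D = make_denoiser("tikhonov", {"alpha": alpha})
        res = red_admm_restore(b, op, D, mu,
                               SolverConfig(gamma=1.0, tol=1e-14, max_iter=5000))
        A = dense_matrix(op)
        w = mu * alpha / (1 + alpha)
        x_closed = np.linalg.solve(A.T @ A + w * np.eye(b.size), A.T @ b.ravel())
        rel = np.linalg.norm(res.x_star.ravel() - x_closed) / np.linalg.norm(x_closed)
        assert rel <= 1e-6

    def test_produces_comparable_result_object(self, deblur_task_64):
        D = make_denoiser("tv", {"strength": 8.0})
        res = red_admm_restore(deblur_task_64["b"], deblur_task_64["op"], D, mu=0.5,
                               cfg=SolverConfig(max_iter=30))
        assert res.method == "red"
        assert res.x_star.shape == deblur_task_64["b"].shape
        assert len(res.history) == res.iterations

    def test_nonpositive_mu_rejected(self):
        b = np.ones((8, 8))
        op = _delta_operator(b.shape)
        with pytest.raises(ValueError):
            red_admm_restore(b, op, make_denoiser("identity"), mu=0.0)
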