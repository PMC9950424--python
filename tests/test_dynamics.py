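import numpy as np
import pytest
from scipy.integrate import solve_ivp

from adprog.dynamics import (
    AffineSystem,
    CovariateVector,
    VelocityParams,
    assemble_system,
    solve_trajectory,
    sparsity_mask,
    velocity_at,
)

from conftest import random_stable_system, random_velocity_params


class TestAssembleSystem:
    def test_zero_covariates_give_baseline_matrix(self):
        rng = np.random.default_rng(1)
        params = random_velocity_params(rng)
        sys = assemble_system(params, CovariateVector(age_std=0.0, apoe4=0))
        np.testing.assert_array_equal(sys.A, params.V)
        np.testing.assert_array_equal(sys.b, params.v0)

    def test_null_parameters_give_null_system(self):
        sys = assemble_system(VelocityParams.zeros(), CovariateVector(age_std=0.7, apoe4=1))
        assert not sys.A.any() and not sys.b.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_elementwise_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = random_velocity_params(rng)
        sys = assemble_system(params, CovariateVector(age_std=1.0, apoe4=1))
        expected = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                expected[i, j] = params.V[i, j] + params.W_age[i, j] + params.W_apoe[i, j]
        np.testing.assert_allclose(sys.A, expected, atol=0)

    def test_sparsity_violation_rejected(self):
        V = np.zeros((5, 5))
        V[0, 3] = 0.1  # CSF row, cognitive column
        with pytest.raises(ValueError, match="block"):
            VelocityParams(V=V, W_age=np.zeros((5, 5)), W_apoe=np.zeros((5, 5)), v0=np.zeros(5))


class TestVelocityAt:
    def test_origin_returns_intercept(self):
        rng = np.random.default_rng(2)
        A, b = random_stable_system(rng)
        np.testing.assert_array_equal(velocity_at(np.zeros(5), AffineSystem(A, b)), b)

    def test_null_system_is_static(self):
        assert not velocity_at(np.ones(5), AffineSystem(np.zeros((5, 5)), np.zeros(5))).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_row_dot_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A, b = random_stable_system(rng)
        x = rng.standard_normal(5)
        expected = np.array([sum(A[i, j] * x[j] for j in range(5)) + b[i] for i in range(5)])
        np.testing.assert_allclose(velocity_at(x, AffineSystem(A, b)), expected, atol=1e-14)


class TestSolveTrajectory:
    times = np.linspace(-5.0, 12.0, 30)

    def test_null_system_constant_solution(self):
        x0 = np.arange(5.0)
        traj = solve_trajectory(x0, AffineSystem(np.zeros((5, 5)), np.zeros(5)), self.times)
        np.testing.assert_allclose(traj, np.tile(x0, (30, 1)), atol=1e-13)

    def test_pure_drift(self):
        v0 = np.array([0.1, -0.2, 0.3, 0.0, 1.0])
        x0 = np.ones(5)
        traj = solve_trajectory(x0, AffineSystem(np.zeros((5, 5)), v0), self.times)
        np.testing.assert_allclose(traj, x0 + np.outer(self.times, v0), atol=1e-12)

    def test_scalar_affine_closed_form(self):
        # 1-D subsystem dx/dt = -0.5 x + 1, x(0)=0  =>  x(t) = 2(1 - e^{-t/2})
        A = np.zeros((5, 5))
        A[0, 0] = -0.5
        b = np.zeros(5)
        b[0] = 1.0
        t = np.array([0.0, 0.5, 1.0, 2.0, 5.0])
        traj = solve_trajectory(np.zeros(5), AffineSystem(A, b), t)
        np.testing.assert_allclose(traj[:, 0], 2.0 * (1.0 - np.exp(-t / 2.0)), atol=1e-10)
        assert abs(traj[3, 0] - 2.0 * (1.0 - np.exp(-1.0))) < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_runge_kutta_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A, b = random_stable_system(rng)
        x0 = rng.standard_normal(5)
        t = np.linspace(0.0, 20.0, 41)
        exact = solve_trajectory(x0, AffineSystem(A, b), t)
        sol = solve_ivp(lambda _, x: A @ x + b, (0, 20), x0, t_eval=t, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(exact - sol.y.T)) < 1e-6

    def test_overflow_reports_offending_time(self):
        A = 5.0 * np.eye(5)
        with pytest.raises(FloatingPointError, match="t="):
            solve_trajectory(np.ones(5), AffineSystem(A, np.zeros(5)), np.array([0.0, 500.0]))


class TestFlowProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_semigroup_property(self, seed):
        rng = np.random.default_rng(seed)
        A, b = random_stable_system(rng)
        sys = AffineSystem(A, b)
        x0 = rng.standard_normal(5)
        t1, dt = 3.7, 2.9
        x_t1 = solve_trajectory(x0, sys, np.array([t1]))[0]
        via_restart = solve_trajectory(x_t1, sys, np.array([dt]))[0]
        direct = solve_trajectory(x0, sys, np.array([t1 + dt]))[0]
        np.testing.assert_allclose(via_restart, direct, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_backward_forward_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        A, b = random_stable_system(rng)
        sys = AffineSystem(A, b)
        x0 = rng.standard_normal(5)
        back = solve_trajectory(x0, sys, np.array([-6.0]))[0]
        forth = solve_trajectory(back, sys, np.array([6.0]))[0]
        np.testing.assert_allclose(forth, x0, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_csf_subsystem_ignores_cognitive_initial_values(self, seed):
        """The forced-zero block decouples biomarker dynamics from cognition."""
        rng = np.random.default_rng(seed)
        params = random_velocity_params(rng)
        sys = assemble_system(params, CovariateVector(age_std=0.4, apoe4=1))
        t = np.linspace(0.0, 15.0, 16)
        x0 = rng.standard_normal(5)
        x0_perturbed = x0.copy()
        x0_perturbed[2:] += rng.standard_normal(3)
        csf_a = solve_trajectory(x0, sys, t)[:, :2]
        csf_b = solve_trajectory(x0_perturbed, sys, t)[:, :2]
        np.testing.assert_allclose(csf_a, csf_b, atol=1e-10)

    def test_mask_marks_exactly_the_zero_block(self):
        mask = sparsity_mask()
        assert mask.sum() == 6
        assert mask[np.ix_([0, 1], [2, 3, 4])].all()
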