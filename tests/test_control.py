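import numpy as np
import pytest

from tumoropt import (
    ControlGrid,
    CostWeights,
    ModelParameters,
    Trajectory,
    adjoint_rhs,
    characterize_controls,
    cost_functional,
    evaluate_controls,
    forward_backward_sweep,
    gradient_check,
    hamiltonian,
    make_initial_state,
    rhs,
)

from conftest import random_admissible_state


@pytest.fixture(scope="module")
def weights() -> CostWeights:
    return CostWeights(A=1.0, B=10.0, C=1000.0, tf=50.0)


def grid(tf: float, step: float) -> np.ndarray:
    return np.arange(int(round(tf / step)) + 1) * step


class TestCostWeights:
    def test_validation(self):
        with pytest.raises(ValueError):
            CostWeights(B=0.0)
        with pytest.raises(ValueError):
            CostWeights(C=-1.0)
        with pytest.raises(ValueError):
            CostWeights(tf=0.0)
        assert CostWeights(A=0.0).A == 0.0  # degenerate case is allowed

    def test_second_order_condition_symbolic(self):
        """The cost integrand is strictly convex in each control: its second
        derivative is 2B (resp. 2C) > 0, so the characterized controls are
        minimizers."""
        import sympy as sp

        A, B, C, T, uE, uM = sp.symbols("A B C T uE uM", positive=True)
        L = A * T + B * uE**2 + C * uM**2
        assert sp.diff(L, uE, 2) == 2 * B
        assert sp.diff(L, uM, 2) == 2 * C


class TestControlGrid:
    def test_bounds_enforced(self):
        t = grid(1.0, 0.5)
        with pytest.raises(ValueError):
            ControlGrid(t, np.array([0.0, 1.5, 0.0]), np.zeros(3))
        with pytest.raises(ValueError):
            ControlGrid(t, np.zeros(3), np.array([-0.1, 0.0, 0.0]))

    def test_integrals(self):
        t = grid(10.0, 0.1)
        g = ControlGrid.constant(t, uE=0.3, uM=0.7)
        iE, iM = g.integrals()
        assert iE == pytest.approx(3.0)
        assert iM == pytest.approx(7.0)


class TestCostFunctional:
    def test_zero(self, weights):
        t = grid(10.0, 0.1)
        traj = Trajectory(times=t, states=np.zeros((t.size, 11)))
        assert cost_functional(traj, ControlGrid.constant(t), weights) == 0.0

    def test_constant_tumor(self):
        w = CostWeights(A=1.0, B=1.0, C=1.0, tf=50.0)
        t = grid(50.0, 0.5)
        states = np.zeros((t.size, 11))
        states[:, 0] = 1.0
        traj = Trajectory(times=t, states=states)
        assert cost_functional(traj, ControlGrid.constant(t), w) == pytest.approx(50.0)

    def test_constant_controls_closed_form(self):
        # 2*0.09*10 + 1*0.49*10 = 6.7
        w = CostWeights(A=1.0, B=2.0, C=1.0, tf=10.0)
        t = grid(10.0, 0.1)
        traj = Trajectory(times=t, states=np.zeros((t.size, 11)))
        cost = cost_functional(traj, ControlGrid.constant(t, 0.3, 0.7), w)
        assert cost == pytest.approx(6.7, rel=1e-12)

    def test_grid_mismatch_rejected(self, weights):
        t = grid(10.0, 0.1)
        traj = Trajectory(times=t, states=np.zeros((t.size, 11)))
        other = ControlGrid.constant(grid(10.0, 0.2))
        with pytest.raises(ValueError, match="time grid"):
            cost_functional(traj, other, weights)


class TestHamiltonian:
    def test_zero_adjoint_is_running_cost(self, params, weights):
        y = make_initial_state(1e7)
        H = hamiltonian(y, np.zeros(11), 0.3, 0.7, params, weights)
        expected = weights.A * 1e7 + weights.B * 0.09 + weights.C * 0.49
        assert H == pytest.approx(expected, rel=1e-12)

    def test_zero_state_only_nk_source(self, params, weights):
        lam = np.linspace(-1, 1, 11)
        H = hamiltonian(np.zeros(11), lam, 0.0, 0.0, params, weights)
        assert H == pytest.approx(lam[1] * params.b1, rel=1e-12)

    def test_dot_product_oracle(self, params, weights):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = random_admissible_state(rng)
            lam = rng.uniform(-1, 1, 11)
            uE, uM = rng.uniform(0, 1, 2)
            expected = (
                weights.A * y[0] + weights.B * uE**2 + weights.C * uM**2
                + float(np.dot(lam, rhs(y, params, uE, uM)))
            )
            got = hamiltonian(y, lam, uE, uM, params, weights)
            assert got == pytest.approx(expected, rel=1e-9)


class TestAdjointRhs:
    def test_homogeneous_zero(self, params):
        w = CostWeights(A=0.0, B=1.0, C=1.0, tf=10.0)
        y = make_initial_state(1e7)
        out = adjoint_rhs(np.zeros(11), y, params, w)
        np.testing.assert_array_equal(out, np.zeros(11))

    def test_tumor_weight_only(self, params):
        w = CostWeights(A=1.0, B=1.0, C=1.0, tf=10.0)
        y = make_initial_state(1e7)
        out = adjoint_rhs(np.zeros(11), y, params, w)
        expected = np.zeros(11)
        expected[0] = -1.0
        np.testing.assert_allclose(out, expected, rtol=0, atol=1e-12)

    def test_matches_negative_gradient_of_hamiltonian(self, params, weights):
        """Spot FD check; the exhaustive 100-point version lives in the
        acceptance suite."""
        rng = np.random.default_rng(11)
        uE, uM = 0.4, 0.6
        for _ in range(10):
            y = random_admissible_state(rng)
            lam = rng.uniform(-1, 1, 11)
            exact = adjoint_rhs(lam, y, params, weights)
            for i in range(0, 11, 3):
                h = 3e-3 * max(abs(y[i]), 1e-3)
                yp = y.copy(); yp[i] += h
                ym = y.copy(); ym[i] -= h
                fd = -(
                    hamiltonian(yp, lam, uE, uM, params, weights)
                    - hamiltonian(ym, lam, uE, uM, params, weights)
                ) / (2 * h)
                denom = max(abs(exact[i]), abs(fd))
                if denom > 1e-6:
                    assert abs(exact[i] - fd) / denom < 1e-4

    def test_limit_convention_at_zero_cd8(self, params, weights):
        # same convention as the model RHS: kill-term rows drop at ET == 0
        y = make_initial_state(1e7)
        y[2] = 0.0
        lam = np.ones(11)
        out = adjoint_rhs(lam, y, params, weights)
        assert np.all(np.isfinite(out))


class TestCharacterization:
    def test_zero_costate_gives_zero(self, params, weights):
        assert characterize_controls(np.zeros(11), params, weights) == (0.0, 0.0)

    def test_saturation(self, params):
        w = CostWeights(A=1.0, B=2.0, C=3.0, tf=10.0)
        lam = np.zeros(11)
        lam[2] = -4.0 * w.B / params.omega1      # RE ~ 2 -> clipped to 1
        uE, _ = characterize_controls(lam, params, w)
        assert uE == 1.0
        lam[2] = -10.0 * w.B / params.omega1     # deeper negative: still 1
        uE, _ = characterize_controls(lam, params, w)
        assert uE == 1.0

    def test_positive_costate_clips_to_zero(self, params, weights):
        lam = np.zeros(11)
        lam[2] = 5.0
        lam[10] = 5.0
        assert characterize_controls(lam, params, weights) == (0.0, 0.0)

    def test_interior_value(self, params):
        w = CostWeights(A=1.0, B=2.0, C=3.0, tf=10.0)
        lam = np.zeros(11)
        lam[2] = -w.B / params.omega1            # RE == 0.5
        lam[10] = -3.0 * w.C / params.omega2     # RM == 1.5 -> clipped
        uE, uM = characterize_controls(lam, params, w)
        assert uE == pytest.approx(0.5)
        assert uM == 1.0


@pytest.fixture(scope="module")
def small_solution():
    # weights with meaningful control cost so the optimality margin over
    # the constant baselines is well above the discretization error
    w = CostWeights(A=1.0, B=10.0, C=1000.0, tf=10.0)
    return forward_backward_sweep(
        1e7, weights=w, suppression=False, step=0.05, tol=1e-5, max_iter=200
    )


@pytest.fixture(scope="module")
def interior_solution():
    p = ModelParameters().replace(vE=0.0, vM=0.0)
    w = CostWeights(A=1.0, B=10.0, C=1000.0, tf=10.0)
    t = np.arange(int(round(10.0 / 0.05)) + 1) * 0.05
    return evaluate_controls(
        make_initial_state(1e7), p, w, ControlGrid.constant(t, 0.3, 0.7)
    )


class TestSweep:
    def test_zero_tumor_weight_returns_zero_controls(self):
        w = CostWeights(A=0.0, B=1.0, C=1.0, tf=5.0)
        sol = forward_backward_sweep(1e7, weights=w, step=0.05, suppression=True)
        assert sol.converged
        assert np.all(sol.controls.uE == 0.0)
        assert np.all(sol.controls.uM == 0.0)
        assert sol.cost == 0.0
        np.testing.assert_array_equal(sol.adjoints, np.zeros_like(sol.adjoints))

    def test_converges(self, small_solution):
        assert small_solution.converged
        assert small_solution.iterations < 200

    def test_transversality_exact(self, small_solution):
        np.testing.assert_array_equal(small_solution.adjoints[-1], np.zeros(11))

    def test_control_bounds(self, small_solution):
        for u in (small_solution.controls.uE, small_solution.controls.uM):
            assert u.min() >= 0.0 and u.max() <= 1.0

    def test_fixed_point_residual(self, small_solution):
        assert small_solution.control_residual <= 1e-3

    def test_cost_beats_constant_baselines(self, small_solution):
        sol = small_solution
        y0 = make_initial_state(1e7, suppression=False)
        for u in (0.0, 1.0):
            base = evaluate_controls(
                y0, sol.params, sol.weights, ControlGrid.constant(sol.times, u, u)
            )
            assert sol.cost <= base.cost

    def test_cost_history_recorded(self, small_solution):
        assert len(small_solution.cost_history) >= 2
        assert all(np.isfinite(small_solution.cost_history))

    def test_states_nonnegative(self, small_solution):
        assert small_solution.states.min() >= 0.0

    def test_infusions_zeroed(self, small_solution):
        assert small_solution.params.vE == 0.0
        assert small_solution.params.vM == 0.0

    def test_invalid_settings_rejected(self, weights):
        with pytest.raises(ValueError):
            forward_backward_sweep(1e7, weights=weights, relaxation=0.0)
        with pytest.raises(ValueError):
            forward_backward_sweep(1e7, weights=weights, relaxation=1.5)
        with pytest.raises(ValueError):
            forward_backward_sweep(1e7, weights=weights, step=-0.1)
        with pytest.raises(ValueError):
            forward_backward_sweep(1e7, weights=weights, max_iter=0)

    def test_nonconvergence_flagged_not_raised(self):
        w = CostWeights(A=1.0, B=1.0, C=1.0, tf=5.0)
        sol = forward_backward_sweep(
            1e7, weights=w, step=0.05, tol=1e-12, max_iter=2
        )
        assert not sol.converged
        assert sol.iterations == 2

    def test_deterministic(self):
        w = CostWeights(A=1.0, B=10.0, C=1000.0, tf=5.0)
        a = forward_backward_sweep(1e7, weights=w, step=0.05, max_iter=10)
        b = forward_backward_sweep(1e7, weights=w, step=0.05, max_iter=10)
        np.testing.assert_array_equal(a.controls.uE, b.controls.uE)
        np.testing.assert_array_equal(a.states, b.states)
        assert a.cost_history == b.cost_history


class TestGradientCheck:
    def test_zero_perturbation(self, interior_solution):
        assert gradient_check(interior_solution, perturbation=0.0) == 0.0

    def test_coarse_grid_tolerance(self, interior_solution):
        assert gradient_check(interior_solution, perturbation=0.1) <= 1e-3

    def test_discrepancy_shrinks_with_refinement(self):
        p = ModelParameters().replace(vE=0.0, vM=0.0)
        w = CostWeights(A=1.0, B=10.0, C=1000.0, tf=10.0)
        discrepancies = []
        for step, pert in ((0.05, 0.1), (0.025, 0.05)):
            t = np.arange(int(round(10.0 / step)) + 1) * step
            sol = evaluate_controls(
                make_initial_state(1e7), p, w, ControlGrid.constant(t, 0.3, 0.7)
            )
            discrepancies.append(gradient_check(sol, perturbation=pert))
        assert discrepancies[1] < discrepancies[0]


class TestSolutionExport:
    def test_csv_and_sidecar(self, tmp_path):
        w = CostWeights(A=1.0, B=1.0, C=1.0, tf=2.0)
        sol = forward_backward_sweep(1e7, weights=w, step=0.1, max_iter=5)
        out = tmp_path / "sol.csv"
        sol.to_csv(out)
        import json

        import pandas as pd

        df = pd.read_csv(out, comment="#")
        assert {"time", "T", "lam1", "lam11", "uE", "uM"} <= set(df.columns)
        sidecar = json.loads((tmp_path / "sol.json").read_text())
        assert "diagnostics" in sidecar and "config" in sidecar
        assert sidecar["diagnostics"]["cost"] == pytest.approx(sol.cost)
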