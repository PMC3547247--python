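"""Model right-hand sides, steady states, reductions, and Jacobians."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gcmotion.fields import ChemokineEnvironment
from gcmotion.models import (ChemotaxisParams, FullModel, MassActionParams,
                             ReceptorParams, SingleReceptorModel, ToyModel,
                             ToyParams, finite_difference_jacobian,
                             mass_action_rhs, receptor_rhs,
                             receptor_steady_state, reduced_equilibria,
                             reduced_velocity_rhs, toy_receptor_steady_state)
from gcmotion.scenarios import make_model


class TestToyModel:
    def test_zero_receptors_zero_velocity(self, toy_model):
        dy = toy_model.rhs(0.0, np.array([10.0, 0.0, 0.0, 0.0]))
        assert dy[1] == 0.0  # no receptors -> no force
        p = toy_model.params
        assert dy[2] == pytest.approx(p.pi1)
        assert dy[3] == pytest.approx(p.pi2)

    def test_no_force_at_isolated_peak(self):
        # k so large the other field is negligible at this field's centre
        env = ChemokineEnvironment.symmetric(c=20.0, w=15.7, k=400.0)
        model = ToyModel(env, ToyParams(pi1=0.3, pi2=1.0, delta1=1e-3,
                                        delta2=1e-3, gamma=1.0))
        dy = model.rhs(0.0, np.array([env.f1.center, 0.0, 1.0, 1.0]))
        assert abs(dy[1]) < 1e-12

    def test_steady_state_values(self):
        assert toy_receptor_steady_state(0.3, 0.001, 0.0) == pytest.approx(
            300.0)  # f=0: synthesis/degradation balance pi/delta
        assert toy_receptor_steady_state(0.3, 0.001, 20.0) == pytest.approx(
            0.3 / 20.001, rel=1e-12)

    def test_steady_state_monotone_in_chemokine(self):
        fs = np.linspace(0.0, 30.0, 200)
        rs = toy_receptor_steady_state(0.3, 0.001, fs)
        assert np.all(np.diff(rs) < 0)

    def test_steady_state_division_by_zero_rejected(self):
        with pytest.raises(ZeroDivisionError):
            toy_receptor_steady_state(0.3, 0.0, 0.0)

    def test_receptor_ode_converges_to_steady_state(self, toy_model):
        # hold the cell at a fixed position and integrate dr/dt alone
        x = 10.0
        f_local = toy_model.env.f1.value(x)
        p = toy_model.params
        target = toy_receptor_steady_state(p.pi1, p.delta1, f_local)
        sol = solve_ivp(lambda t, r: p.pi1 - r * f_local - p.delta1 * r,
                        (0.0, 50.0 / (p.delta1 + f_local)), [1.0],
                        rtol=1e-10, atol=1e-12)
        assert abs(sol.y[0, -1] - target) < 1e-6


class TestReducedModel:
    def test_rhs_value(self, unit_env):
        got = reduced_velocity_rhs(0.0, 2.0, unit_env)
        exp = 2.0 * unit_env.f1.gradient(0.0) + unit_env.f2.gradient(0.0)
        assert got == pytest.approx(exp, rel=1e-12)

    def test_s0_single_state_at_f2_center(self, unit_env):
        eqs = reduced_equilibria(0.0, unit_env)
        assert [(round(x, 6), s) for x, s in eqs] == [(1.5, True)]

    def test_s1_bistable_symmetric(self, unit_env):
        eqs = reduced_equilibria(1.0, unit_env)
        stable = [x for x, s in eqs if s]
        assert len(stable) == 2
        assert stable[0] == pytest.approx(-stable[1], abs=1e-9)

    def test_s45_only_dz_state_remains(self, unit_env):
        eqs = reduced_equilibria(4.5, unit_env)
        stable = [x for x, s in eqs if s]
        # exact root of 4.5 f1' + f2' = 0 (brentq oracle, xtol 1e-14)
        assert stable == [pytest.approx(-1.4924432721891063, abs=1e-6)]


class TestReceptorEquation:
    RP = ReceptorParams(pi=0.15, tau=0.06, kappa=0.5, delta=0.006)

    def test_no_ligand_limit(self):
        assert receptor_rhs(2.0, 0.0, self.RP) == pytest.approx(
            0.15 - 0.006 * 2.0)

    def test_saturation_limit(self):
        # f -> inf: loss rate tends to tau + delta
        got = receptor_rhs(2.0, 1e12, self.RP)
        assert got == pytest.approx(0.15 - (0.06 + 0.006) * 2.0, rel=1e-9)

    def test_closed_form_steady_state(self):
        # pi/(delta + tau*kappa*f/(1+kappa*f)) at f=10: 0.15/0.056
        assert receptor_steady_state(self.RP, 10.0) == pytest.approx(
            0.15 / 0.056, rel=1e-12)
        sol = solve_ivp(lambda t, r: receptor_rhs(r, 10.0, self.RP),
                        (0, 2000.0), [1.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(0.15 / 0.056, abs=1e-6)


class TestMassAction:
    MP = MassActionParams(k_on=0.1, k_off=0.05, mu=0.02, beta=0.01,
                          delta=0.004, pi=0.15, tau=0.006)

    def test_no_ligand(self):
        # with L=0 and B=I=0, binding never starts and U -> pi/tau
        sol = solve_ivp(lambda t, y: mass_action_rhs(y, 0.0, self.MP),
                        (0, 5000), [1.0, 0.0, 0.0], rtol=1e-10, atol=1e-12)
        U, B, I = sol.y[:, -1]
        assert B == 0.0 and I == 0.0
        assert U == pytest.approx(self.MP.pi / self.MP.tau, rel=1e-6)

    def test_total_receptor_flux_balance(self, rng):
        # d(U+B+I)/dt == pi - tau U - delta I identically
        for _ in range(20):
            y = rng.uniform(0, 10, size=3)
            L = rng.uniform(0, 20)
            dy = mass_action_rhs(y, L, self.MP)
            assert dy.sum() == pytest.approx(
                self.MP.pi - self.MP.tau * y[0] - self.MP.delta * y[2],
                abs=1e-9)

    def test_quasi_steady_state_reduction(self):
        """Fast binding + internalization: U+B tracks the reduced equation.

        With B in quasi-equilibrium, kappa = k_on/(k_off + mu) and the
        surface receptor r = U + B obeys the saturable loss law with
        removal rate (mu - tau) for the bound fraction and tau for the
        rest; beta = 0 isolates the reduction from recycling feedback.
        """
        mp = MassActionParams(k_on=100.0, k_off=100.0, mu=10.0, beta=0.0,
                              delta=0.0, pi=0.15, tau=0.006)
        L = 0.05
        kappa = mp.k_on / (mp.k_off + mp.mu)
        rp = ReceptorParams(pi=mp.pi, tau=mp.mu - mp.tau, kappa=kappa,
                            delta=mp.tau)
        t_end = 2000.0
        t_eval = np.linspace(100.0, t_end, 200)  # after transient
        sol3 = solve_ivp(lambda t, y: mass_action_rhs(y, L, mp),
                         (0, t_end), [1.0, 0.0, 0.0], rtol=1e-10,
                         atol=1e-12, t_eval=t_eval, method="LSODA")
        surface = sol3.y[0] + sol3.y[1]
        sol1 = solve_ivp(lambda t, r: receptor_rhs(r, L, rp), (0, t_end),
                         [1.0], rtol=1e-10, atol=1e-12, t_eval=t_eval)
        rel = np.abs(surface - sol1.y[0]) / np.abs(sol1.y[0])
        assert rel.max() < 0.05


class TestFullModel:
    def _symmetric_model(self):
        env = ChemokineEnvironment.symmetric(c=10.0, w=25.0, k=50.0)
        rp = ReceptorParams(pi=0.15, tau=0.06, kappa=0.5, delta=0.006)
        cp = ChemotaxisParams(chi=28.0, epsilon1=0.3, epsilon2=0.3,
                              gamma=5.0)
        return FullModel(env, rp, rp, cp)

    def test_symmetric_manifold_invariant(self):
        model = self._symmetric_model()
        y0 = np.array([0.0, 0.0, 1.3, 1.3])
        dy = model.rhs(0.0, y0)
        assert dy[0] == 0.0 and abs(dy[1]) < 1e-14
        sol = solve_ivp(model.rhs, (0, 200.0), y0, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(sol.y[0])) < 1e-8   # x stays on the manifold
        assert np.max(np.abs(sol.y[2] - sol.y[3])) < 1e-8

    def test_magenta_converges_green_oscillates(self):
        # steady-state vs oscillatory (k, pi1) pairs of the two-parameter
        # diagram, from the reference initial condition
        for name, osc in (("fig7_magenta", False), ("fig7_green", True)):
            model = make_model("full", __import__(
                "gcmotion.scenarios", fromlist=["SCENARIOS"]
            ).SCENARIOS[name].parameters)
            sol = solve_ivp(model.rhs, (0, 3000.0), [0.0, 1.0, 1.0, 1.0],
                            rtol=1e-8, atol=1e-10,
                            t_eval=np.linspace(2000, 3000, 500))
            spread = sol.y[0].max() - sol.y[0].min()
            assert (spread > 10.0) == osc

    def test_jacobian_symmetry_at_symmetric_equilibrium(self):
        model = self._symmetric_model()
        r_ss = model.receptor_steady_states(0.0)[0]
        J = model.jacobian(np.array([0.0, 0.0, r_ss, r_ss]))
        # x -> -x, r1 <-> r2 symmetry: P J P = J for the signed swap P
        P = np.array([[-1, 0, 0, 0], [0, -1, 0, 0],
                      [0, 0, 0, 1], [0, 0, 1, 0]], dtype=float)
        assert np.allclose(P @ J @ P, J, atol=1e-7)


class TestJacobians:
    def test_toy_far_field_spectrum(self):
        # far from both fields: block-triangular Jacobian with eigenvalues
        # {-delta1, -delta2, 0, -gamma}
        env = ChemokineEnvironment.symmetric(c=20.0, w=10.0, k=30.0)
        tp = ToyParams(pi1=0.3, pi2=1.0, delta1=0.002, delta2=0.005,
                       gamma=1.3)
        model = ToyModel(env, tp)
        J = model.jacobian(np.array([500.0, 0.0, 1.0, 1.0]))
        eigs = np.sort(np.linalg.eigvals(J).real)
        assert np.allclose(sorted([-0.002, -0.005, 0.0, -1.3]), eigs,
                           atol=1e-10)

    def test_analytic_matches_finite_difference(self, toy_model, rng):
        for _ in range(50):
            y = np.array([rng.uniform(-60, 60), rng.uniform(-5, 5),
                          rng.uniform(0, 5), rng.uniform(0, 5)])
            J_an = toy_model.jacobian(y)
            J_fd = finite_difference_jacobian(
                lambda z: toy_model.rhs(0.0, z), y)
            assert np.allclose(J_an, J_fd, rtol=1e-5, atol=1e-5)


class TestSingleReceptorVariant:
    def test_r2_frozen(self, full_scenario):
        model = make_model("single_receptor", full_scenario.parameters)
        dy = model.rhs(0.0, np.array([5.0, 1.0, 1.0, 0.7]))
        assert dy[3] == 0.0

    def test_equilibrium_matches_full_model(self, full_scenario, full_model):
        # with r2 pinned at the full model's steady-state profile the
        # algebraic fixed-point equations coincide
        frozen = make_model("single_receptor", full_scenario.parameters)
        x_full = full_model.equilibria_x()
        x_frozen = frozen.equilibria_x()
        assert np.allclose(x_full, x_frozen, atol=1e-9)


class TestNonNegativity:
    @pytest.mark.parametrize("scenario,model_name", [
        ("fig2_default", "toy"), ("fig4_default", "full")])
    def test_receptors_stay_nonnegative(self, scenario, model_name, rng):
        from gcmotion.scenarios import load_scenario
        sc = load_scenario(scenario)
        model = make_model(model_name, sc.parameters)
        for _ in range(10):
            y0 = np.array([rng.uniform(-40, 40), rng.uniform(-3, 3),
                           rng.uniform(0, 3), rng.uniform(0, 3)])
            sol = solve_ivp(model.rhs, (0, 500.0), y0, rtol=1e-8,
                            atol=1e-10)
            assert sol.y[2:].min() >= -1e-9
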