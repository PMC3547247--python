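"""Equilibrium location, stability, continuation, and Hopf detection."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gcmotion.bifurcation import (continue_equilibrium, find_equilibrium,
                                  oscillatory_window, trace_branch,
                                  trace_hopf_boundary,
                                  classify_parameter_point)
from gcmotion.fields import ChemokineEnvironment
from gcmotion.models import ToyModel, ToyParams
from gcmotion.scenarios import load_scenario, make_model


def _toy_factory(params):
    return lambda k: make_model("toy", {**params, "k": k})


def _full_factory(params):
    return lambda k: make_model("full", {**params, "k": k})


class TestFindEquilibrium:
    def test_symmetric_toy_equilibrium(self):
        env = ChemokineEnvironment.symmetric(c=20.0, w=15.7, k=30.0)
        tp = ToyParams(pi1=0.5, pi2=0.5, delta1=1e-3, delta2=1e-3,
                       gamma=1.0)
        model = ToyModel(env, tp)
        eq = find_equilibrium(model, np.array([0.1, 0.0, 1.0, 1.0]))
        assert abs(eq.state[0]) < 1e-9 and abs(eq.state[1]) < 1e-12
        r_expected = 0.5 / (1e-3 + env.f1.value(0.0))
        assert eq.state[2] == pytest.approx(r_expected, rel=1e-9)
        assert eq.state[3] == pytest.approx(r_expected, rel=1e-9)

    def test_residual_below_newton_tol(self, toy_model):
        x0 = toy_model.equilibria_x()[0]
        eq = find_equilibrium(toy_model, toy_model.equilibrium_state(x0))
        # independent rhs re-evaluation
        res = np.max(np.abs(toy_model.rhs(0.0, eq.state)))
        assert res < 1e-10

    def test_nonconvergence_reported(self, toy_model):
        with pytest.raises(RuntimeError, match="residual|singular"):
            find_equilibrium(toy_model, np.array([1e4, 1e4, -1e4, 1e4]),
                             max_iter=2)


class TestContinuation:
    def test_toy_branch_hopf_and_fold(self, toy_scenario):
        branch, points = continue_equilibrium(
            _toy_factory(toy_scenario.parameters), (20.0, 50.0), step=0.25)
        kinds = {p.label: p for p in points}
        assert "H1" in kinds and any(p.kind == "fold" for p in points)
        h1 = kinds["H1"].param_value
        fold = next(p for p in points if p.kind == "fold").param_value
        assert h1 < fold
        # between H1 and the fold the followed branch is unstable;
        # below H1 it is stable
        for eq in branch:
            if eq.param_value < h1 - 0.3:
                assert eq.stable
            elif h1 + 0.3 < eq.param_value < fold - 0.3:
                assert not eq.stable

    def test_hopf_refinement_small_real_part(self, toy_scenario):
        _, points = continue_equilibrium(
            _toy_factory(toy_scenario.parameters), (36.0, 40.0), step=0.25,
            param_tol=1e-5)
        h1 = next(p for p in points if p.kind == "hopf")
        assert abs(h1.info["max_re_pair"]) < 1e-6

    def test_symmetric_toy_relabeling_invariance(self):
        # swapping the two zones' parameters mirrors the system; the
        # oscillation window in k is identical
        base = dict(c=20.0, w=15.7, delta1=1e-3, delta2=1e-3, gamma=1.0)
        win = {}
        for tag, (a, b) in {"fwd": (0.3, 1.0), "rev": (1.0, 0.3)}.items():
            on, off = oscillatory_window(
                _toy_factory({**base, "pi1": a, "pi2": b}), (20.0, 50.0),
                step=0.25)
            win[tag] = (on.param_value, off.param_value)
        assert win["fwd"][0] == pytest.approx(win["rev"][0], abs=2e-3)
        assert win["fwd"][1] == pytest.approx(win["rev"][1], abs=2e-3)


class TestArclengthTrace:
    def test_traverses_folds(self, toy_scenario):
        pts = trace_branch(_toy_factory(toy_scenario.parameters),
                           (20.0, 50.0), ds=0.25)
        ks = np.array([p.param_value for p in pts])
        # the connected S-curve turns back in k (two folds) and then
        # continues to the upper stable branch
        assert ks.max() > 40.0
        assert np.any(np.diff(ks) < 0)
        assert pts[-1].stable

    def test_window_is_internally_consistent(self, toy_scenario):
        factory = _toy_factory(toy_scenario.parameters)
        on, off = oscillatory_window(factory, (20.0, 50.0), step=0.25)
        assert on.param_value < off.param_value
        # inside the window no stable equilibrium exists on the traced
        # curve, and simulation from near the (unstable) equilibrium
        # grows away from it
        k_mid = 0.5 * (on.param_value + off.param_value)
        model = factory(k_mid)
        x = model.equilibria_x()[0]
        y0 = model.equilibrium_state(x) + np.array([0.1, 0, 0, 0])
        sol = solve_ivp(model.rhs, (0.0, 2500.0), y0, rtol=1e-8, atol=1e-10)
        assert np.max(np.abs(sol.y[0] - x)) > 0.5


class TestStabilityAgreesWithSimulation:
    @pytest.mark.parametrize("name", ["fig7_magenta", "fig7_red",
                                      "fig7_green", "fig7_cyan"])
    def test_eigenvalues_predict_attraction(self, name):
        sc = load_scenario(name)
        model = make_model("full", sc.parameters)
        roots = model.equilibria_x()
        x = roots[np.argmin(np.abs(roots))]
        state = model.equilibrium_state(x)
        eigs = np.linalg.eigvals(model.jacobian(state))
        stable = bool(np.all(eigs.real < 0))
        y0 = state + np.array([0.5, 0.0, 0.0, 0.0])
        sol = solve_ivp(model.rhs, (0.0, 1500.0), y0, rtol=1e-8,
                        atol=1e-10, t_eval=np.linspace(1200, 1500, 100))
        drift = np.max(np.abs(sol.y[0] - x))
        if stable:
            assert drift < 0.5
        else:
            assert drift > 1.0


class TestHopfBoundary:
    def test_toy_boundary_contains_oscillatory_crosses(self, toy_scenario):
        # the three (k, pi1) pairs marked oscillatory on the two-parameter
        # diagram sit inside the per-pi1 oscillation windows
        rows = trace_hopf_boundary(
            lambda k, pi1: make_model(
                "toy", {**toy_scenario.parameters, "k": k, "pi1": pi1}),
            (25.0, 60.0), [0.35, 0.58, 0.805], step=0.5)
        crosses = {0.35: 40.0, 0.58: 45.0, 0.805: 50.0}
        for row in rows:
            k = crosses[row["p2"]]
            assert row["p1_onset"] is not None
            assert row["p1_onset"] < k < row["p1_offset"]

    def test_full_parameter_point_classification(self, full_scenario):
        # eigenvalue-based oscillatory/steady-state split at fixed k=50
        for pi1, expect in [(0.15, "oscillatory"), (0.25, "steady_state"),
                            (0.05, "steady_state")]:
            model = make_model("full", {**full_scenario.parameters,
                                        "k": 50.0, "pi1": pi1})
            assert classify_parameter_point(model) == expect
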