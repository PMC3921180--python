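"""Model bank: ODE right-hand sides, solver contract, algebraic curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from nsode.core import Dataset
from nsode.models import (
    REPRESSILATOR_TRUE_ICS,
    REPRESSILATOR_TRUE_PARAMS,
    get_model,
    default_prior,
)


def dataset_for(times, variable, sigma=1.0):
    return Dataset(
        pd.DataFrame(
            {"time": times, "variable": variable, "value": 0.0, "sigma": sigma}
        )
    )


def count_maxima(y):
    return int(np.sum((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])))


TRUTH = np.array([REPRESSILATOR_TRUE_PARAMS["alpha"], REPRESSILATOR_TRUE_PARAMS["beta"]])


@pytest.fixture(scope="module")
def repressilator_truth():
    return get_model("repressilator", fixed_ics=REPRESSILATOR_TRUE_ICS)


class TestRepressilator:
    def test_truth_sustains_oscillation(self, repressilator_truth):
        t = np.linspace(0, 50, 1001)
        sol = repressilator_truth.simulate(TRUTH, t)
        assert sol.success
        assert count_maxima(sol.state("p_cI")) >= 2

    def test_zero_alpha_decays(self, repressilator_truth):
        t = np.linspace(0, 40, 200)
        sol = repressilator_truth.simulate(np.array([0.0, 2.0]), t)
        assert np.all(np.abs(sol.states[-1]) < 1e-6)

    def test_symmetric_fixed_point(self, repressilator_truth):
        # m* = p* with m*(1 + m*^2) = alpha, found by root bracketing
        alpha = 125.0
        m_star = brentq(lambda m: m * (1 + m * m) - alpha, 0, alpha)
        model = get_model(
            "repressilator", fixed_ics={s: m_star for s in REPRESSILATOR_TRUE_ICS}
        )
        sol = model.simulate(np.array([alpha, 3.3]), np.linspace(0, 5, 20))
        np.testing.assert_allclose(sol.states, m_star, rtol=1e-4)

    def test_matches_reference_solver(self, repressilator_truth):
        t = np.arange(0, 50.1, 2.0)
        ours = repressilator_truth.simulate(TRUTH, t)

        def rhs(t, y, a, b):
            m, p = y[:3], y[3:]
            rep = np.array([p[2], p[0], p[1]])
            return np.concatenate([-m + a / (1 + rep**2), -b * (p - m)])

        y0 = np.array([REPRESSILATOR_TRUE_ICS[s] for s in ours.state_names])
        ref = solve_ivp(rhs, (0, 50), y0, args=(125.0, 2.0), t_eval=t,
                        rtol=1e-10, atol=1e-12, method="LSODA")
        scale = np.abs(ref.y.T).max()
        assert np.max(np.abs(ours.states - ref.y.T)) / scale < 1e-4

    def test_solver_tolerance_refinement_stable(self, repressilator_truth):
        t = np.arange(0, 50.1, 2.0)
        base = repressilator_truth.simulate(TRUTH, t).states
        tight = repressilator_truth.with_options(rtol=5e-7, atol=5e-9).simulate(
            TRUTH, t
        ).states
        assert np.max(np.abs(base - tight)) / np.abs(base).max() < 1e-5


class TestLotkaVolterra:
    def test_coexistence_equilibrium(self):
        model = get_model("lotka_volterra", fixed_ics={"x": 3.0 / 1.5, "y": 2.0 / 0.5})
        theta = np.array([2.0, 0.5, 3.0, 1.5])  # equilibrium (c/d, a/b)
        sol = model.simulate(theta, np.linspace(0, 10, 50))
        np.testing.assert_allclose(sol.states[:, 0], 2.0, rtol=1e-5)
        np.testing.assert_allclose(sol.states[:, 1], 4.0, rtol=1e-5)

    def test_prey_grows_exponentially_without_predator(self):
        model = get_model("lotka_volterra", fixed_ics={"x": 1.0, "y": 0.0})
        a = 0.8
        t = np.linspace(0, 5, 20)
        sol = model.simulate(np.array([a, 0.5, 1.0, 0.3]), t)
        np.testing.assert_allclose(sol.states[:, 0], np.exp(a * t), rtol=1e-5)

    def test_first_integral_conserved(self):
        a, b, c, d = 1.1, 0.4, 0.8, 0.2
        model = get_model("lotka_volterra", fixed_ics={"x": 6.0, "y": 2.0})
        tight = model.with_options(rtol=1e-10, atol=1e-12)
        sol = tight.simulate(np.array([a, b, c, d]), np.linspace(0, 30, 300))
        x, y = sol.states[:, 0], sol.states[:, 1]
        inv = d * x - c * np.log(x) + b * y - a * np.log(y)
        assert np.max(np.abs(inv - inv[0])) < 1e-6 * abs(inv[0])


class TestGoodwin:
    def test_no_production_decays(self):
        model = get_model("goodwin", fixed_ics={"x": 2.0, "y": 1.0, "z": 3.0})
        theta = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        sol = model.simulate(theta, np.linspace(0, 20, 50))
        assert np.all(sol.states[-1] < 1e-6)

    def test_high_hill_exponent_oscillates(self):
        model = get_model(
            "goodwin", hill_free=True, fixed_ics={"x": 0.1, "y": 0.2, "z": 2.5}
        )
        theta = np.array([1.0, 0.1, 1.0, 0.1, 1.0, 0.1, 10.0])
        sol = model.simulate(theta, np.linspace(0, 200, 4000))
        assert sol.success
        assert count_maxima(sol.states[:, 0]) >= 2

    def test_default_hill_is_fixed_constant(self):
        model = get_model("goodwin")
        assert "h" not in model.param_names
        assert model.constants == (2.0,)

    def test_negative_states_not_clipped(self):
        # nothing in the solver forces concentrations to stay positive
        model = get_model("goodwin", fixed_ics={"x": -1.0, "y": -0.5, "z": 0.0})
        theta = np.array([0.0, 0.5, 1.0, 0.1, 1.0, 0.1])
        sol = model.simulate(theta, np.linspace(0, 5, 20))
        assert sol.success
        assert sol.states.min() < 0


class TestSchnakenberg:
    def test_fixed_point_closed_form(self):
        a, b = 0.7, 1.3
        u_star, v_star = a + b, b / (a + b) ** 2
        model = get_model("schnakenberg", fixed_ics={"u": u_star, "v": v_star})
        sol = model.simulate(np.array([a, b, 1.0]), np.linspace(0, 10, 40))
        np.testing.assert_allclose(sol.states[:, 0], u_star, rtol=1e-5)
        np.testing.assert_allclose(sol.states[:, 1], v_star, rtol=1e-5)

    def test_limit_cycle_regime(self):
        model = get_model("schnakenberg", fixed_ics={"u": 0.5, "v": 1.0})
        sol = model.simulate(np.array([0.1, 0.5, 1.0]), np.linspace(0, 200, 4000))
        assert sol.success
        assert count_maxima(sol.states[:, 0]) >= 2

    def test_mass_bookkeeping_identity(self):
        # d(u+v)/dt = tau * (a + b - u)
        model = get_model("schnakenberg", fixed_ics={"u": 1.0, "v": 0.5})
        a, b = 0.4, 0.9
        t = np.linspace(0, 10, 2001)
        sol = model.with_options(rtol=1e-10, atol=1e-12).simulate(
            np.array([a, b, 1.0]), t
        )
        total = sol.states.sum(axis=1)
        dt = t[1] - t[0]
        lhs = np.gradient(total, dt)
        rhs = a + b - sol.states[:, 0]
        assert np.max(np.abs(lhs - rhs)[2:-2]) < 1e-3


class TestAutonomy:
    def test_time_translation_invariance(self):
        # integrating from the state at t0 reproduces the shifted solution
        model = get_model("repressilator", fixed_ics=REPRESSILATOR_TRUE_ICS)
        tight = model.with_options(rtol=1e-9, atol=1e-11)
        t = np.linspace(0, 30, 61)
        sol = tight.simulate(TRUTH, t)
        mid_state = dict(zip(sol.state_names, sol.states[30]))
        sol2 = tight.with_options(fixed_ics=mid_state).simulate(TRUTH, t[:31])
        np.testing.assert_allclose(sol2.states, sol.states[30:], rtol=1e-4, atol=1e-6)


class TestAlgebraicModels:
    def test_linear_value(self):
        model = get_model("linear")
        ds = dataset_for([0.0, 1.0], "y")
        np.testing.assert_allclose(
            model.predict(np.array([0.12, 0.20]), ds), [0.20, 0.32]
        )

    def test_sigmoid_asymptotes(self):
        model = get_model("sigmoid")
        ds = dataset_for([-1e4, 1e4], "y")
        k1, k2 = 1.4, 2.1
        pred = model.predict(np.array([k1, k2, 5.0, 0.5]), ds)
        np.testing.assert_allclose(pred, [k1, k1 + k2], atol=1e-9)

    def test_quadratic_nests_linear(self):
        quad = get_model("quadratic")
        lin = get_model("linear")
        x = np.linspace(-3, 3, 11)
        ds = dataset_for(x, "y")
        np.testing.assert_allclose(
            quad.predict(np.array([0.0, 0.7, -0.2]), ds),
            lin.predict(np.array([0.7, -0.2]), ds),
        )

    def test_tanh_curve(self):
        model = get_model("tanh")
        ds = dataset_for([0.0, 2.0], "y")
        np.testing.assert_allclose(
            model.predict(np.array([5.0, 0.25]), ds), [0.0, 5 * np.tanh(0.5)]
        )


class TestPredictContract:
    def test_overflow_parameters_fail_quietly(self):
        model = get_model("lotka_volterra")
        ds = dataset_for(np.linspace(0, 50, 20), "x")
        # explosive growth: solve must flag failure, not crash
        pred = model.predict(np.array([10.0, 0.0, 0.0, 0.0, 5.0, 0.0]), ds)
        assert np.all(np.isnan(pred))

    def test_unknown_variable_is_setup_error(self):
        model = get_model("lotka_volterra")
        frame = pd.DataFrame(
            {
                "time": [0.0, 0.0, 0.0],
                "variable": ["a", "b", "c"],
                "value": 0.0,
                "sigma": 1.0,
            }
        )
        with pytest.raises(KeyError):
            model.bind(Dataset(frame))

    def test_positional_variable_mapping(self):
        # a foreign variable name maps onto the model's designated observable
        model = get_model("lotka_volterra", fixed_ics={"x": 1.0, "y": 0.0})
        ds = dataset_for([0.0, 1.0], "p_cI")
        pred = model.predict(np.array([0.5, 0.1, 0.1, 0.1]), ds)
        np.testing.assert_allclose(pred, [1.0, np.exp(0.5)], rtol=1e-5)

    def test_normalized_output_has_unit_max(self):
        model = get_model(
            "repressilator", fixed_ics=REPRESSILATOR_TRUE_ICS
        ).with_options(normalize_output=True)
        ds = dataset_for(np.linspace(0, 50, 25), "p_cI")
        pred = model.predict(TRUTH, ds)
        assert np.max(np.abs(pred)) == pytest.approx(1.0)

    def test_default_priors_match_parameters(self):
        for name in ("repressilator", "lotka_volterra", "goodwin", "schnakenberg", "tanh"):
            model = get_model(name)
            prior = default_prior(model)
            assert prior.names == model.param_names
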