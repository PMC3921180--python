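"""Model bank: oscillatory ODE systems and algebraic curve models.

Four coupled ODE models that can all produce oscillatory time courses —
the repressilator gene circuit, Lotka-Volterra predator-prey dynamics,
the Goodwin protein/mRNA negative-feedback oscillator and the
trimolecular Schnakenberg reaction system — plus simple algebraic curves
(linear, quadratic, sigmoid, hyperbolic tangent) used for low-dimensional
regression tests.

Every model is a :class:`ModelSpec`: a named predictor mapping an
inferred parameter vector (kinetic constants first, then any inferred
initial conditions) to model values at the observed ``(time, variable)``
pairs of a :class:`~nsode.core.Dataset`.  ODE predictors integrate with
the compiled Dormand-Prince solver in :mod:`nsode._integrate`; a solve
that fails (overflow, step budget) yields NaN predictions, which the
likelihood converts to ``-inf`` — sampling never crashes on a bad
parameter point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from numba import njit

from ._integrate import dp45_solve
from .core import Dataset, PriorSpec

__all__ = [
    "ModelSpec",
    "TrajectorySolution",
    "get_model",
    "default_prior",
    "MODEL_NAMES",
    "REPRESSILATOR_TRUE_PARAMS",
    "REPRESSILATOR_TRUE_ICS",
]

# Ground-truth repressilator configuration used throughout the synthetic
# experiments: alpha (maximal transcription rate) and beta (protein/mRNA
# decay ratio), with initial conditions that start the circuit off its
# limit cycle but inside its basin.
REPRESSILATOR_TRUE_PARAMS = {"alpha": 125.0, "beta": 2.0}
REPRESSILATOR_TRUE_ICS = {
    "m_lacI": 0.0,
    "m_tetR": 0.0,
    "m_cI": 0.0,
    "p_lacI": 5.0,
    "p_tetR": 0.0,
    "p_cI": 15.0,
}


# --------------------------------------------------------------------------
# Compiled right-hand sides.  Signature: rhs(t, y, k, dy) writes into dy.
# Fixed structural constants ride at the tail of k after the kinetic
# parameters (see ModelSpec.constants).
# --------------------------------------------------------------------------

@njit(cache=True)
def _repressilator_rhs(t, y, k, dy):
    # y = (m_lacI, m_tetR, m_cI, p_lacI, p_tetR, p_cI); k = (alpha, beta, n, alpha0)
    alpha = k[0]
    beta = k[1]
    n = k[2]
    a0 = k[3]
    # cyclic repression lacI -> tetR -> cI -> lacI (mRNA i repressed by
    # the protein of the upstream gene)
    dy[0] = -y[0] + alpha / (1.0 + np.abs(y[5]) ** n) + a0
    dy[1] = -y[1] + alpha / (1.0 + np.abs(y[3]) ** n) + a0
    dy[2] = -y[2] + alpha / (1.0 + np.abs(y[4]) ** n) + a0
    dy[3] = -beta * (y[3] - y[0])
    dy[4] = -beta * (y[4] - y[1])
    dy[5] = -beta * (y[5] - y[2])


@njit(cache=True)
def _lotka_volterra_rhs(t, y, k, dy):
    # y = (x, y); k = (a, b, c, d)
    dy[0] = y[0] * (k[0] - k[1] * y[1])
    dy[1] = -y[1] * (k[2] - k[3] * y[0])


@njit(cache=True)
def _goodwin_rhs(t, y, k, dy):
    # y = (x, y, z); k = (a, b, c, d, e, f, h)
    z = y[2]
    hill = 0.0 if z <= 0.0 else z ** k[6]
    dy[0] = k[0] / (1.0 + hill) - k[1] * y[0]
    dy[1] = k[2] * y[0] - k[3] * y[1]
    dy[2] = k[4] * y[1] - k[5] * y[2]


@njit(cache=True)
def _schnakenberg_rhs(t, y, k, dy):
    # y = (u, v); k = (a, b, tau)
    uuv = y[0] * y[0] * y[1]
    dy[0] = k[2] * (k[0] - y[0] + uuv)
    dy[1] = k[2] * (k[1] - uuv)


_RHS = {
    "repressilator": _repressilator_rhs,
    "lotka_volterra": _lotka_volterra_rhs,
    "goodwin": _goodwin_rhs,
    "schnakenberg": _schnakenberg_rhs,
}


# --------------------------------------------------------------------------
# Algebraic curve models: f(x, theta) -> values
# --------------------------------------------------------------------------

def _linear(x, th):
    return th[0] * x + th[1]


def _quadratic(x, th):
    return th[0] * x ** 2 + th[1] * x + th[2]


def _sigmoid(x, th):
    # k1 + k2 / (1 + exp(-k4 (x - k3))): asymptotes k1 (x -> -inf) and k1+k2
    with np.errstate(over="ignore"):
        return th[0] + th[1] / (1.0 + np.exp(-th[3] * (x - th[2])))


def _tanh_curve(x, th):
    return th[0] * np.tanh(th[1] * x)


@dataclass(frozen=True)
class TrajectorySolution:
    """Dense ODE solution: time grid, state matrix and a success flag."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), n_state)
    success: bool
    state_names: tuple[str, ...]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]


@dataclass(frozen=True)
class ModelSpec:
    """A named predictor from parameter vectors to observed-point values.

    For ODE models the inferred vector is the kinetic constants followed
    by the initial conditions of every state *not* listed in
    ``fixed_ics`` (in state order, named ``<state>0``).  ``constants``
    are structural values fixed by the model definition (e.g. the
    repressilator Hill coefficient) appended to the kinetic block before
    reaching the compiled right-hand side.
    """

    name: str
    kinetic_names: tuple[str, ...]
    state_names: tuple[str, ...] = ()
    rhs: Callable | None = None
    constants: tuple[float, ...] = ()
    fixed_ics: dict[str, float] = field(default_factory=dict)
    obs_order: tuple[str, ...] = ()  # positional mapping of data variables
    algebraic: Callable | None = None
    rtol: float = 1e-6
    atol: float = 1e-8
    normalize_output: bool = False

    @property
    def inferred_ic_states(self) -> tuple[str, ...]:
        return tuple(s for s in self.state_names if s not in self.fixed_ics)

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.kinetic_names + tuple(f"{s}0" for s in self.inferred_ic_states)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def is_ode(self) -> bool:
        return self.rhs is not None

    # -- parameter unpacking ------------------------------------------
    def _split(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"{self.name}: expected {self.n_params} parameters "
                f"{self.param_names}, got shape {theta.shape}"
            )
        nk = len(self.kinetic_names)
        k = np.concatenate([theta[:nk], np.asarray(self.constants, dtype=float)])
        y0 = np.empty(len(self.state_names))
        j = nk
        for i, s in enumerate(self.state_names):
            if s in self.fixed_ics:
                y0[i] = self.fixed_ics[s]
            else:
                y0[i] = theta[j]
                j += 1
        return k, y0

    # -- simulation ----------------------------------------------------
    def simulate(self, theta: np.ndarray, t: np.ndarray) -> TrajectorySolution:
        """Integrate the ODE at all times in ``t`` (must include t=0 start)."""
        if not self.is_ode:
            raise TypeError(f"{self.name} is an algebraic model; call predict")
        t = np.asarray(t, dtype=float)
        k, y0 = self._split(theta)
        grid = t
        prepend = t[0] > 0.0
        if prepend:  # initial conditions are defined at time zero
            grid = np.concatenate([[0.0], t])
        states, ok = dp45_solve(self.rhs, k, y0, grid, self.rtol, self.atol)
        if prepend:
            states = states[1:]
        return TrajectorySolution(t, states, bool(ok), self.state_names)

    def _resolve_variables(self, variables: tuple[str, ...]) -> dict[str, int]:
        """Map dataset variable names to state indices.

        A variable matching a state name maps to that state; otherwise
        variables are assigned positionally along ``obs_order``.  Unknown
        variables are a configuration error raised at bind time.
        """
        mapping: dict[str, int] = {}
        order = list(self.obs_order or self.state_names)
        pos = 0
        for v in variables:
            if v in self.state_names:
                mapping[v] = self.state_names.index(v)
            else:
                if pos >= len(order):
                    raise KeyError(
                        f"{self.name}: cannot map data variable {v!r}; "
                        f"states are {self.state_names}"
                    )
                mapping[v] = self.state_names.index(order[pos])
                pos += 1
        return mapping

    def bind(self, data: Dataset) -> Callable[[np.ndarray], np.ndarray]:
        """Return a fast ``theta -> predicted values`` closure for ``data``.

        Variable mapping and time-grid bookkeeping happen once, here;
        per-call work is a single compiled ODE solve (or a vectorised
        formula evaluation for algebraic models).
        """
        times = data.times
        if self.algebraic is not None:
            f = self.algebraic
            n_par = self.n_params

            def predict_alg(theta: np.ndarray) -> np.ndarray:
                theta = np.asarray(theta, dtype=float)
                if theta.shape != (n_par,):
                    raise ValueError(f"{self.name}: expected {n_par} parameters")
                with np.errstate(all="ignore"):
                    return np.asarray(f(times, theta), dtype=float)

            return predict_alg

        var_to_state = self._resolve_variables(data.variables)
        if np.any(times < 0):
            raise ValueError("observation times must be non-negative")
        grid, inv = np.unique(np.concatenate([[0.0], times]), return_inverse=True)
        row_grid_idx = inv[1:]
        row_state_idx = np.array(
            [var_to_state[v] for v in data.frame["variable"]], dtype=int
        )
        rhs, rtol, atol = self.rhs, self.rtol, self.atol
        split = self._split
        if self.normalize_output:
            var_rows = [
                (data.frame["variable"] == v).to_numpy() for v in data.variables
            ]

        def predict_ode(theta: np.ndarray) -> np.ndarray:
            k, y0 = split(theta)
            states, ok = dp45_solve(rhs, k, y0, grid, rtol, atol)
            if not ok:
                return np.full(len(times), np.nan)
            pred = states[row_grid_idx, row_state_idx]
            if self.normalize_output:
                # scale-free fitting against amplitude-normalised data:
                # each variable's predicted trace is divided by its own
                # maximum absolute value, exactly as the data were
                pred = pred.copy()
                for rows in var_rows:
                    scale = np.max(np.abs(pred[rows]))
                    if scale == 0.0 or not np.isfinite(scale):
                        return np.full(len(times), np.nan)
                    pred[rows] = pred[rows] / scale
            return pred

        return predict_ode

    def predict(self, theta: np.ndarray, data: Dataset) -> np.ndarray:
        """One-off prediction at the dataset's observed points."""
        return self.bind(data)(theta)

    def with_options(self, **kwargs) -> "ModelSpec":
        return replace(self, **kwargs)


# --------------------------------------------------------------------------
# Registry
# --------------------------------------------------------------------------

def _make_repressilator(fixed_ics: dict[str, float] | None = None,
                        hill_n: float = 2.0, alpha0: float = 0.0) -> ModelSpec:
    return ModelSpec(
        name="repressilator",
        kinetic_names=("alpha", "beta"),
        state_names=("m_lacI", "m_tetR", "m_cI", "p_lacI", "p_tetR", "p_cI"),
        rhs=_repressilator_rhs,
        constants=(hill_n, alpha0),
        fixed_ics=dict(fixed_ics or {}),
        obs_order=("p_cI", "p_lacI"),
    )


def _make_lotka_volterra(fixed_ics=None) -> ModelSpec:
    return ModelSpec(
        name="lotka_volterra",
        kinetic_names=("a", "b", "c", "d"),
        state_names=("x", "y"),
        rhs=_lotka_volterra_rhs,
        fixed_ics=dict(fixed_ics or {}),
        obs_order=("x", "y"),
    )


def _make_goodwin(fixed_ics=None, hill_h: float = 2.0,
                  hill_free: bool = False) -> ModelSpec:
    # the classical Goodwin loop with a fixed low Hill exponent has no
    # limit cycle (oscillation needs h > 8): fits are damped transients,
    # which is the behaviour this model is meant to contribute to the
    # comparison.  Pass hill_free=True to infer h instead.
    if hill_free:
        kinetic = ("a", "b", "c", "d", "e", "f", "h")
        constants: tuple[float, ...] = ()
    else:
        kinetic = ("a", "b", "c", "d", "e", "f")
        constants = (hill_h,)
    return ModelSpec(
        name="goodwin",
        kinetic_names=kinetic,
        state_names=("x", "y", "z"),
        rhs=_goodwin_rhs,
        constants=constants,
        fixed_ics=dict(fixed_ics or {}),
        obs_order=("x", "y", "z"),
    )


def _make_schnakenberg(fixed_ics=None) -> ModelSpec:
    return ModelSpec(
        name="schnakenberg",
        kinetic_names=("a", "b", "tau"),
        state_names=("u", "v"),
        rhs=_schnakenberg_rhs,
        fixed_ics=dict(fixed_ics or {}),
        obs_order=("u", "v"),
    )


_ALGEBRAIC = {
    "linear": (("m", "c"), _linear),
    "quadratic": (("gamma", "beta", "alpha"), _quadratic),
    "sigmoid": (("k1", "k2", "k3", "k4"), _sigmoid),
    "tanh": (("theta1", "theta2"), _tanh_curve),
}

_ODE_FACTORIES = {
    "repressilator": _make_repressilator,
    "lotka_volterra": _make_lotka_volterra,
    "goodwin": _make_goodwin,
    "schnakenberg": _make_schnakenberg,
}

MODEL_NAMES = tuple(_ODE_FACTORIES) + tuple(_ALGEBRAIC)


def get_model(name: str, **options) -> ModelSpec:
    """Look up a model by registry name.

    ODE models accept ``fixed_ics={state: value}`` to pin known initial
    conditions (unpinned states become inferred parameters); the
    repressilator additionally accepts ``hill_n`` and ``alpha0``.
    """
    if name in _ODE_FACTORIES:
        return _ODE_FACTORIES[name](**options)
    if name in _ALGEBRAIC:
        if options:
            raise TypeError(f"algebraic model {name!r} takes no options")
        params, f = _ALGEBRAIC[name]
        return ModelSpec(name=name, kinetic_names=params, algebraic=f)
    raise KeyError(f"unknown model {name!r}; available: {MODEL_NAMES}")


# Default uniform prior bounds.  These are a documented, reproduction-
# sensitive choice: the repressilator's alpha prior spans both the
# stable and the oscillatory regime and its initial conditions get a
# generous non-negative range (in comparison runs its output is
# amplitude-normalised, so the natural scales still apply); the other
# comparison models share U(0, 10) on every rate and initial condition.
_INFERENCE_BOUNDS = {"alpha": (0.0, 250.0), "beta": (0.0, 10.0)}
_INFERENCE_IC_BOUNDS = (0.0, 50.0)
_COMPARISON_BOUNDS = (0.0, 10.0)

_CURVE_BOUNDS = {
    "linear": {"m": (-5.0, 5.0), "c": (-5.0, 5.0)},
    "quadratic": {"gamma": (-2.0, 2.0), "beta": (-5.0, 5.0), "alpha": (-5.0, 5.0)},
    "sigmoid": {"k1": (0.0, 10.0), "k2": (0.0, 10.0), "k3": (0.0, 10.0), "k4": (0.0, 2.0)},
    "tanh": {"theta1": (0.0, 10.0), "theta2": (0.0, 1.0)},
}


def default_prior(model: ModelSpec, context: str = "comparison") -> PriorSpec:
    """Documented default uniform prior for a bank model.

    ``context="inference"`` gives the wide repressilator bounds used for
    direct parameter estimation on un-normalised data;
    ``context="comparison"`` gives U(0, 10) on every rate and initial
    condition, appropriate after amplitude normalisation.
    """
    if model.algebraic is not None:
        bounds = _CURVE_BOUNDS[model.name]
        return PriorSpec([(p, *bounds[p]) for p in model.param_names])
    if model.name == "repressilator":
        entries = []
        for p in model.param_names:
            if p in _INFERENCE_BOUNDS:
                entries.append((p, *_INFERENCE_BOUNDS[p]))
            else:
                entries.append((p, *_INFERENCE_IC_BOUNDS))
        return PriorSpec(entries)
    if context not in ("inference", "comparison"):
        raise ValueError(f"unknown prior context {context!r}")
    return PriorSpec([(p, *_COMPARISON_BOUNDS) for p in model.param_names])
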