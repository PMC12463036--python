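"""Model abstraction and the built-in model zoo.

A :class:`ModelSpec` describes either a closed-form observable function
``h(t, θ)`` or an ODE system ``φ̇ = f(φ, θ, t)`` with an observable map
``h(φ)``.  Every analysis in this package (sensitivities, Fisher
information, profile likelihood, uncertainty bands, design) consumes a
``ModelSpec`` plus a parameter vector, so user-defined models plug in by
constructing one of these objects directly.

The zoo ships standard textbook forms of the benchmark systems:

* ``polynomial`` — cubic test function with a deliberately degenerate
  basis member that vanishes at t = 1, 2, 3.
* ``hill`` — saturating dose–response curve (the independent variable is
  ligand concentration, treated uniformly as "time" in all interfaces).
* ``nn1`` — single-hidden-layer neural network, used purely as a
  parametric family for identifiability analysis.
* ``lv`` — Lotka–Volterra predator–prey system.
* ``mm`` — Michaelis–Menten enzyme kinetics (mass-action, four states).
* ``seir`` — SEIR epidemic compartments as population fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelSpec",
    "IntegrationError",
    "ModelEvaluationError",
    "solve_states",
    "eval_observable",
    "nn_forward",
    "polynomial",
    "hill",
    "nn1",
    "lv",
    "mm",
    "seir",
    "make_model",
    "MODEL_FACTORIES",
    "DEFAULT_THETA",
]

# Solver defaults are tighter than typical because sensitivities are
# finite-differenced downstream of the solves.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """ODE integration failed (step-size collapse or non-finite state)."""


class ModelEvaluationError(RuntimeError):
    """Model output was non-finite or otherwise invalid."""


@dataclass(frozen=True)
class ModelSpec:
    """A dynamic model with parameters and an observable map.

    Parameters
    ----------
    name : str
        Identifier for reports.
    kind : {"closed_form", "ode"}
        Closed-form models evaluate ``output(times, theta)`` directly;
        ODE models integrate ``rhs`` from ``initial_state(theta)`` and
        apply ``observable`` to the state trajectory.
    param_names : tuple of str
        Unique identifiers, one per parameter (length k).
    t_domain : (float, float)
        Closed interval of admissible times.
    observable_names : tuple of str
        One identifier per observable coordinate (length L).
    output : callable, optional
        ``output(times, theta) -> (N, L)``; closed-form models only.
        Must be pure (same inputs, same output).
    rhs : callable, optional
        ``rhs(phi, theta, t) -> dphi``; ODE models only.
    initial_state : callable, optional
        ``initial_state(theta) -> (M,)`` state at ``t_domain[0]``;
        may depend on theta.
    state_names : tuple of str
        State identifiers (ODE models; length M).
    observable : callable, optional
        ``observable(states) -> observations`` mapping an ``(N, M)``
        state block to ``(N, L)`` observations.  Defaults to identity
        on ODE models when omitted.
    """

    name: str
    kind: str
    param_names: tuple[str, ...]
    t_domain: tuple[float, float]
    observable_names: tuple[str, ...]
    output: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray] | None = None
    initial_state: Callable[[np.ndarray], np.ndarray] | None = None
    state_names: tuple[str, ...] = ()
    observable: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("closed_form", "ode"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(set(self.param_names)) != len(self.param_names):
            raise ValueError("param_names must be unique")
        if self.kind == "closed_form" and self.output is None:
            raise ValueError("closed_form models require an output function")
        if self.kind == "ode" and (self.rhs is None or self.initial_state is None):
            raise ValueError("ode models require rhs and initial_state")

    @property
    def k(self) -> int:
        """Number of parameters."""
        return len(self.param_names)

    @property
    def n_observables(self) -> int:
        """Observable dimension L."""
        return len(self.observable_names)

    @property
    def state_dim(self) -> int:
        """State dimension M (1 for closed-form models)."""
        return len(self.state_names) if self.kind == "ode" else 1

    def check_theta(self, theta: Sequence[float]) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k,):
            raise ValueError(
                f"model {self.name!r} expects {self.k} parameters, got shape {theta.shape}"
            )
        return theta

    def check_times(self, times: Sequence[float]) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.t_domain
        if times.size and (times.min() < lo - 1e-12 or times.max() > hi + 1e-12):
            raise ValueError(
                f"times outside t_domain [{lo}, {hi}] for model {self.name!r}"
            )
        return times


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def solve_states(
    model: ModelSpec,
    theta: Sequence[float],
    times: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Integrate an ODE model; row j of the result is the state at times[j].

    Uses an adaptive solver with automatic stiffness handling (LSODA);
    deterministic for fixed inputs and tolerances.
    """
    if model.kind != "ode":
        raise ValueError("solve_states requires an ode model")
    theta = model.check_theta(theta)
    times = model.check_times(times)
    phi0 = np.asarray(model.initial_state(theta), dtype=float)
    t0 = model.t_domain[0]
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    if t_sorted.size == 0 or t_sorted[-1] <= t0:
        return np.tile(phi0, (len(times), 1))

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return np.asarray(model.rhs(y, theta, t), dtype=float)

    sol = solve_ivp(
        f,
        (t0, max(t_sorted[-1], t0)),
        phi0,
        method="LSODA",
        t_eval=t_sorted,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration of model {model.name!r} failed near t={sol.t[-1] if sol.t.size else t0}: "
            f"{sol.message}"
        )
    states_sorted = sol.y.T
    if not np.all(np.isfinite(states_sorted)):
        bad = t_sorted[~np.all(np.isfinite(states_sorted), axis=1)][0]
        raise IntegrationError(
            f"non-finite state for model {model.name!r} at t={bad}"
        )
    states = np.empty_like(states_sorted)
    states[order] = states_sorted
    return states


def eval_observable(
    model: ModelSpec,
    theta: Sequence[float],
    times: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Evaluate the observables h(φ(t, θ)) at each time; returns (N, L)."""
    theta = model.check_theta(theta)
    times = model.check_times(times)
    if model.kind == "closed_form":
        out = np.asarray(model.output(times, theta), dtype=float)
    else:
        states = solve_states(model, theta, times, rtol=rtol, atol=atol)
        h = model.observable
        out = states if h is None else np.asarray(h(states), dtype=float)
    out = out.reshape(len(times), model.n_observables)
    if not np.all(np.isfinite(out)):
        raise ModelEvaluationError(
            f"non-finite observable output from model {model.name!r}"
        )
    return out


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------

def polynomial() -> ModelSpec:
    """Cubic benchmark h(t;θ) = θ1 + θ2 t² + θ3 (t−1)(t−2)(t−3) + 2.

    The third basis function vanishes at t = 1, 2, 3, so data restricted
    to those times carries no information about θ3.
    """

    def output(t: np.ndarray, th: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return (th[0] + th[1] * t**2 + th[2] * (t - 1) * (t - 2) * (t - 3) + 2)[
            :, None
        ]

    return ModelSpec(
        name="polynomial",
        kind="closed_form",
        param_names=("theta1", "theta2", "theta3"),
        t_domain=(0.0, 4.0),
        observable_names=("h",),
        output=output,
    )


def hill() -> ModelSpec:
    """Hill dose–response h(x;θ) = Vmax xⁿ / (xⁿ + Kdⁿ), θ = (Vmax, Kd, n).

    The independent variable is ligand concentration x ≥ 0; it plays the
    role of "time" in every interface.  For Vmax > 0 the response is
    non-negative and bounded by Vmax.
    """

    def output(x: np.ndarray, th: np.ndarray) -> np.ndarray:
        vmax, kd, n = th
        x = np.asarray(x, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            xn = np.power(x, n, where=x > 0, out=np.zeros_like(x))
            val = np.where(x > 0, vmax * xn / (xn + kd**n), 0.0)
        return val[:, None]

    return ModelSpec(
        name="hill",
        kind="closed_form",
        param_names=("Vmax", "Kd", "n"),
        t_domain=(0.0, 4.0),
        observable_names=("response",),
        output=output,
    )


def nn_forward(
    weights: Sequence[float],
    t: float | np.ndarray,
    activation: str = "tanh",
    m_neurons: int = 1,
) -> float | np.ndarray:
    """Single-hidden-layer network Σ_m w2_m·act(w1_m·t + b1_m) + b2.

    ``weights`` is flat in the order: input weights w1 (m), input biases
    b1 (m), output weights w2 (m), output bias b2 (scalar) — length
    3·m_neurons + 1.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (3 * m_neurons + 1,):
        raise ValueError(
            f"expected {3 * m_neurons + 1} weights for {m_neurons} neurons, "
            f"got {weights.size}"
        )
    if activation not in ("relu", "tanh"):
        raise ValueError(f"unknown activation {activation!r}")
    w1 = weights[:m_neurons]
    b1 = weights[m_neurons : 2 * m_neurons]
    w2 = weights[2 * m_neurons : 3 * m_neurons]
    b2 = weights[-1]
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    pre = np.outer(t_arr, w1) + b1
    act = np.maximum(pre, 0.0) if activation == "relu" else np.tanh(pre)
    out = act @ w2 + b2
    return out if np.ndim(t) else float(out[0])


def nn1(m_neurons: int = 3, activation: str = "tanh") -> ModelSpec:
    """Single-hidden-layer network as a parametric model, k = 3·m + 1."""
    names = (
        tuple(f"w1_{j}" for j in range(m_neurons))
        + tuple(f"b1_{j}" for j in range(m_neurons))
        + tuple(f"w2_{j}" for j in range(m_neurons))
        + ("b2",)
    )

    def output(t: np.ndarray, th: np.ndarray) -> np.ndarray:
        return np.asarray(
            nn_forward(th, t, activation=activation, m_neurons=m_neurons)
        )[:, None]

    return ModelSpec(
        name=f"nn1_{activation}{m_neurons}",
        kind="closed_form",
        param_names=names,
        t_domain=(0.0, 1.0),
        observable_names=("y",),
        output=output,
    )


def _selector(state_names: tuple[str, ...], observables: Sequence[str]):
    idx = [state_names.index(s) for s in observables]

    def h(states: np.ndarray) -> np.ndarray:
        return np.asarray(states)[..., idx]

    return h


def lv(observables: Sequence[str] = ("prey", "predator")) -> ModelSpec:
    """Lotka–Volterra: ẋ = αx − βxy, ẏ = δxy − γy; θ = (α, β, δ, γ).

    Initial populations are fixed at (x0, y0) = (30, 4).
    """
    states = ("prey", "predator")

    def rhs(phi: np.ndarray, th: np.ndarray, t: float) -> np.ndarray:
        x, y = phi
        a, b, d, g = th
        return np.array([a * x - b * x * y, d * x * y - g * y])

    return ModelSpec(
        name="lv",
        kind="ode",
        param_names=("alpha", "beta", "delta", "gamma"),
        t_domain=(0.0, 20.0),
        observable_names=tuple(observables),
        rhs=rhs,
        initial_state=lambda th: np.array([30.0, 4.0]),
        state_names=states,
        observable=_selector(states, observables),
    )


def mm(observables: Sequence[str] = ("S", "P")) -> ModelSpec:
    """Michaelis–Menten mass-action kinetics, states (S, E, ES, P).

    Ṡ = −k1·S·E + k−1·ES, Ė = −k1·S·E + (k−1 + k2)·ES,
    ĖS = k1·S·E − (k−1 + k2)·ES, Ṗ = k2·ES; θ = (k1, k−1, k2).
    Conserves E + ES (total enzyme) and S + ES + P (total substrate).
    Default observables follow the substrate-and-product readout; use
    ``observables=("P",)`` for the product-only case.
    """
    states = ("S", "E", "ES", "P")

    def rhs(phi: np.ndarray, th: np.ndarray, t: float) -> np.ndarray:
        s, e, es, p = phi
        k1, km1, k2 = th
        bind = k1 * s * e
        return np.array(
            [
                -bind + km1 * es,
                -bind + (km1 + k2) * es,
                bind - (km1 + k2) * es,
                k2 * es,
            ]
        )

    return ModelSpec(
        name="mm",
        kind="ode",
        param_names=("k1", "km1", "k2"),
        t_domain=(0.0, 40.0),
        observable_names=tuple(observables),
        rhs=rhs,
        initial_state=lambda th: np.array([10.0, 1.0, 0.0, 0.0]),
        state_names=states,
        observable=_selector(states, observables),
    )


def seir(observables: Sequence[str] = ("I",)) -> ModelSpec:
    """SEIR epidemic model in population fractions; θ = (β, σ, γ).

    Ṡ = −βSI, Ė = βSI − σE, İ = σE − γI, Ṙ = γI.  The total
    S + E + I + R is conserved.  Supported observable selections include
    ("I",), ("E", "I"), ("I", "R"), and ("S", "E", "I", "R").
    """
    states = ("S", "E", "I", "R")

    def rhs(phi: np.ndarray, th: np.ndarray, t: float) -> np.ndarray:
        s, e, i, r = phi
        beta, sigma, gamma = th
        inf = beta * s * i
        return np.array([-inf, inf - sigma * e, sigma * e - gamma * i, gamma * i])

    return ModelSpec(
        name="seir",
        kind="ode",
        param_names=("beta", "sigma", "gamma"),
        t_domain=(0.0, 100.0),
        observable_names=tuple(observables),
        rhs=rhs,
        initial_state=lambda th: np.array([0.99, 0.0, 0.01, 0.0]),
        state_names=states,
        observable=_selector(states, observables),
    )


MODEL_FACTORIES: dict[str, Callable[..., ModelSpec]] = {
    "polynomial": polynomial,
    "hill": hill,
    "nn1": nn1,
    "lv": lv,
    "mm": mm,
    "seir": seir,
}

#: Reference parameter values used by the packaged configurations.
DEFAULT_THETA: dict[str, tuple[float, ...]] = {
    "polynomial": (1.0, 1.0, 1.0),
    "hill": (2.0, 1.0, 4.0),
    "lv": (0.55, 0.028, 0.024, 0.84),
    "mm": (1.0, 0.5, 0.3),
    "seir": (0.6, 0.2, 0.15),
}


def make_model(name: str, **kwargs) -> ModelSpec:
    """Instantiate a zoo model by name, forwarding factory options."""
    try:
        factory = MODEL_FACTORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; available: {sorted(MODEL_FACTORIES)}"
        ) from None
    return factory(**kwargs)
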