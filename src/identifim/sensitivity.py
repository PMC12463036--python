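"""Generalized sensitivity matrix of the observables w.r.t. parameters.

The sensitivity matrix s(θ*) stacks N time blocks, each an L×k block
with entry (l, i) = ∂h_l(φ(t_n, θ*))/∂θ_i, giving an (N·L)×k matrix.
Its Gram matrix SᵀS is the Fisher Information Matrix analysed downstream.

Two computation routes are provided: central finite differences on the
model output (any model), and forward sensitivity ODEs (ODE models),
which integrate the variational system Ż = J_f·Z + ∂f/∂θ alongside the
states.  ``method="auto"`` picks the forward route for ODE models.

Sensitivities are computed on raw (unnormalized) parameters by default;
an optional relative scaling multiplies column i by |θ*_i| and is flagged
in the result so reports can surface it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .models import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    IntegrationError,
    ModelSpec,
    eval_observable,
    solve_states,
)

__all__ = ["SensitivityMatrix", "sensitivity_matrix", "forward_sensitivity_odes"]

# Central-difference steps (relative, floored at the absolute scale 1).
FD_THETA_STEP = 1e-6
FD_STATE_STEP = 1e-7


@dataclass
class SensitivityMatrix:
    """Stacked (N·L)×k sensitivity matrix with its block-order convention.

    Block order: N time blocks, each L×k; ``block(n)`` returns the block
    for the n-th time point.
    """

    values: np.ndarray
    times: np.ndarray
    param_names: tuple[str, ...]
    n_observables: int
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n, l = len(self.times), self.n_observables
        if self.values.shape != (n * l, len(self.param_names)):
            raise ValueError(
                f"sensitivity values shape {self.values.shape} does not match "
                f"N·L={n * l}, k={len(self.param_names)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite sensitivity entries")

    @property
    def k(self) -> int:
        return len(self.param_names)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def block(self, n: int) -> np.ndarray:
        l = self.n_observables
        return self.values[n * l : (n + 1) * l]


def _fd_sensitivities(
    model: ModelSpec,
    theta: np.ndarray,
    times: np.ndarray,
    rel_step: float,
) -> np.ndarray:
    if model.kind == "ode":
        return _fd_sensitivities_ode(model, theta, times, rel_step)
    n, l, k = len(times), model.n_observables, model.k
    out = np.empty((n * l, k))
    for i in range(k):
        h = rel_step * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        diff = (eval_observable(model, tp, times) - eval_observable(model, tm, times)) / (
            2.0 * h
        )
        if not np.all(np.isfinite(diff)):
            bad = times[~np.all(np.isfinite(diff), axis=1)][0]
            raise ValueError(
                f"non-finite derivative for parameter {model.param_names[i]!r} "
                f"at t={bad}"
            )
        out[:, i] = diff.reshape(n * l)
    return out


def _fd_sensitivities_ode(
    model: ModelSpec,
    theta: np.ndarray,
    times: np.ndarray,
    rel_step: float,
) -> np.ndarray:
    """Central differences via a single joint integration of all 2k
    perturbed trajectories.

    Integrating the copies together makes them share the adaptive step
    sequence, so solver discretization error is strongly correlated
    across copies and largely cancels in the difference quotient —
    independent solves would leave noise of order rtol/(2h).  Tolerances
    are tightened for the same reason.
    """
    n, l, k, m = len(times), model.n_observables, model.k, model.state_dim
    steps = np.array([rel_step * max(1.0, abs(theta[i])) for i in range(k)])
    thetas = []
    for i in range(k):
        for sign in (+1.0, -1.0):
            tp = theta.copy()
            tp[i] += sign * steps[i]
            thetas.append(tp)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    y0 = np.concatenate([np.asarray(model.initial_state(tp), float) for tp in thetas])
    if t_sorted.size == 0 or t_sorted[-1] <= model.t_domain[0]:
        traj = np.tile(y0, (n, 1))
    else:
        def joint_rhs(t: float, y: np.ndarray) -> np.ndarray:
            out = np.empty_like(y)
            for j, tp in enumerate(thetas):
                out[j * m : (j + 1) * m] = np.asarray(
                    model.rhs(y[j * m : (j + 1) * m], tp, t), dtype=float
                )
            return out

        sol = solve_ivp(
            joint_rhs,
            (model.t_domain[0], max(t_sorted[-1], model.t_domain[0])),
            y0,
            method="LSODA",
            t_eval=t_sorted,
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                f"finite-difference sensitivity integration failed for model "
                f"{model.name!r}: {sol.message}"
            )
        traj = np.empty_like(sol.y.T)
        traj[order] = sol.y.T
    h_fn = model.observable
    out = np.empty((n * l, k))
    for i in range(k):
        sp = traj[:, (2 * i) * m : (2 * i + 1) * m]
        sm = traj[:, (2 * i + 1) * m : (2 * i + 2) * m]
        op = sp if h_fn is None else np.asarray(h_fn(sp), float)
        om = sm if h_fn is None else np.asarray(h_fn(sm), float)
        diff = (op.reshape(n, l) - om.reshape(n, l)) / (2.0 * steps[i])
        if not np.all(np.isfinite(diff)):
            raise ValueError(
                f"non-finite derivative for parameter {model.param_names[i]!r}"
            )
        out[:, i] = diff.reshape(n * l)
    return out


def forward_sensitivity_odes(
    model: ModelSpec,
    theta: Sequence[float],
    times: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate states and state sensitivities Z = ∂φ/∂θ jointly.

    The augmented system is Ż = J_f(φ,θ)·Z + ∂f/∂θ with
    Z(0) = ∂φ0/∂θ; J_f and ∂f/∂θ are obtained by central differences
    on the right-hand side.

    Returns
    -------
    states : (N, M) array
    sens : (N, M, k) array — rows align with states, columns with
        parameters.
    """
    if model.kind != "ode":
        raise ValueError("forward_sensitivity_odes requires an ode model")
    theta = model.check_theta(theta)
    times = model.check_times(times)
    m, k = model.state_dim, model.k
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]

    def f(phi: np.ndarray, th: np.ndarray, t: float) -> np.ndarray:
        return np.asarray(model.rhs(phi, th, t), dtype=float)

    def jac_state(phi: np.ndarray, t: float) -> np.ndarray:
        J = np.empty((m, m))
        for j in range(m):
            h = FD_STATE_STEP * max(1.0, abs(phi[j]))
            pp, pm = phi.copy(), phi.copy()
            pp[j] += h
            pm[j] -= h
            J[:, j] = (f(pp, theta, t) - f(pm, theta, t)) / (2.0 * h)
        return J

    def jac_theta(phi: np.ndarray, t: float) -> np.ndarray:
        J = np.empty((m, k))
        for i in range(k):
            h = FD_THETA_STEP * max(1.0, abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            J[:, i] = (f(phi, tp, t) - f(phi, tm, t)) / (2.0 * h)
        return J

    def z0() -> np.ndarray:
        Z = np.empty((m, k))
        for i in range(k):
            h = FD_THETA_STEP * max(1.0, abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            Z[:, i] = (
                np.asarray(model.initial_state(tp), float)
                - np.asarray(model.initial_state(tm), float)
            ) / (2.0 * h)
        return Z

    def aug_rhs(t: float, y: np.ndarray) -> np.ndarray:
        phi = y[:m]
        Z = y[m:].reshape(m, k)
        dphi = f(phi, theta, t)
        dZ = jac_state(phi, t) @ Z + jac_theta(phi, t)
        return np.concatenate([dphi, dZ.reshape(-1)])

    y0 = np.concatenate(
        [np.asarray(model.initial_state(theta), float), z0().reshape(-1)]
    )
    if t_sorted.size == 0 or t_sorted[-1] <= model.t_domain[0]:
        y_flat = np.tile(y0, (len(times), 1))
        return y_flat[:, :m], y_flat[:, m:].reshape(len(times), m, k)
    sol = solve_ivp(
        aug_rhs,
        (model.t_domain[0], max(t_sorted[-1], model.t_domain[0])),
        y0,
        method="LSODA",
        t_eval=t_sorted,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(
            f"forward sensitivity integration failed for model {model.name!r}: "
            f"{sol.message}"
        )
    y_sorted = sol.y.T
    y = np.empty_like(y_sorted)
    y[order] = y_sorted
    states = y[:, :m]
    sens = y[:, m:].reshape(len(times), m, k)
    return states, sens


def _observable_jacobian(model: ModelSpec, state: np.ndarray) -> np.ndarray:
    """∂h/∂φ at one state point, (L, M), by central differences on h."""
    m, l = model.state_dim, model.n_observables
    h = model.observable
    if h is None:
        return np.eye(m)
    J = np.empty((l, m))
    for j in range(m):
        step = FD_STATE_STEP * max(1.0, abs(state[j]))
        sp, sm = state.copy(), state.copy()
        sp[j] += step
        sm[j] -= step
        J[:, j] = (
            np.asarray(h(sp[None, :]), float).reshape(l)
            - np.asarray(h(sm[None, :]), float).reshape(l)
        ) / (2.0 * step)
    return J


def sensitivity_matrix(
    model: ModelSpec,
    theta: Sequence[float],
    times: Sequence[float],
    method: str = "auto",
    rel_step: float = FD_THETA_STEP,
    scaled: bool = False,
) -> SensitivityMatrix:
    """Build the stacked sensitivity matrix s(θ*).

    ``method="auto"`` dispatches to forward sensitivity ODEs for ODE
    models and central finite differences otherwise.  The chain rule
    through the observable map h is applied for ODE models.
    """
    theta = model.check_theta(theta)
    times = model.check_times(times)
    if method == "auto":
        method = "forward_ode" if model.kind == "ode" else "finite_difference"
    if method == "forward_ode":
        if model.kind != "ode":
            raise ValueError("forward_ode method requires an ode model")
        states, sens = forward_sensitivity_odes(model, theta, times)
        l = model.n_observables
        values = np.empty((len(times) * l, model.k))
        for n in range(len(times)):
            dh = _observable_jacobian(model, states[n])
            values[n * l : (n + 1) * l] = dh @ sens[n]
    elif method == "finite_difference":
        values = _fd_sensitivities(model, theta, times, rel_step)
    else:
        raise ValueError(f"unknown sensitivity method {method!r}")
    if scaled:
        values = values * np.abs(theta)[None, :]
    return SensitivityMatrix(
        values=values,
        times=times,
        param_names=model.param_names,
        n_observables=model.n_observables,
        scaled=scaled,
    )
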