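"""Least-squares parameter estimation and the regularized MAP refit.

The plain fit minimizes the sum-of-squares loss
l(θ) = Σᵢ ‖h(φ(tᵢ, θ)) − ĥᵢ‖² with a trust-region least-squares solver
whose Jacobian comes from the sensitivity module.

When the Fisher information is singular, the regularized refit adds a
ridge penalty confined to the non-identifiable subspace,
λ‖U_nullᵀ(θ − θ*)‖², which pins the flat directions to the reference
estimate θ* without biasing the identifiable ones.  The penalty is
implemented as extra residual rows √λ·U_nullᵀ(θ − θ*), so the same
least-squares machinery applies.  The information matrix of the refit is
λ·U_null·U_nullᵀ + SᵀS, which is full rank whenever U_null completes the
eigenbasis of SᵀS — every eigenvalue below the threshold is replaced by λ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .data import Dataset
from .models import ModelSpec, eval_observable
from .sensitivity import SensitivityMatrix, sensitivity_matrix

__all__ = [
    "FitResult",
    "loss",
    "fit_least_squares",
    "fit_regularized",
    "regularized_fim",
]

DEFAULT_LAMBDA = 1.0
MAX_ITERATIONS = 500


@dataclass
class FitResult:
    theta_hat: np.ndarray
    loss: float
    n_iterations: int
    converged: bool
    regularized: bool = False
    lam: float = 0.0
    u_null: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    grad_norm: float = np.nan
    objective: float | None = None  # loss + penalty when regularized

    def to_report(self) -> dict:
        return {
            "theta_hat": self.theta_hat,
            "loss": self.loss,
            "objective": self.objective if self.objective is not None else self.loss,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "regularized": self.regularized,
            "lambda": self.lam,
            "u_null_shape": list(self.u_null.shape),
            "grad_norm": self.grad_norm,
        }


def loss(model: ModelSpec, dataset: Dataset, theta: Sequence[float]) -> float:
    """Sum of squared residuals Σᵢ ‖h(φ(tᵢ, θ)) − ĥᵢ‖²."""
    theta = model.check_theta(theta)
    dataset.check_model(model)
    pred = eval_observable(model, theta, dataset.times)
    return float(np.sum((pred - dataset.observations) ** 2))


def _check_orthonormal(u_null: np.ndarray, k: int) -> np.ndarray:
    u_null = np.asarray(u_null, dtype=float)
    if u_null.size == 0:
        return u_null.reshape(k, 0)
    if u_null.ndim != 2 or u_null.shape[0] != k:
        raise ValueError(f"u_null must be k×(k−r) with k={k}, got {u_null.shape}")
    gram = u_null.T @ u_null
    if np.abs(gram - np.eye(u_null.shape[1])).max() > 1e-8:
        raise ValueError("u_null columns are not orthonormal within 1e-8")
    return u_null


def _solve(
    model: ModelSpec,
    dataset: Dataset,
    theta0: np.ndarray,
    bounds,
    extra_rows,  # callable theta -> residuals, or None
    extra_jac: np.ndarray | None,
):
    k = model.k
    if bounds is None:
        lo, hi = np.full(k, -np.inf), np.full(k, np.inf)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)

    def residuals(theta: np.ndarray) -> np.ndarray:
        base = (
            eval_observable(model, theta, dataset.times) - dataset.observations
        ).reshape(-1)
        if extra_rows is None:
            return base
        return np.concatenate([base, extra_rows(theta)])

    def jac(theta: np.ndarray) -> np.ndarray:
        J = sensitivity_matrix(model, theta, dataset.times).values
        if extra_jac is None:
            return J
        return np.vstack([J, extra_jac])

    sol = least_squares(
        residuals,
        np.clip(theta0, lo, hi),
        jac=jac,
        bounds=(lo, hi),
        method="trf",
        max_nfev=MAX_ITERATIONS,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    return sol


def fit_least_squares(
    model: ModelSpec,
    dataset: Dataset,
    theta0: Sequence[float],
    bounds: tuple | None = None,
    seed: int = 0,
    n_multistart: int = 0,
) -> FitResult:
    """Trust-region least-squares fit with analytic sensitivity Jacobian.

    ``n_multistart`` > 0 adds that many seeded log-uniform perturbations
    of ``theta0`` (factors in [2/3, 3/2]) as extra starts, keeping the
    best solution; useful for ODE models with rough loss surfaces.
    """
    theta0 = model.check_theta(theta0)
    dataset.check_model(model)
    if dataset.n_times < 1:
        raise ValueError("cannot fit an empty dataset")
    starts = [theta0]
    if n_multistart > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_multistart):
            factors = np.exp(rng.uniform(np.log(2 / 3), np.log(3 / 2), model.k))
            starts.append(theta0 * factors)
    best, failures = None, []
    for s in starts:
        try:
            sol = _solve(model, dataset, s, bounds, None, None)
        except Exception as exc:
            failures.append(str(exc))
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} fit starts failed: {failures[:3]}"
        )
    fitted_loss = float(2.0 * best.cost)
    return FitResult(
        theta_hat=best.x,
        loss=fitted_loss,
        n_iterations=int(best.nfev),
        converged=bool(best.success),
        grad_norm=float(np.abs(best.grad).max()) if best.grad is not None else np.nan,
    )


def fit_regularized(
    model: ModelSpec,
    dataset: Dataset,
    theta_star: Sequence[float],
    u_null: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    theta0: Sequence[float] | None = None,
    bounds: tuple | None = None,
) -> FitResult:
    """MAP refit: minimize loss(θ) + λ‖U_nullᵀ(θ − θ*)‖².

    With an empty ``u_null`` (no non-identifiable directions) this
    reduces exactly to :func:`fit_least_squares`.
    """
    theta_star = model.check_theta(theta_star)
    dataset.check_model(model)
    u_null = _check_orthonormal(u_null, model.k)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    theta0 = theta_star if theta0 is None else model.check_theta(theta0)
    if u_null.shape[1] == 0 or lam == 0:
        res = fit_least_squares(model, dataset, theta0, bounds=bounds)
        res.regularized = True
        res.lam = float(lam)
        res.u_null = u_null
        res.objective = res.loss
        return res
    sqlam = np.sqrt(lam)
    anchor = u_null.T @ theta_star

    def extra_rows(theta: np.ndarray) -> np.ndarray:
        return sqlam * (u_null.T @ theta - anchor)

    sol = _solve(model, dataset, theta0, bounds, extra_rows, sqlam * u_null.T)
    data_loss = loss(model, dataset, sol.x)
    return FitResult(
        theta_hat=sol.x,
        loss=data_loss,
        n_iterations=int(sol.nfev),
        converged=bool(sol.success),
        regularized=True,
        lam=float(lam),
        u_null=u_null,
        grad_norm=float(np.abs(sol.grad).max()) if sol.grad is not None else np.nan,
        objective=float(2.0 * sol.cost),
    )


def regularized_fim(
    S: SensitivityMatrix | np.ndarray,
    u_null: np.ndarray,
    lam: float,
) -> np.ndarray:
    """Information matrix of the regularized refit: λ·U_null·U_nullᵀ + SᵀS.

    When ``u_null`` spans the null eigendirections of SᵀS, the spectrum
    equals the retained eigenvalues plus λ with multiplicity k−r, so the
    result is full rank for any λ > 0.
    """
    values = S.values if isinstance(S, SensitivityMatrix) else np.asarray(S, float)
    k = values.shape[1]
    u_null = _check_orthonormal(u_null, k)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    F = values.T @ values + lam * (u_null @ u_null.T)
    return (F + F.T) / 2.0
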