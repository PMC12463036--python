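"""Prediction uncertainty from null-space parameter perturbations.

Perturbations are restricted to the non-identifiable subspace: θ̂ = θ̃ +
U_null·ε with ε ~ N(0, τ²I), giving parameter covariance
Cov(θ̂) = τ²·U_null·U_nullᵀ.  First-order propagation through the
observable sensitivities yields Var(h_l(t)) = ∇θh_l·Cov·∇θh_lᵀ and the
normal-approximation confidence band mean ± z_{α/2}·√Var.  Because the
null directions leave the fit unchanged to first order, the band
collapses to (numerically) zero width at the data times for models whose
sensitivities annihilate U_null exactly — the signature that the retained
uncertainty is genuinely invisible to the data.

A seeded Monte-Carlo band (empirical quantiles over model evaluations at
sampled θ̂) is available for nonlinear models where the linearization is
suspect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .models import ModelSpec, eval_observable
from .sensitivity import sensitivity_matrix

__all__ = [
    "UncertaintyBand",
    "nullspace_covariance",
    "predictive_variance",
    "confidence_band",
    "analytic_band",
    "monte_carlo_band",
    "default_tau",
]


@dataclass
class UncertaintyBand:
    times: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    tau: float
    method: str  # "analytic" | "monte_carlo"

    def to_report(self) -> dict:
        return {
            "times": self.times,
            "mean": self.mean,
            "variance": self.variance,
            "lower": self.lower,
            "upper": self.upper,
            "alpha": self.alpha,
            "tau": self.tau,
            "method": self.method,
        }


def default_tau(theta: Sequence[float]) -> float:
    """Default null-space perturbation scale: 0.1·max(1, ‖θ‖)/√k."""
    theta = np.asarray(theta, dtype=float)
    return 0.1 * max(1.0, float(np.linalg.norm(theta))) / np.sqrt(theta.size)


def _check_u_null(u_null: np.ndarray) -> np.ndarray:
    u_null = np.asarray(u_null, dtype=float)
    if u_null.ndim != 2:
        raise ValueError("u_null must be a 2-D k×(k−r) matrix")
    if u_null.shape[1] > 0:
        gram = u_null.T @ u_null
        if np.abs(gram - np.eye(u_null.shape[1])).max() > 1e-8:
            raise ValueError("u_null columns are not orthonormal within 1e-8")
    return u_null


def nullspace_covariance(u_null: np.ndarray, tau: float) -> np.ndarray:
    """Parameter covariance τ²·U_null·U_nullᵀ (rank k−r, PSD)."""
    u_null = _check_u_null(u_null)
    if tau < 0:
        raise ValueError("tau must be non-negative")
    k = u_null.shape[0]
    if u_null.shape[1] == 0:
        return np.zeros((k, k))
    cov = tau**2 * (u_null @ u_null.T)
    return (cov + cov.T) / 2.0


def predictive_variance(
    model: ModelSpec,
    theta_tilde: Sequence[float],
    cov: np.ndarray,
    times: Sequence[float],
) -> np.ndarray:
    """First-order propagated variance per observable and grid time.

    Var(h_l(t)) = ∇θh_l(φ(t, θ̃))·cov·∇θh_l(φ(t, θ̃))ᵀ, with gradients
    from the sensitivity module.  Returns an (N_grid, L) matrix clipped
    at zero.
    """
    theta_tilde = model.check_theta(theta_tilde)
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (model.k, model.k):
        raise ValueError(f"cov must be {model.k}×{model.k}, got {cov.shape}")
    if np.abs(cov - cov.T).max() > 1e-8 * (1.0 + np.abs(cov).max()):
        raise ValueError("cov must be symmetric")
    S = sensitivity_matrix(model, theta_tilde, times).values
    var_rows = np.einsum("ij,jk,ik->i", S, cov, S)
    return np.clip(var_rows, 0.0, None).reshape(len(np.atleast_1d(times)), -1)


def confidence_band(
    mean: np.ndarray, variance: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normal-approximation band mean ± z_{α/2}·√variance."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(np.clip(variance, 0.0, None))
    return mean - half, mean + half


def evaluation_grid(
    model: ModelSpec, data_times: Sequence[float] | None = None, n_points: int = 200
) -> np.ndarray:
    """Default band grid: uniform over t_domain plus all data times."""
    grid = np.linspace(*model.t_domain, n_points)
    if data_times is not None:
        grid = np.unique(np.concatenate([grid, np.atleast_1d(data_times)]))
    return grid


def analytic_band(
    model: ModelSpec,
    theta_tilde: Sequence[float],
    u_null: np.ndarray,
    tau: float,
    alpha: float = 0.05,
    times: Sequence[float] | None = None,
) -> UncertaintyBand:
    """Analytic null-space band from first-order propagation."""
    theta_tilde = model.check_theta(theta_tilde)
    if times is None:
        times = evaluation_grid(model)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    cov = nullspace_covariance(u_null, tau)
    mean = eval_observable(model, theta_tilde, times)
    variance = predictive_variance(model, theta_tilde, cov, times)
    lower, upper = confidence_band(mean, variance, alpha)
    return UncertaintyBand(
        times=times,
        mean=mean,
        variance=variance,
        lower=lower,
        upper=upper,
        alpha=float(alpha),
        tau=float(tau),
        method="analytic",
    )


def monte_carlo_band(
    model: ModelSpec,
    theta_tilde: Sequence[float],
    u_null: np.ndarray,
    tau: float,
    n_samples: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    times: Sequence[float] | None = None,
) -> UncertaintyBand:
    """Empirical quantile band over seeded null-space parameter draws."""
    theta_tilde = model.check_theta(theta_tilde)
    u_null = _check_u_null(u_null)
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if times is None:
        times = evaluation_grid(model)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    mean = eval_observable(model, theta_tilde, times)
    rng = np.random.default_rng(seed)
    eps = tau * rng.standard_normal((n_samples, u_null.shape[1]))
    draws, dropped = [], 0
    for row in eps:
        try:
            draws.append(eval_observable(model, theta_tilde + u_null @ row, times))
        except Exception:
            dropped += 1
    if dropped:
        warnings.warn(f"monte_carlo_band: dropped {dropped} failed draws", stacklevel=2)
        if dropped > 0.1 * n_samples:
            raise RuntimeError(
                f"monte_carlo_band: {dropped}/{n_samples} draws failed (>10%)"
            )
    stack = np.stack(draws) if draws else mean[None]
    lower = np.quantile(stack, alpha / 2.0, axis=0)
    upper = np.quantile(stack, 1.0 - alpha / 2.0, axis=0)
    variance = stack.var(axis=0, ddof=1) if len(stack) > 1 else np.zeros_like(mean)
    return UncertaintyBand(
        times=times,
        mean=mean,
        variance=variance,
        lower=lower,
        upper=upper,
        alpha=float(alpha),
        tau=float(tau),
        method="monte_carlo",
    )
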