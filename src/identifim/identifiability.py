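"""Fisher-information eigenanalysis and identifiability diagnostics.

Core quantities
---------------
* Fisher Information Matrix F = SᵀS of the sensitivity matrix S.
* Thresholded eigendecomposition F = UΣUᵀ splitting parameter space into
  identifiable directions Ur (eigenvalues above a threshold eps_eig) and
  non-identifiable directions U_null.
* Per-coordinate metric ‖(I − AA†)sᵢ‖∞ — the ∞-norm of the residual of
  sensitivity column sᵢ projected onto the span A of the remaining
  columns.  It is zero exactly when sᵢ ∈ range(A), i.e. when parameter i
  is non-identifiable given the others; larger values mean the data pin
  the parameter down more strongly.
* Profile likelihood PL(ĥ | θᵢ) = min over the other parameters of the
  least-squares loss, the classical benchmark the coordinate metric
  linearizes.
* Contribution index ξ = σmin/σmax of the FIM, a scalar summary of how
  evenly a dataset informs all parameter directions.
* Structural rank test: numerical column rank of S on a dense time grid —
  full column rank on a sufficiently rich grid indicates structural
  identifiability.
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
    "FIMAnalysis",
    "CoordinateReport",
    "ProfileCurve",
    "LinearizedProblem",
    "fim",
    "eigendecompose_fim",
    "coordinate_metric",
    "profile_likelihood",
    "contribution_index",
    "structural_rank_test",
    "linearized_problem",
]

# SVD rank cutoff for pseudoinverse projections (relative to the largest
# singular value).
DEFAULT_TOL_RANK = 1e-10
# Relative flatness tolerance for profile-likelihood classification.
DEFAULT_TOL_FLAT = 1e-6


@dataclass
class FIMAnalysis:
    """Eigendecomposition F = UΣUᵀ split at a threshold.

    ``u_ident`` holds the first r eigenvector columns (eigenvalues above
    ``eps_eig``); ``u_null`` the remaining k−r columns spanning the
    non-identifiable subspace.
    """

    F: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    eps_eig: float
    param_names: tuple[str, ...] = ()
    near_degenerate: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.F.shape[0]

    @property
    def r(self) -> int:
        return int(np.sum(self.eigenvalues > self.eps_eig))

    @property
    def u_ident(self) -> np.ndarray:
        return self.eigenvectors[:, : self.r]

    @property
    def u_null(self) -> np.ndarray:
        return self.eigenvectors[:, self.r :]

    @property
    def full_rank(self) -> bool:
        return self.r == self.k

    def to_report(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues,
            "eigenvectors": self.eigenvectors,
            "r": self.r,
            "k": self.k,
            "eps_eig": self.eps_eig,
            "param_names": list(self.param_names),
            "contribution_index": contribution_index(self.F),
            "near_degenerate": self.near_degenerate,
        }


@dataclass
class CoordinateReport:
    """Per-parameter identifiability metric ‖(I − AA†)sᵢ‖∞ and flags."""

    metric: np.ndarray
    flags: np.ndarray  # True = identifiable
    param_names: tuple[str, ...]
    tol_coord: float
    scaled: bool = False

    def to_report(self) -> dict:
        return {
            "metric": self.metric,
            "identifiable": self.flags,
            "param_names": list(self.param_names),
            "tol_coord": self.tol_coord,
            "scaled_sensitivities": self.scaled,
        }


@dataclass
class ProfileCurve:
    """Profile likelihood trace for one parameter coordinate."""

    param_index: int
    grid: np.ndarray
    pl_values: np.ndarray
    converged: np.ndarray
    classification: str  # "identifiable" | "flat"
    tol_flat: float

    def to_report(self) -> dict:
        return {
            "param_index": self.param_index,
            "grid": self.grid,
            "pl_values": self.pl_values,
            "converged": self.converged,
            "classification": self.classification,
            "tol_flat": self.tol_flat,
        }


@dataclass
class LinearizedProblem:
    """Local linear least-squares surrogate min ‖Sθ − b‖² around θ*."""

    S: np.ndarray
    b: np.ndarray


def linearized_problem(
    model: ModelSpec,
    dataset: Dataset,
    theta_star: Sequence[float],
    S: SensitivityMatrix | None = None,
) -> LinearizedProblem:
    """Form (S, b) with b = ĥ − h(φ(t, θ*)) + Sθ* in block order."""
    theta_star = model.check_theta(theta_star)
    dataset.check_model(model)
    if S is None:
        S = sensitivity_matrix(model, theta_star, dataset.times)
    pred = eval_observable(model, theta_star, dataset.times)
    b = (dataset.observations - pred).reshape(-1) + S.values @ theta_star
    return LinearizedProblem(S=S.values, b=b)


def fim(S: SensitivityMatrix | np.ndarray) -> np.ndarray:
    """Fisher Information Matrix F = SᵀS, symmetrized against round-off."""
    values = S.values if isinstance(S, SensitivityMatrix) else np.asarray(S, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite sensitivity input")
    F = values.T @ values
    return (F + F.T) / 2.0


def eigendecompose_fim(
    F: np.ndarray,
    eps_eig: float,
    param_names: Sequence[str] = (),
) -> FIMAnalysis:
    """Full EVD with eigenvalues sorted non-increasing and clipped at 0.

    Eigenvector signs follow a deterministic convention: the
    largest-magnitude component of each column is made positive (ties
    broken by lowest index).  Near-degenerate eigenvalue pairs (relative
    gap < 1e-8) are flagged in ``near_degenerate``, since eigenvectors
    within such clusters are only defined up to rotation.
    """
    F = np.asarray(F, dtype=float)
    if eps_eig < 0:
        raise ValueError("eps_eig must be non-negative")
    scale = 1.0 + np.abs(F).max() if F.size else 1.0
    if np.abs(F - F.T).max() > 1e-8 * scale:
        raise ValueError("FIM is not symmetric within tolerance")
    Fs = (F + F.T) / 2.0
    w, U = np.linalg.eigh(Fs)
    order = np.argsort(w, kind="stable")[::-1]
    w, U = w[order], U[:, order]
    w = np.clip(w, 0.0, None)
    for j in range(U.shape[1]):
        col = U[:, j]
        pivot = int(np.argmax(np.abs(col)))  # argmax takes the lowest index on ties
        if col[pivot] < 0:
            U[:, j] = -col
    near = []
    wmax = w[0] if w.size else 0.0
    for j in range(len(w) - 1):
        if w[j] - w[j + 1] < 1e-8 * max(wmax, 1e-300):
            near.append([j, j + 1])
    return FIMAnalysis(
        F=Fs,
        eigenvalues=w,
        eigenvectors=U,
        eps_eig=float(eps_eig),
        param_names=tuple(param_names),
        near_degenerate=near,
    )


def coordinate_metric(
    S: SensitivityMatrix | np.ndarray,
    tol_rank: float = DEFAULT_TOL_RANK,
    tol_coord: float | None = None,
    param_names: Sequence[str] | None = None,
) -> CoordinateReport:
    """Residual ∞-norm of each sensitivity column against the others.

    For each parameter i, A is S with column i deleted (range-equivalent
    to permuting the column to the end); the minimum-norm least-squares
    solution x̂ = A†sᵢ is computed by SVD with relative rank cutoff
    ``tol_rank``, and metric[i] = ‖sᵢ − Ax̂‖∞.  A zero metric means sᵢ
    lies in the span of the other columns, i.e. coordinate i is
    non-identifiable.

    ``tol_coord`` defaults to 1e-8 times the largest absolute entry of S.
    """
    if isinstance(S, SensitivityMatrix):
        values = S.values
        names = S.param_names
        scaled = S.scaled
    else:
        values = np.asarray(S, dtype=float)
        names = tuple(param_names) if param_names else tuple(
            f"theta{i + 1}" for i in range(values.shape[1])
        )
        scaled = False
    k = values.shape[1]
    if k < 2:
        raise ValueError("coordinate metric requires at least 2 parameters")
    if tol_coord is None:
        tol_coord = 1e-8 * (np.abs(values).max() if values.size else 0.0)
    metric = np.empty(k)
    for i in range(k):
        si = values[:, i]
        A = np.delete(values, i, axis=1)
        xhat, *_ = np.linalg.lstsq(A, si, rcond=tol_rank)
        metric[i] = np.abs(si - A @ xhat).max()
    flags = metric > tol_coord
    return CoordinateReport(
        metric=metric,
        flags=flags,
        param_names=names,
        tol_coord=float(tol_coord),
        scaled=scaled,
    )


def _loss_residuals(
    model: ModelSpec, dataset: Dataset, theta: np.ndarray
) -> np.ndarray:
    pred = eval_observable(model, theta, dataset.times)
    return (pred - dataset.observations).reshape(-1)


def profile_likelihood(
    model: ModelSpec,
    dataset: Dataset,
    theta_star: Sequence[float],
    i: int,
    half_width_fraction: float = 0.5,
    n_points: int = 21,
    tol_flat: float = DEFAULT_TOL_FLAT,
    bounds: tuple | None = None,
    u_null: np.ndarray | None = None,
    lam: float = 0.0,
) -> ProfileCurve:
    """Profile the loss along parameter i, minimizing over the others.

    The grid spans θᵢ*·(1 ± half_width_fraction) (an absolute window of
    ±half_width_fraction when θᵢ* = 0).  Grid points are visited outward
    from the one nearest θᵢ*, warm-starting each inner solve from its
    inner neighbour's optimum.  Classification is "flat" when
    max(PL) − min(PL) ≤ tol_flat·(1 + min(PL)).

    With ``u_null`` and ``lam`` set, the profiled objective is the
    regularized one, loss(θ) + λ‖u_nullᵀ(θ − θ*)‖², so the effect of the
    null-space penalty on coordinate identifiability can be inspected
    directly.
    """
    theta_star = model.check_theta(theta_star)
    dataset.check_model(model)
    k = model.k
    if not 0 <= i < k:
        raise ValueError(f"parameter index {i} out of range for k={k}")
    center = theta_star[i]
    half = abs(center) * half_width_fraction if center != 0 else half_width_fraction
    grid = np.linspace(center - half, center + half, n_points)
    rest_idx = [j for j in range(k) if j != i]

    if bounds is None:
        lo = np.full(k - 1, -np.inf)
        hi = np.full(k - 1, np.inf)
    else:
        lo = np.asarray(bounds[0], float)[rest_idx]
        hi = np.asarray(bounds[1], float)[rest_idx]

    if u_null is not None and lam > 0 and u_null.size:
        sq = np.sqrt(lam)
        pen_anchor = sq * (np.asarray(u_null, float).T @ theta_star)
        pen_mat = sq * np.asarray(u_null, float).T
    else:
        pen_anchor = pen_mat = None

    def solve_at(gval: float, start: np.ndarray) -> tuple[float, np.ndarray, bool]:
        def residuals(rest: np.ndarray) -> np.ndarray:
            full = np.empty(k)
            full[i] = gval
            full[rest_idx] = rest
            res = _loss_residuals(model, dataset, full)
            if pen_mat is not None:
                res = np.concatenate([res, pen_mat @ full - pen_anchor])
            return res

        def jac(rest: np.ndarray) -> np.ndarray:
            full = np.empty(k)
            full[i] = gval
            full[rest_idx] = rest
            Sm = sensitivity_matrix(model, full, dataset.times)
            J = Sm.values[:, rest_idx]
            if pen_mat is not None:
                J = np.vstack([J, pen_mat[:, rest_idx]])
            return J

        try:
            sol = least_squares(
                residuals,
                np.clip(start, lo, hi),
                jac=jac,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            return 2.0 * sol.cost, sol.x, bool(sol.success)
        except Exception:
            return np.nan, start, False

    pl = np.full(n_points, np.nan)
    conv = np.zeros(n_points, dtype=bool)
    center_idx = int(np.argmin(np.abs(grid - center)))
    start0 = theta_star[rest_idx]
    # outward sweep: center -> right, then center -> left
    for sweep in (range(center_idx, n_points), range(center_idx - 1, -1, -1)):
        warm = start0.copy()
        for j in sweep:
            val, warm_new, ok = solve_at(grid[j], warm)
            pl[j], conv[j] = val, ok
            if ok:
                warm = warm_new
    n_fail = int(np.sum(~conv))
    if n_fail > n_points // 2:
        raise RuntimeError(
            f"profile likelihood: {n_fail}/{n_points} inner solves failed"
        )
    finite = pl[np.isfinite(pl)]
    span = finite.max() - finite.min()
    flat = span <= tol_flat * (1.0 + finite.min())
    return ProfileCurve(
        param_index=i,
        grid=grid,
        pl_values=pl,
        converged=conv,
        classification="flat" if flat else "identifiable",
        tol_flat=float(tol_flat),
    )


def contribution_index(F: np.ndarray) -> float:
    """ξ = σmin/σmax of the FIM eigenvalues (clipped at zero), in [0, 1]."""
    F = np.asarray(F, dtype=float)
    w = np.clip(np.linalg.eigvalsh((F + F.T) / 2.0), 0.0, None)
    smax, smin = w.max(), w.min()
    if smax <= 0.0 or smin < 1e-300:
        return 0.0
    return float(smin / smax)


def structural_rank_test(
    model: ModelSpec,
    theta: Sequence[float],
    n_grid: int = 50,
) -> dict:
    """Numerical column rank of S on a dense uniform time grid.

    Full column rank on a rich grid is the practical test for structural
    identifiability; a rank defect that persists as the grid densifies
    indicates structurally indistinguishable parameter combinations.
    """
    theta = model.check_theta(theta)
    if n_grid * model.n_observables < model.k:
        raise ValueError(
            f"need n_grid·L ≥ k ({n_grid}·{model.n_observables} < {model.k})"
        )
    grid = np.linspace(*model.t_domain, n_grid)
    S = sensitivity_matrix(model, theta, grid)
    sv = np.linalg.svd(S.values, compute_uv=False)
    rank = int(np.sum(sv > 1e-10 * (sv[0] if sv.size else 0.0)))
    return {"rank": rank, "full_rank": rank == model.k, "singular_values": sv}
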