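"""Greedy optimal measurement-time selection.

Starting from an initial time set T, the algorithm repeatedly scores
every candidate time t by how much information its sensitivity block
S̃(t) injects into the current non-identifiable directions,
d(t) = diag(U_nullᵀ·S̃ᵀS̃·U_null), and appends the candidate that
activates the most null directions.  The FIM is updated by
F ← F + S̃ᵀS̃ and re-decomposed; iteration stops once all k eigenvalues
exceed the threshold (full numerical rank, success) or the iteration cap
is hit.

Candidate selection is lexicographic: (1) the count of entries of d(t)
above ``tol_design`` — the number of null directions the point activates;
(2) the total Σd(t); (3) the smallest t.  Since each added block S̃ᵀS̃ is
positive semidefinite, no eigenvalue ever decreases across iterations.
Candidates already in T are excluded, so T never contains duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .identifiability import eigendecompose_fim
from .models import ModelSpec
from .sensitivity import sensitivity_matrix

__all__ = ["DesignResult", "candidate_score", "optimal_design"]

DEFAULT_M_MAX = 50
DEFAULT_GRID_POINTS = 201


@dataclass
class DesignResult:
    times: np.ndarray  # final ordered time set T
    added_times: np.ndarray
    iterations: list = field(default_factory=list)
    success: bool = False
    eps_eig: float = 0.0
    m: int = 0
    m_max: int = 0
    q: int = 0
    message: str = ""

    def to_report(self) -> dict:
        return {
            "times": self.times,
            "added_times": self.added_times,
            "iterations": self.iterations,
            "success": self.success,
            "eps_eig": self.eps_eig,
            "m": self.m,
            "m_max": self.m_max,
            "q": self.q,
            "message": self.message,
        }


def candidate_score(
    model: ModelSpec,
    theta: Sequence[float],
    t: float,
    u_null: np.ndarray,
) -> np.ndarray:
    """d(t) = diag(U_nullᵀ·S̃(t)ᵀ·S̃(t)·U_null), one entry per null direction.

    Entry j is ‖S̃(t)·u_j‖² — the squared information the candidate time
    contributes along null direction u_j; all entries are ≥ 0.
    """
    u_null = np.asarray(u_null, dtype=float)
    if u_null.ndim != 2 or u_null.shape[1] < 1:
        raise ValueError("candidate_score requires at least one null direction")
    block = sensitivity_matrix(model, theta, [t]).values  # (L, k)
    proj = block @ u_null
    return np.sum(proj**2, axis=0)


def optimal_design(
    model: ModelSpec,
    theta: Sequence[float],
    initial_times: Sequence[float] | None,
    candidate_grid: Sequence[float] | None = None,
    eps_eig: float = 1e-6,
    m_max: int = DEFAULT_M_MAX,
    seed: int = 0,
    tol_design: float | None = None,
) -> DesignResult:
    """Greedily extend the measurement schedule to full FIM rank.

    Parameters
    ----------
    initial_times : starting schedule (q ≥ 1); if empty or None, one
        point is drawn from the candidate grid with the given seed.
    candidate_grid : candidate pool; defaults to 201 uniform points over
        the model's time domain.
    eps_eig : eigenvalue threshold defining "identifiable".
    tol_design : threshold for a "nonzero" score entry; defaults to
        1e-10·(1 + largest current eigenvalue), recomputed per iteration.
    """
    theta = model.check_theta(theta)
    if candidate_grid is None:
        candidate_grid = np.linspace(*model.t_domain, DEFAULT_GRID_POINTS)
    candidate_grid = model.check_times(candidate_grid)
    candidate_grid = np.unique(candidate_grid)

    initial_times = (
        np.asarray([], dtype=float)
        if initial_times is None
        else np.atleast_1d(np.asarray(initial_times, dtype=float))
    )
    if initial_times.size == 0:
        rng = np.random.default_rng(seed)
        initial_times = np.array([rng.choice(candidate_grid)])
    initial_times = model.check_times(initial_times)
    q = initial_times.size

    # One sensitivity solve covers every candidate block (θ is fixed).
    blocks = {
        float(t): sensitivity_matrix(model, theta, [t]).values
        for t in candidate_grid
    }
    k, l = model.k, model.n_observables

    S0 = sensitivity_matrix(model, theta, initial_times).values
    F = S0.T @ S0
    T = sorted(float(t) for t in initial_times)
    in_T = set(T)
    added: list[float] = []
    iterations: list[dict] = []

    ana = eigendecompose_fim(F, eps_eig, model.param_names)
    prev_eigs = ana.eigenvalues
    success = ana.full_rank
    message = "initial schedule already yields full rank" if success else ""
    m = q
    while not success and m < m_max:
        tol = (
            tol_design
            if tol_design is not None
            else 1e-10 * (1.0 + float(prev_eigs[0]))
        )
        u_null = ana.u_null
        best = None  # (count, total, -t, t, d)
        for t, block in blocks.items():
            if t in in_T:
                continue
            proj = block @ u_null
            d = np.sum(proj**2, axis=0)
            key = (int(np.sum(d > tol)), float(d.sum()), -t)
            if best is None or key > best[0]:
                best = (key, t, d)
        if best is None or best[0][0] == 0:
            message = (
                "no candidate contributes to any non-identifiable direction; "
                "the model may be structurally non-identifiable on this grid"
            )
            break
        _, t_new, d = best
        block = blocks[t_new]
        F = F + block.T @ block
        T.append(t_new)
        T.sort()
        in_T.add(t_new)
        added.append(t_new)
        m += 1
        rank_before = ana.r
        ana = eigendecompose_fim(F, eps_eig, model.param_names)
        if np.any(ana.eigenvalues < prev_eigs - 1e-8 * (1.0 + prev_eigs[0])):
            raise AssertionError("eigenvalue decreased after adding a PSD block")
        prev_eigs = ana.eigenvalues
        iterations.append(
            {
                "chosen": t_new,
                "score": d,
                "rank_before": rank_before,
                "rank_after": ana.r,
                "eigenvalues": ana.eigenvalues.copy(),
            }
        )
        success = ana.full_rank
    if not success and not message:
        message = f"iteration cap m_max={m_max} reached with rank {ana.r} < {k}"
    return DesignResult(
        times=np.asarray(T),
        added_times=np.asarray(added),
        iterations=iterations,
        success=bool(success),
        eps_eig=float(eps_eig),
        m=m,
        m_max=m_max,
        q=q,
        message=message,
    )
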