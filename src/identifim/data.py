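"""Datasets, synthetic-data generation, and report I/O.

Observations follow the additive Gaussian noise model: the observable
trajectory of a model evaluated at a reference parameter vector, plus
i.i.d. zero-mean Gaussian noise per entry.  Noise is homoscedastic per
observable; a per-observable sigma vector is accepted because observable
scales can differ widely (e.g. prey vs predator counts).

Datasets are stored as delimited text tables: one time column followed by
L observable columns, header row required.  Comma or tab delimiters are
autodetected on read; the decimal separator is always a point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ModelSpec, eval_observable

__all__ = [
    "Dataset",
    "generate_synthetic",
    "default_sigma",
    "read_dataset",
    "write_dataset",
    "write_report",
    "read_report",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class Dataset:
    """N time points with an N×L observation table."""

    times: np.ndarray
    observations: np.ndarray
    observable_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.observations = np.asarray(self.observations, dtype=float)
        if self.observations.ndim == 1:
            self.observations = self.observations[:, None]
        if self.times.size < 1:
            raise ValueError("dataset must contain at least one time point")
        if self.observations.shape != (self.times.size, len(self.observable_names)):
            raise ValueError(
                f"observations shape {self.observations.shape} does not match "
                f"N={self.times.size}, L={len(self.observable_names)}"
            )
        if not (
            np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.observations))
        ):
            raise ValueError("dataset contains non-finite entries")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("dataset times must be sorted non-decreasing")

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_observables(self) -> int:
        return len(self.observable_names)

    def check_model(self, model: ModelSpec) -> None:
        if self.n_observables != model.n_observables:
            raise ValueError(
                f"dataset has {self.n_observables} observables but model "
                f"{model.name!r} produces {model.n_observables}"
            )


def default_sigma(
    model: ModelSpec, theta: Sequence[float], times: Sequence[float], fraction: float = 0.05
) -> np.ndarray:
    """Per-observable noise scale: a fraction of each trajectory's range."""
    traj = eval_observable(model, theta, times)
    return fraction * (traj.max(axis=0) - traj.min(axis=0))


def generate_synthetic(
    model: ModelSpec,
    theta: Sequence[float],
    times: Sequence[float],
    sigma: float | Sequence[float],
    seed: int,
) -> Dataset:
    """Model output plus additive Gaussian noise from a seeded generator."""
    theta = model.check_theta(theta)
    times = model.check_times(times)
    clean = eval_observable(model, theta, times)
    sigma_vec = np.broadcast_to(
        np.asarray(sigma, dtype=float), (model.n_observables,)
    ).copy()
    if np.any(sigma_vec < 0):
        raise ValueError("noise sigma must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(clean.shape) * sigma_vec[None, :]
    return Dataset(
        times=times,
        observations=clean + noise,
        observable_names=model.observable_names,
        meta={
            "model": model.name,
            "theta": [float(v) for v in theta],
            "sigma": [float(v) for v in sigma_vec],
            "seed": int(seed),
            "synthetic": True,
        },
    )


def read_dataset(path: str | Path) -> Dataset:
    """Read a delimited table (time column + L observable columns)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty dataset file {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=0)
    except Exception as exc:  # pragma: no cover - pandas message pass-through
        raise ValueError(f"could not parse dataset file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(
            f"dataset file {path} must have a time column plus at least one "
            "observable column"
        )
    # A numeric-looking header row means the file had no header.
    try:
        float(str(df.columns[0]))
    except ValueError:
        pass
    else:
        raise ValueError(f"dataset file {path} is missing a header row")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"dataset file {path} contains non-numeric cells")
    times = values[:, 0].astype(float)
    obs = values[:, 1:].astype(float)
    if np.any(np.diff(times) < 0):
        warnings.warn(f"times in {path} were not sorted; reordering", stacklevel=2)
        order = np.argsort(times, kind="stable")
        times, obs = times[order], obs[order]
    return Dataset(
        times=times,
        observations=obs,
        observable_names=tuple(str(c) for c in df.columns[1:]),
        meta={"path": str(path)},
    )


def write_dataset(dataset: Dataset, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        np.column_stack([dataset.times, dataset.observations]),
        columns=["time", *dataset.observable_names],
    )
    df.to_csv(path, index=False, sep=sep, float_format="%.17g")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if hasattr(obj, "to_report"):
        return _jsonify(obj.to_report())
    return obj


def write_report(path: str | Path, **sections) -> dict:
    """Serialize analysis objects to a versioned JSON report.

    Any object exposing ``to_report()`` (FIMAnalysis, CoordinateReport,
    FitResult, DesignResult, ...) is converted; arrays become nested
    lists.  Returns the dict that was written.
    """
    report = {"schema_version": REPORT_SCHEMA_VERSION}
    report.update({k: _jsonify(v) for k, v in sections.items()})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
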