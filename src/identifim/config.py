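"""YAML run configurations and the packaged model-zoo protocols.

A config resolves to a model, a reference parameter vector, a measurement
schedule, and the analysis knobs (noise sigma, eigenvalue threshold,
regularization weight λ, perturbation scale τ, band level α, design
block).  Packaged configs under ``identifim/configs/`` fix the default
protocols for each zoo model; ``load_config`` accepts either a packaged
name (e.g. ``"hill"``) or a path to a user YAML file.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .data import Dataset, default_sigma, generate_synthetic, read_dataset
from .models import ModelSpec, make_model
from .uncertainty import default_tau

__all__ = [
    "load_config",
    "packaged_config_names",
    "build_model",
    "resolve_times",
    "resolve_sigma",
    "resolve_dataset",
    "resolve_theta",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def packaged_config_names() -> list[str]:
    root = resources.files("identifim") / "configs"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_config(name_or_path: str | Path) -> dict:
    """Load a packaged config by name or a YAML file by path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") or path.exists():
        text = path.read_text()
    else:
        ref = resources.files("identifim") / "configs" / f"{name_or_path}.yaml"
        if not ref.is_file():
            raise ConfigError(
                f"unknown config {name_or_path!r}; packaged: {packaged_config_names()}"
            )
        text = ref.read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    problems = validate(cfg)
    if problems:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(problems))
    return cfg


def validate(cfg: dict) -> list[str]:
    problems = []
    if "model" not in cfg:
        problems.append("missing required key 'model'")
    theta = cfg.get("theta")
    if theta is None:
        problems.append("missing required key 'theta' (list of values, or 'fit')")
    elif not (theta == "fit" or isinstance(theta, (list, tuple))):
        problems.append("'theta' must be a list of numbers or the string 'fit'")
    if theta == "fit" and "theta0" not in cfg:
        problems.append("theta='fit' requires a 'theta0' starting vector")
    for key in ("eps_eig", "lambda", "tau", "alpha"):
        val = cfg.get(key)
        if val is not None and not isinstance(val, (int, float)):
            problems.append(f"'{key}' must be a number")
    return problems


def build_model(cfg: dict) -> ModelSpec:
    opts = dict(cfg.get("model_options") or {})
    if "observables" in cfg and cfg["observables"] is not None:
        opts["observables"] = tuple(cfg["observables"])
    return make_model(cfg["model"], **opts)


def _grid(spec: Any) -> np.ndarray:
    if isinstance(spec, dict):
        return np.linspace(float(spec["start"]), float(spec["stop"]), int(spec["num"]))
    return np.asarray(spec, dtype=float)


def resolve_times(cfg: dict, model: ModelSpec) -> np.ndarray:
    spec = cfg.get("t_grid")
    if spec is None:
        raise ConfigError("config has no 't_grid' (list or {start, stop, num})")
    return model.check_times(_grid(spec))


def resolve_sigma(
    cfg: dict, model: ModelSpec, theta: Sequence[float], times: Sequence[float]
) -> np.ndarray:
    sigma = cfg.get("noise_sigma", "auto")
    if isinstance(sigma, str):
        if sigma != "auto":
            raise ConfigError(f"noise_sigma must be a number, list, or 'auto', got {sigma!r}")
        return default_sigma(model, theta, times)
    return np.broadcast_to(np.asarray(sigma, float), (model.n_observables,)).copy()


def resolve_dataset(
    cfg: dict,
    model: ModelSpec,
    theta_ref: Sequence[float],
    data_path: str | Path | None = None,
    seed: int | None = None,
) -> Dataset:
    """Load the dataset from a file, or synthesize it from the config."""
    if data_path is not None:
        ds = read_dataset(data_path)
        ds.check_model(model)
        return ds
    times = resolve_times(cfg, model)
    sigma = resolve_sigma(cfg, model, theta_ref, times)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    return generate_synthetic(model, theta_ref, times, sigma, seed)


def resolve_theta(cfg: dict, model: ModelSpec) -> np.ndarray | None:
    """Explicit theta from the config, or None when theta='fit'."""
    theta = cfg["theta"]
    if theta == "fit":
        return None
    return model.check_theta(np.asarray(theta, dtype=float))


def resolve_tau(cfg: dict, theta: Sequence[float]) -> float:
    tau = cfg.get("tau")
    return default_tau(theta) if tau is None else float(tau)
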