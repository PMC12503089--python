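"""Study configuration: one human-editable YAML/JSON file per planned study.

Minimal example::

    schema: immunodesign/1
    initial_information:
      A0: 0
      tmax: 30
      Amax: 10
      tplat: 365
      Aplat: 1

Optional blocks override the measurement-error defaults (sigma 0.25,
rho 0.73), add per-time sampling windows, and tune solver/optimizer
settings.  Loading fills all defaults, so the resolved configuration echoed
next to the results is self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import SolverOptions
from .types import ErrorModel, InitialInformation, OptimizerSettings

__all__ = ["StudyConfig", "ConfigError", "load_config"]

SCHEMA_TAG = "immunodesign/1"

_INFO_FIELDS = ("A0", "tmax", "Amax", "tplat", "Aplat")


class ConfigError(ValueError):
    """Malformed study configuration, with the offending field named."""


@dataclass(frozen=True)
class StudyConfig:
    info: InitialInformation
    error: ErrorModel = ErrorModel()
    windows: tuple | None = None
    optimizer: OptimizerSettings = OptimizerSettings()
    solver: SolverOptions = SolverOptions()

    def resolved(self) -> dict:
        """Fully-resolved plain-dict form (defaults filled), for echoing."""
        out = {
            "schema": SCHEMA_TAG,
            "initial_information": self.info.as_dict(),
            "error_model": {"sigma": self.error.sigma, "rho": self.error.rho},
            "solver": {
                "tol": self.solver.tol,
                "max_iterations": self.solver.max_iterations,
            },
            "optimizer": {
                "max_evals": self.optimizer.max_evals,
                "initial_step": (
                    list(self.optimizer.initial_step)
                    if self.optimizer.initial_step is not None
                    else None
                ),
                "step_expansion": self.optimizer.step_expansion,
                "shrink_factor": self.optimizer.shrink_factor,
                "tol_step": self.optimizer.tol_step,
            },
        }
        if self.windows is not None:
            out["windows"] = [list(w) for w in self.windows]
        return out


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing field {key!r} in {context}")
    return mapping[key]


def parse_config(raw: dict) -> StudyConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    schema = raw.get("schema", SCHEMA_TAG)
    if schema != SCHEMA_TAG:
        raise ConfigError(f"unsupported schema {schema!r}; expected {SCHEMA_TAG!r}")
    info_raw = _require(raw, "initial_information", "configuration root")
    if not isinstance(info_raw, dict):
        raise ConfigError("'initial_information' must be a mapping")
    for f in _INFO_FIELDS:
        _require(info_raw, f, "'initial_information'")
    unknown = set(info_raw) - set(_INFO_FIELDS)
    if unknown:
        raise ConfigError(f"unknown initial_information field(s): {sorted(unknown)}")
    try:
        info = InitialInformation(**{f: float(info_raw[f]) for f in _INFO_FIELDS})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid initial_information: {exc}") from exc

    err_raw = raw.get("error_model", {})
    try:
        error = ErrorModel(
            sigma=float(err_raw.get("sigma", 0.25)),
            rho=float(err_raw.get("rho", 0.73)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid error_model: {exc}") from exc

    windows = raw.get("windows")
    if windows is not None:
        try:
            windows = tuple((float(lo), float(hi)) for lo, hi in windows)
        except (TypeError, ValueError) as exc:
            raise ConfigError(
                "'windows' must be a list of [lower, upper] pairs"
            ) from exc
        for lo, hi in windows:
            if lo > hi:
                raise ConfigError(f"window [{lo}, {hi}] has lower > upper")

    solver_raw = raw.get("solver", {})
    try:
        solver = SolverOptions(
            tol=float(solver_raw.get("tol", 1e-8)),
            max_iterations=int(solver_raw.get("max_iterations", 1000)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid solver settings: {exc}") from exc

    opt_raw = raw.get("optimizer", {})
    try:
        optimizer = OptimizerSettings(
            max_evals=int(opt_raw.get("max_evals", 100_000)),
            initial_step=opt_raw.get("initial_step"),
            step_expansion=float(opt_raw.get("step_expansion", 1.5)),
            shrink_factor=float(opt_raw.get("shrink_factor", 0.5)),
            tol_step=float(opt_raw.get("tol_step", 1e-4)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid optimizer settings: {exc}") from exc

    return StudyConfig(
        info=info, error=error, windows=windows,
        optimizer=optimizer, solver=solver,
    )


def load_config(path) -> StudyConfig:
    """Read a YAML or JSON study configuration from ``path``."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return parse_config(raw)
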