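"""Core value types shared across the package.

All times are real-valued days, counted from the immunization event;
antibody concentrations are in arbitrary (but consistent) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InitialInformation",
    "CurveParameters",
    "ErrorModel",
    "Design",
    "OptimizerSettings",
]


@dataclass(frozen=True)
class InitialInformation:
    """The five clinician-provided quantities that pin down a kinetics curve.

    Attributes
    ----------
    A0 : float
        Expected antibody concentration at the immunization event (t = 0).
        ``A0 = 0`` means the population starts without detectable antibodies.
    tmax : float
        Time of the expected maximum concentration, in days.
    Amax : float
        Expected maximum antibody concentration.
    tplat : float
        Time at which the concentration settles onto its plateau, in days.
    Aplat : float
        Expected plateau concentration.
    """

    A0: float
    tmax: float
    Amax: float
    tplat: float
    Aplat: float

    def __post_init__(self) -> None:
        if self.A0 < 0:
            raise ValueError(f"A0 must be >= 0, got {self.A0}")
        if self.Aplat < 0:
            raise ValueError(f"Aplat must be >= 0, got {self.Aplat}")
        if not 0 < self.tmax < self.tplat:
            raise ValueError(
                f"need 0 < tmax < tplat, got tmax={self.tmax}, tplat={self.tplat}"
            )
        if not (self.Amax > self.A0 and self.Amax > self.Aplat):
            raise ValueError(
                "Amax must exceed both A0 and Aplat (initial rise, later decline); "
                f"got A0={self.A0}, Amax={self.Amax}, Aplat={self.Aplat}"
            )

    def replace(self, **changes: float) -> "InitialInformation":
        """Return a copy with the given fields overridden."""
        vals = dict(
            A0=self.A0, tmax=self.tmax, Amax=self.Amax,
            tplat=self.tplat, Aplat=self.Aplat,
        )
        vals.update(changes)
        return InitialInformation(**vals)

    def as_dict(self) -> dict:
        return dict(
            A0=self.A0, tmax=self.tmax, Amax=self.Amax,
            tplat=self.tplat, Aplat=self.Aplat,
        )


@dataclass(frozen=True)
class CurveParameters:
    """Calibrated parameters of the scaled, shifted beta-density mean curve.

    The mean curve before the plateau is the beta density evaluated at the
    scaled time ``x = (t + c) / t_scale``.  Both shape parameters must exceed
    one so that the curve rises from (near) zero, peaks, and declines.

    Attributes
    ----------
    alpha, beta : float
        Beta-density shape parameters, both > 1.
    t_scale : float
        Scale (days) mapping study time onto the unit interval.
    c : float
        Time shift (days) letting the curve start above zero at t = 0.
        Zero exactly when the generating ``A0`` is zero.
    """

    alpha: float
    beta: float
    t_scale: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > 1 and self.beta > 1):
            raise ValueError(
                f"shape parameters must both exceed 1, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.t_scale <= 0:
            raise ValueError(f"t_scale must be > 0, got {self.t_scale}")
        if self.c < 0:
            raise ValueError(f"shift c must be >= 0, got {self.c}")

    @property
    def n_parameters(self) -> int:
        """Dimension of the identifiable parameter vector: 3 if c = 0 else 4."""
        return 3 if self.c == 0 else 4

    def as_array(self) -> np.ndarray:
        """Parameter vector (alpha, beta, t_scale[, c]); c only when nonzero."""
        if self.c == 0:
            return np.array([self.alpha, self.beta, self.t_scale])
        return np.array([self.alpha, self.beta, self.t_scale, self.c])

    def as_dict(self) -> dict:
        return dict(alpha=self.alpha, beta=self.beta, t_scale=self.t_scale, c=self.c)


@dataclass(frozen=True)
class ErrorModel:
    """Measurement-error model: common known variance with AR(1) correlation.

    ``sigma`` is the measurement standard deviation (concentration units);
    ``rho`` the lag-one correlation between successive measurements of the
    same subject, by measurement order.
    """

    sigma: float = 0.25
    rho: float = 0.73

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not -1 < self.rho < 1:
            raise ValueError(f"rho must lie strictly in (-1, 1), got {self.rho}")


@dataclass(frozen=True)
class Design:
    """An ordered blood-sampling schedule with optional per-time windows."""

    times: tuple
    lower_bounds: tuple = None
    upper_bounds: tuple = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", tuple(t))
        if np.any(np.diff(t) < 0):
            raise ValueError(f"times must be nondecreasing, got {self.times}")
        lb = self.lower_bounds
        ub = self.upper_bounds
        if lb is not None:
            lb = tuple(float(v) for v in lb)
            object.__setattr__(self, "lower_bounds", lb)
            if len(lb) != len(t):
                raise ValueError("lower_bounds length must match times")
            if np.any(np.asarray(lb) > t):
                raise ValueError("lower_bounds must be <= times elementwise")
            if np.any(np.asarray(lb) < 0):
                raise ValueError("all sampling times (and bounds) must be >= 0")
        if ub is not None:
            ub = tuple(float(v) for v in ub)
            object.__setattr__(self, "upper_bounds", ub)
            if len(ub) != len(t):
                raise ValueError("upper_bounds length must match times")
            if np.any(np.asarray(ub) < t):
                raise ValueError("upper_bounds must be >= times elementwise")
        if np.any(t < 0):
            raise ValueError("all sampling times must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


@dataclass(frozen=True)
class OptimizerSettings:
    """Controls for the bound-constrained Hooke-Jeeves pattern search.

    ``initial_step`` may be None, in which case the search uses one tenth of
    each coordinate's box width; the chosen step is then multiplied by
    ``step_expansion`` before the search starts.
    """

    max_evals: int = 100_000
    initial_step: Sequence[float] | None = None
    step_expansion: float = 1.5
    shrink_factor: float = 0.5
    tol_step: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_evals < 1:
            raise ValueError("max_evals must be >= 1")
        if self.initial_step is not None:
            step = tuple(float(s) for s in self.initial_step)
            if any(s <= 0 for s in step):
                raise ValueError("initial_step entries must be > 0")
            object.__setattr__(self, "initial_step", step)
        if self.step_expansion < 1:
            raise ValueError("step_expansion must be >= 1")
        if not 0 < self.shrink_factor < 1:
            raise ValueError("shrink_factor must lie in (0, 1)")
        if self.tol_step <= 0:
            raise ValueError("tol_step must be > 0")
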