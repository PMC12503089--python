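"""Calibration of the beta-curve parameters from the initial information.

The five clinical inputs (A0, tmax, Amax, tplat, Aplat) determine the curve
parameters (alpha, beta, t_scale[, c]) through a nonlinear system: the mode
of the beta density must sit at the scaled peak time, and the curve must
pass through the peak and plateau heights (plus the starting height A0 when
it is positive).  With A0 = 0 the shift c is identically zero and the system
has three unknowns; with A0 > 0 it has four.

The system is solved by a multi-start root search.  To keep every iterate
inside the feasible open region (shapes above one, scaled times inside the
unit interval, nonnegative shift) the solver works in the transformed
coordinates

    (log(alpha - 1), log(beta - 1), log(t_scale - tplat - c)[, log c])

and reports back-transformed parameters.  Each start is attempted with a
full-Newton hybrid method and a quasi-Newton (Broyden-type) method; the
first converged, feasible root wins.  Starting values place the beta-density
mode exactly at the scaled peak time so the mode equation holds at the start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import betaln

from .kinetics import beta_density, mode_location
from .types import CurveParameters, InitialInformation

__all__ = ["CalibrationResult", "SolverOptions", "system_residual", "calibrate"]

#: min separation of shapes from 1 for a root to count as feasible
_SHAPE_MARGIN = 1e-9
#: shifts below this are treated as numerically degenerate for A0 > 0
_MIN_SHIFT = 1e-8


@dataclass(frozen=True)
class SolverOptions:
    """Settings of the multi-start root search."""

    tol: float = 1e-8
    max_iterations: int = 1000
    t_scale_factors: tuple = (1.05, 1.5, 2.0, 3.0, 5.0, 10.0)
    alpha_starts: tuple = (1.1, 1.5, 2.0, 3.0)
    methods: tuple = ("hybr", "broyden1")


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one calibration attempt.

    ``params`` is present only when ``converged`` is true, in which case the
    residual infinity-norm is below tolerance and all parameter constraints
    hold.
    """

    converged: bool
    params: CurveParameters | None = None
    residual_norm: float = float("inf")
    method_used: str = ""
    n_iterations: int = 0


def system_residual(params: CurveParameters, info: InitialInformation) -> np.ndarray:
    """Residual vector of the calibration system at ``params``.

    Ordering: mode equation, (starting-height equation when A0 > 0),
    peak-height equation, plateau-height equation.  A root of the system
    gives the exact zero vector.
    """
    a, b, ts, c = params.alpha, params.beta, params.t_scale, params.c
    x_max = (info.tmax + c) / ts
    x_plat = (info.tplat + c) / ts
    for x in (x_max, x_plat):
        if not 0 <= x <= 1:
            raise ValueError(f"scaled time {x} outside [0, 1]")
    r_mode = mode_location(a, b) - x_max
    r_max = beta_density(x_max, a, b) - info.Amax
    r_plat = beta_density(x_plat, a, b) - info.Aplat
    if info.A0 == 0:
        return np.array([r_mode, r_max, r_plat])
    x_c = c / ts
    r_start = beta_density(x_c, a, b) - info.A0
    return np.array([r_mode, r_start, r_max, r_plat])


def _raw_residual(a, b, ts, c, info):
    """Residual on raw parameters without the domain checks of the public op."""
    with np.errstate(all="ignore"):
        lb = betaln(a, b)
        x_max = (info.tmax + c) / ts
        x_plat = (info.tplat + c) / ts

        def dens(x):
            return np.exp((a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - lb)

        r_mode = (a - 1) / (a + b - 2) - x_max
        r_max = dens(x_max) - info.Amax
        r_plat = dens(x_plat) - info.Aplat
        if info.A0 == 0:
            return np.array([r_mode, r_max, r_plat])
        r_start = dens(c / ts) - info.A0
        return np.array([r_mode, r_start, r_max, r_plat])


def calibrate(
    info: InitialInformation, options: SolverOptions | None = None
) -> CalibrationResult:
    """Solve the calibration system for ``info``.

    Automatically selects the three-unknown system (c forced to 0) when
    ``info.A0 == 0`` and the four-unknown shifted system otherwise.  Never
    raises on solver failure: a non-converged ``CalibrationResult`` is
    returned instead so misspecification sweeps can count failures.
    """
    opts = options or SolverOptions()
    shifted = info.A0 > 0
    tplat = info.tplat

    if info.Aplat == 0:
        # no root exists: the beta density is strictly positive on the open
        # interval, so an exact-zero plateau height can only be approached
        # in the limit.  Accepting a near-root at absolute tolerance would
        # be a solver artifact, not a calibration.
        return CalibrationResult(converged=False)

    def unpack(q):
        a = 1.0 + np.exp(q[0])
        b = 1.0 + np.exp(q[1])
        if shifted:
            c = np.exp(q[3])
            ts = tplat + c + np.exp(q[2])
        else:
            c = 0.0
            ts = tplat + np.exp(q[2])
        return a, b, ts, c

    def residual(q):
        a, b, ts, c = unpack(q)
        return _raw_residual(a, b, ts, c, info)

    n_attempts = 0
    # full-Newton hybrid first across all starts: the quasi-Newton fallback
    # only runs when every hybrid attempt has failed (it is far slower per
    # failed attempt but occasionally converges where the hybrid does not)
    for method in opts.methods:
        for ts_factor in opts.t_scale_factors:
            for a0 in opts.alpha_starts:
                ts0 = ts_factor * tplat
                c0 = 0.05 * info.tmax if shifted else 0.0
                x0 = (info.tmax + c0) / ts0
                # place the mode at the scaled peak time: solves the mode
                # equation exactly at the start
                b0 = (a0 - 1) / x0 - a0 + 2
                if b0 <= 1:
                    continue
                q0 = [np.log(a0 - 1), np.log(b0 - 1), np.log(ts0 - tplat - c0)]
                if shifted:
                    q0.append(np.log(c0))
                n_attempts += 1
                try:
                    with np.errstate(all="ignore"), warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        if method == "hybr":
                            sol = optimize.root(residual, q0, method="hybr")
                        else:
                            sol = optimize.root(
                                residual, q0, method=method,
                                options={"maxiter": opts.max_iterations},
                            )
                except Exception:
                    continue
                with np.errstate(all="ignore"):
                    res = residual(sol.x)
                if not np.all(np.isfinite(res)):
                    continue
                rnorm = float(np.max(np.abs(res)))
                if rnorm >= opts.tol:
                    continue
                a, b, ts, c = unpack(sol.x)
                if not (a > 1 + _SHAPE_MARGIN and b > 1 + _SHAPE_MARGIN):
                    continue
                if (tplat + c) / ts > 1:
                    continue
                if shifted and c < _MIN_SHIFT:
                    # degenerate shift: the shifted model collapses onto the
                    # three-parameter one and the root is numerically unstable
                    continue
                params = CurveParameters(alpha=a, beta=b, t_scale=ts, c=c)
                return CalibrationResult(
                    converged=True,
                    params=params,
                    residual_norm=rnorm,
                    method_used=f"{method}[ts0={ts_factor}*tplat,alpha0={a0}]",
                    n_iterations=n_attempts,
                )
    return CalibrationResult(converged=False, n_iterations=n_attempts)
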