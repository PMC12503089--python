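"""Structural antibody-kinetics model.

The expected antibody concentration is taken to follow the functional form
of a beta density on a scaled, optionally shifted time axis until it reaches
a plateau:

    E[A(t)] = f((t + c) / t_scale; alpha, beta)   for 0 <= t < tplat
    E[A(t)] = Aplat                               for t >= tplat

where f is the beta probability density with both shape parameters above 1,
so the curve rises from (near) zero to a single peak and then declines.  The
beta density is used purely as a curve shape: its value at the scaled peak
position equals the expected peak concentration Amax, so no normalizing
Jacobian factor is applied.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln

from .types import CurveParameters, InitialInformation

__all__ = ["beta_density", "mode_location", "mean_concentration", "curve_table"]


def beta_density(x, alpha: float, beta_: float):
    """Beta probability density x^(a-1) (1-x)^(b-1) / B(a, b) on [0, 1].

    Evaluated in the log domain (log-gamma for the beta function) so that
    large shape parameters do not overflow.  Endpoints map to exactly 0
    because both shapes exceed 1.

    Parameters
    ----------
    x : float or array-like
        Point(s) in [0, 1].
    alpha, beta_ : float
        Shape parameters, both strictly greater than 1.
    """
    if not (alpha > 1 and beta_ > 1):
        raise ValueError(f"shape parameters must exceed 1, got ({alpha}, {beta_})")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x must lie in [0, 1]")
    out = np.zeros_like(x)
    inside = (x > 0) & (x < 1)
    xi = x[inside]
    with np.errstate(divide="ignore"):
        log_kernel = (alpha - 1) * np.log(xi) + (beta_ - 1) * np.log1p(-xi)
    out[inside] = np.exp(log_kernel - betaln(alpha, beta_))
    return out if out.ndim else float(out)


def mode_location(alpha: float, beta_: float) -> float:
    """Mode of the beta density, (alpha - 1) / (alpha + beta - 2).

    Strictly inside (0, 1) for shapes above 1; this is the scaled time of
    the expected antibody peak.
    """
    if not (alpha > 1 and beta_ > 1):
        raise ValueError(f"shape parameters must exceed 1, got ({alpha}, {beta_})")
    return (alpha - 1) / (alpha + beta_ - 2)


def mean_concentration(t, params: CurveParameters, info: InitialInformation):
    """Model mean antibody concentration at time(s) ``t`` (days).

    Uses the beta-density branch on [0, tplat) and the constant plateau
    ``Aplat`` from ``tplat`` onwards.  At a converged calibration the two
    branches agree at ``tplat`` up to the solver residual.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    x = (t + params.c) / params.t_scale
    if np.any(x > 1):
        raise ValueError(
            "scaled time (t + c)/t_scale exceeds 1; parameters do not cover this time"
        )
    out = np.full_like(t, float(info.Aplat))
    pre = t < info.tplat
    out[pre] = beta_density(x[pre], params.alpha, params.beta)
    return out if out.ndim else float(out)


def curve_table(params: CurveParameters, info: InitialInformation, n: int = 501):
    """Dense (time, mean) table of the calibrated curve for export/plotting.

    Returns a two-column float array covering [0, tplat] inclusive.
    """
    t = np.linspace(0.0, info.tplat, n)
    return np.column_stack([t, mean_concentration(t, params, info)])
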