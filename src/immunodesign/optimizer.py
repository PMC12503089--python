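"""Bound-constrained Hooke-Jeeves pattern search and the schedule optimizer.

The D-objective is cheap but not smooth enough near degenerate schedules to
trust gradients, so the search is the classic derivative-free Hooke-Jeeves
procedure: greedy exploratory moves coordinate by coordinate, accelerated by
pattern (extrapolation) moves, with the step sizes halved whenever no move
improves, until they fall below a tolerance.  Box constraints are enforced
by clipping every trial point, which is the bounded variant the schedule
search needs (per-time sampling windows).

The search is fully deterministic: identical inputs give identical
schedules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fim import FastDObjective
from .types import CurveParameters, Design, ErrorModel, InitialInformation, OptimizerSettings

__all__ = ["HookeJeevesResult", "OptimalDesignResult", "hooke_jeeves", "optimal_design"]


@dataclass(frozen=True)
class HookeJeevesResult:
    x: np.ndarray
    fun: float
    n_evals: int
    converged: bool  # True when the step tolerance was reached within budget


@dataclass(frozen=True)
class OptimalDesignResult:
    """Optimized schedule with diagnostics."""

    design: Design
    objective: float
    det_fim: float
    n_evals: int
    converged: bool


def hooke_jeeves(
    objective,
    start,
    lower,
    upper,
    settings: OptimizerSettings | None = None,
) -> HookeJeevesResult:
    """Minimize ``objective`` over the box [lower, upper] from ``start``.

    Returns a point whose objective is never worse than the start's.
    Terminates when every step size has shrunk below ``settings.tol_step``
    or the evaluation budget is exhausted.
    """
    settings = settings or OptimizerSettings()
    x0 = np.asarray(start, dtype=float)
    lb = np.asarray(lower, dtype=float)
    ub = np.asarray(upper, dtype=float)
    if lb.shape != x0.shape or ub.shape != x0.shape:
        raise ValueError("start, lower and upper must have the same shape")
    if np.any(lb > ub):
        raise ValueError("invalid bounds: lower > upper")
    if np.any(x0 < lb) or np.any(x0 > ub):
        raise ValueError("start must lie inside the bounds")

    n = x0.size
    if settings.initial_step is not None:
        step = np.asarray(settings.initial_step, dtype=float).copy()
        if step.size != n:
            raise ValueError("initial_step length must match the dimension")
    else:
        step = 0.1 * (ub - lb)
        step[step == 0] = settings.tol_step  # degenerate (pinned) coordinates
    step = step * settings.step_expansion

    n_evals = 0
    budget = settings.max_evals

    def evaluate(x):
        nonlocal n_evals
        n_evals += 1
        return float(objective(x))

    def explore(x, fx):
        """One exploratory pass: greedy +/- step moves along each axis."""
        x = x.copy()
        for i in range(n):
            for delta in (step[i], -step[i]):
                if n_evals >= budget:
                    return x, fx
                xi = np.clip(x[i] + delta, lb[i], ub[i])
                if xi == x[i]:
                    continue
                trial = x.copy()
                trial[i] = xi
                ft = evaluate(trial)
                if ft < fx:
                    x, fx = trial, ft
                    break
        return x, fx

    base = x0.copy()
    f_base = evaluate(base)
    while n_evals < budget and np.max(step) > settings.tol_step:
        new, f_new = explore(base, f_base)
        if f_new < f_base:
            # pattern moves: extrapolate along the improving direction
            while n_evals < budget:
                pattern = np.clip(new + (new - base), lb, ub)
                base, f_base = new, f_new
                f_pat = evaluate(pattern)
                cand, f_cand = explore(pattern, f_pat)
                if f_cand < f_base:
                    new, f_new = cand, f_cand
                else:
                    break
            base, f_base = new, f_new
        else:
            step *= settings.shrink_factor
    return HookeJeevesResult(
        x=base,
        fun=f_base,
        n_evals=n_evals,
        converged=bool(np.max(step) <= settings.tol_step),
    )


def optimal_design(
    params: CurveParameters,
    info: InitialInformation,
    error: ErrorModel,
    windows: tuple | None = None,
    settings: OptimizerSettings | None = None,
    include_c: bool | None = None,
) -> OptimalDesignResult:
    """D-optimal sampling schedule for a calibrated curve.

    The number of sampling times equals the number of curve parameters
    (3 when the curve starts at zero, 4 otherwise); extra samples would only
    replicate existing ones under a locally optimal design.  Start values
    are Day 1, the peak time and the plateau time, plus the midpoint between
    peak and plateau for the four-parameter model.  Default bounds are
    [0, tplat] for every time; ``windows`` may narrow them per time as
    ``((lo1, hi1), ..., (lop, hip))``.

    The returned times are sorted.  The search itself does not constrain the
    ordering - the objective is permutation symmetric and schedules with
    collapsed times score 0, so they are never optimal.
    """
    if include_c is None:
        include_c = params.c > 0
    obj = FastDObjective(params, error, include_c)
    p = obj.p
    if p == 3:
        start = np.array([1.0, info.tmax, info.tplat])
    else:
        start = np.array(
            [1.0, info.tmax, info.tmax + (info.tplat - info.tmax) / 2.0, info.tplat]
        )
    lb = np.zeros(p)
    ub = np.full(p, float(info.tplat))
    if windows is not None:
        if len(windows) != p:
            raise ValueError(f"need {p} per-time windows, got {len(windows)}")
        lb = np.array([w[0] for w in windows], dtype=float)
        ub = np.array([w[1] for w in windows], dtype=float)
        if np.any(lb < 0) or np.any(ub > info.tplat):
            raise ValueError("windows must lie within [0, tplat]")
        start = np.clip(start, lb, ub)

    result = hooke_jeeves(obj, start, lb, ub, settings)
    order = np.argsort(result.x)
    times = result.x[order]
    design = Design(
        times=tuple(times),
        lower_bounds=tuple(lb[order]),
        upper_bounds=tuple(ub[order]),
    )
    det = obj.det_fim(result.x)
    return OptimalDesignResult(
        design=design,
        objective=result.fun,
        det_fim=det,
        n_evals=result.n_evals,
        converged=bool(result.converged and np.isfinite(result.fun)),
    )
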