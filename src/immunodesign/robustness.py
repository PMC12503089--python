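"""Misspecification robustness analysis of the design framework.

At the planning stage the five clinical inputs are guesses, so the schedule
actually used may come from a wrong curve.  The sweeps here quantify the
cost: for each grid value of a misspecified input, re-calibrate the curve,
re-optimize the schedule, then score that schedule under the *true* curve
parameters against the true optimal schedule (D-efficiency), and record how
far each sampling time moved.  Grid points where either the calibration or
the schedule search fails are counted as non-converged and never abort a
sweep.

Twelve preset scenarios span starting level (0 / low / high), speed of the
antibody rise (peak at day 30 / 70) and plateau height (1 / 2.5), with the
peak concentration fixed at 10 as the reference level and the plateau at
day 365.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .calibration import calibrate
from .fim import FastDObjective
from .optimizer import optimal_design
from .types import ErrorModel, InitialInformation, OptimizerSettings

__all__ = [
    "Scenario",
    "SCENARIOS",
    "RobustnessResult",
    "misspecification_range",
    "sweep_single",
    "sweep_double",
    "summarize_pooled",
]

#: symmetric half-widths of the misspecification ranges, per input
_HALF_WIDTH = {"A0": 2.0, "Amax": 2.0, "Aplat": 2.0, "tmax": 14.0, "tplat": 50.0}
#: inputs that cannot go below zero: the range is clipped there
_CLIPPED_AT_ZERO = {"A0", "Aplat"}

SWEEPABLE_PARAMETERS = tuple(_HALF_WIDTH)


@dataclass(frozen=True)
class Scenario:
    """One preset study setting of the robustness analysis."""

    id: int
    description: str
    info: InitialInformation


def _build_scenarios() -> dict:
    presets = {}
    start_label = {0: "start in zero", 1: "start at lower level", 5: "start at higher level"}
    # id -> (A0, tmax, Amax, tplat, Aplat)
    rows = {
        1: (0, 30, 10, 365, 1.0),
        2: (0, 70, 10, 365, 1.0),
        3: (0, 30, 10, 365, 2.5),
        4: (0, 70, 10, 365, 2.5),
        5: (1, 30, 10, 365, 1.0),
        6: (1, 70, 10, 365, 1.0),
        7: (1, 30, 10, 365, 2.5),
        8: (1, 70, 10, 365, 2.5),
        9: (5, 30, 10, 365, 1.0),
        10: (5, 70, 10, 365, 1.0),
        11: (5, 30, 10, 365, 2.5),
        12: (5, 70, 10, 365, 2.5),
    }
    for sid, (A0, tmax, Amax, tplat, Aplat) in rows.items():
        start = start_label[A0]
        pace = "faster increase" if tmax == 30 else "slower increase"
        plat = "lower plateau" if Aplat == 1.0 else "higher plateau"
        presets[sid] = Scenario(
            id=sid,
            description=f"{start}, {pace}, {plat}",
            info=InitialInformation(
                A0=float(A0), tmax=float(tmax), Amax=float(Amax),
                tplat=float(tplat), Aplat=float(Aplat),
            ),
        )
    return presets


SCENARIOS: dict = _build_scenarios()


@dataclass(frozen=True)
class RobustnessResult:
    """One misspecification sweep.

    ``efficiencies`` holds NaN at non-converged grid points; ``deviations``
    (grid x n_times) holds the sorted misspecified minus sorted true
    sampling times, NaN rows where non-converged.  ``summary`` is the
    five-number summary (min, Q1, median, Q3, max) over converged entries.
    """

    scenario_id: int
    varied: tuple
    grid: np.ndarray
    efficiencies: np.ndarray
    deviations: np.ndarray
    n_nonconverged: int
    summary: tuple
    failure_causes: dict = field(default_factory=dict)

    @property
    def converged_efficiencies(self) -> np.ndarray:
        return self.efficiencies[np.isfinite(self.efficiencies)]


def misspecification_range(scenario: Scenario, param: str) -> tuple:
    """Closed misspecification interval for one input of a scenario.

    Heights vary by +/-2 concentration units (clipped at zero where
    negative levels are meaningless), the peak time by +/-14 days and the
    plateau time by +/-50 days.  The starting level is never varied for the
    scenarios that start in zero - whether pre-existing antibodies exist is
    assumed known at the planning stage.
    """
    if param not in _HALF_WIDTH:
        raise ValueError(f"unknown parameter {param!r}; expected one of {SWEEPABLE_PARAMETERS}")
    if param == "A0" and scenario.info.A0 == 0:
        raise ValueError(
            f"A0 is not varied for scenario {scenario.id}: populations starting "
            "in zero are assumed known to do so"
        )
    true = scenario.info.as_dict()[param]
    half = _HALF_WIDTH[param]
    lo, hi = true - half, true + half
    if param in _CLIPPED_AT_ZERO:
        lo = max(0.0, lo)
    return (lo, hi)


def _five_number(values: np.ndarray) -> tuple:
    """Min, Q1, median, Q3, max with linear quartile interpolation."""
    q = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
    return tuple(float(v) for v in q)


class _TrueState:
    """True calibrated curve, optimal schedule and reference determinant."""

    def __init__(self, scenario, error, settings):
        cal = calibrate(scenario.info)
        if not cal.converged:
            raise RuntimeError(f"calibration failed for scenario {scenario.id}")
        self.params = cal.params
        self.include_c = scenario.info.A0 > 0
        self.p = 4 if self.include_c else 3
        opt = optimal_design(self.params, scenario.info, error, settings=settings)
        self.design = opt.design
        self.objective = FastDObjective(self.params, error, self.include_c)
        self.det_true = self.objective.det_fim(self.design.times_array)
        if self.det_true <= 0:
            raise RuntimeError(f"true design is degenerate for scenario {scenario.id}")


def _evaluate_point(
    values: dict, state: _TrueState, error: ErrorModel, settings
) -> tuple:
    """(efficiency, deviations, failure_cause) for one misspecified input set."""
    nan_dev = np.full(state.p, np.nan)
    if values["A0"] == 0 and state.include_c:
        # the misspecified curve drops to 3 parameters: its 3-point schedule
        # cannot identify the 4-parameter truth
        return np.nan, nan_dev, "model_collapse"
    try:
        mis_info = InitialInformation(**values)
    except ValueError:
        return np.nan, nan_dev, "invalid_information"
    cal = calibrate(mis_info)
    if not cal.converged:
        return np.nan, nan_dev, "calibration"
    opt = optimal_design(cal.params, mis_info, error, settings=settings)
    if not opt.converged or len(opt.design) != state.p:
        return np.nan, nan_dev, "optimization"
    times = opt.design.times_array
    det_c = state.objective.det_fim(times)
    eff = float(np.clip((det_c / state.det_true) ** (1.0 / state.p), 0.0, 1.0))
    dev = times - state.design.times_array
    return eff, dev, None


def _run_sweep(scenario, varied, grids, error, settings) -> RobustnessResult:
    state = _TrueState(scenario, error, settings)
    base = scenario.info.as_dict()
    grid_points = list(itertools.product(*grids)) if len(varied) > 1 else [
        (v,) for v in grids[0]
    ]
    effs = np.full(len(grid_points), np.nan)
    devs = np.full((len(grid_points), state.p), np.nan)
    causes: dict = {}
    for i, point in enumerate(grid_points):
        values = dict(base)
        for name, v in zip(varied, point):
            values[name] = float(v)
        eff, dev, cause = _evaluate_point(values, state, error, settings)
        effs[i] = eff
        devs[i] = dev
        if cause is not None:
            causes[cause] = causes.get(cause, 0) + 1
    converged = effs[np.isfinite(effs)]
    summary = _five_number(converged) if converged.size else (np.nan,) * 5
    grid = (
        np.asarray(grids[0])
        if len(varied) == 1
        else np.array(grid_points, dtype=float)
    )
    return RobustnessResult(
        scenario_id=scenario.id,
        varied=tuple(varied),
        grid=grid,
        efficiencies=effs,
        deviations=devs,
        n_nonconverged=int(np.sum(~np.isfinite(effs))),
        summary=summary,
        failure_causes=causes,
    )


def sweep_single(
    scenario: Scenario,
    param: str,
    n_grid: int = 1001,
    error: ErrorModel = ErrorModel(),
    settings: OptimizerSettings | None = None,
) -> RobustnessResult:
    """Vary one input over its misspecification range on an equidistant grid.

    All other inputs stay at their true value.  Every grid point is scored
    by the D-efficiency of its re-optimized schedule under the true curve;
    the range endpoints are always on the grid.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    lo, hi = misspecification_range(scenario, param)
    grid = np.linspace(lo, hi, n_grid)
    return _run_sweep(scenario, (param,), (grid,), error, settings)


def sweep_double(
    scenario: Scenario,
    n_grid_per_axis: int = 101,
    error: ErrorModel = ErrorModel(),
    settings: OptimizerSettings | None = None,
) -> RobustnessResult:
    """Joint misspecification of the peak time and the plateau height.

    Full Cartesian grid over the two ranges (endpoints included); the same
    bookkeeping as :func:`sweep_single` per grid point.
    """
    if n_grid_per_axis < 2:
        raise ValueError("n_grid_per_axis must be >= 2")
    g_tmax = np.linspace(*misspecification_range(scenario, "tmax"), n_grid_per_axis)
    g_aplat = np.linspace(*misspecification_range(scenario, "Aplat"), n_grid_per_axis)
    return _run_sweep(scenario, ("tmax", "Aplat"), (g_tmax, g_aplat), error, settings)


def summarize_pooled(results, by: str | tuple | None = None) -> dict:
    """Pool converged efficiencies of several sweeps of the same input(s).

    Returns the five-number summary plus non-convergence counts, relative
    to the number of attempted runs.
    """
    results = list(results)
    if not results:
        raise ValueError("no sweep results to pool")
    if by is not None:
        want = (by,) if isinstance(by, str) else tuple(by)
        results = [r for r in results if r.varied == want]
        if not results:
            raise ValueError(f"no sweep results vary {by!r}")
    varied = {r.varied for r in results}
    if len(varied) > 1:
        raise ValueError(f"cannot pool sweeps of different parameters: {sorted(varied)}")
    pooled = np.concatenate([r.converged_efficiencies for r in results])
    if pooled.size == 0:
        raise ValueError("no converged grid points to pool")
    n_total = int(sum(r.efficiencies.size for r in results))
    n_nc = int(sum(r.n_nonconverged for r in results))
    mn, q1, med, q3, mx = _five_number(pooled)
    return dict(
        min=mn, q1=q1, median=med, q3=q3, max=mx,
        n_runs=n_total, n_nonconverged=n_nc,
        fraction_nonconverged=n_nc / n_total,
    )
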