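"""Acceptance-threshold calibration against target correction workloads.

Candidate thresholds for one metric (DSC or NSD) are swept with the other
threshold fixed at zero, recording the fraction of instance slices flagged
for correction at each grid point.  Raw sweep curves can be non-monotone
because of sampling noise, so a non-decreasing isotonic (pool-adjacent-
violators) adjustment is applied before the curve is inverted by piecewise
linear interpolation at the scenario's target correction rate (0%, 20%,
40%, 60% for no/low/moderate/high interaction).  Thresholds are calibrated
for DSC and NSD separately but applied jointly during simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

from .annotation_sim import ScenarioSpec, simulate_dataset

log = logging.getLogger(__name__)

DEFAULT_TARGETS: dict[str, float] = {
    "no_edits": 0.0,
    "low": 0.20,
    "moderate": 0.40,
    "high": 0.60,
}

# grid ranges by task family; 20 evenly spaced points by default
GRID_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("bone", "dsc"): (0.90, 0.995),
    ("bone", "nsd"): (0.70, 0.99),
    ("tumor", "dsc"): (0.30, 0.95),
    ("tumor", "nsd"): (0.10, 0.90),
}


def default_grid(task: str, metric: str, n_points: int = 20) -> np.ndarray:
    lo, hi = GRID_RANGES[(task, metric)]
    return np.linspace(lo, hi, n_points)


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map from candidate threshold to observed correction proportion."""

    metric: str  # "dsc" | "nsd"
    grid: np.ndarray
    corrected_fraction: np.ndarray  # isotonic-adjusted, non-decreasing
    raw_fraction: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be a nonempty strictly ascending 1D sequence")
        frac = np.asarray(self.corrected_fraction, dtype=float)
        if frac.shape != grid.shape or np.any((frac < 0) | (frac > 1)):
            raise ValueError("corrected_fraction must match the grid and lie in [0, 1]")


def sweep_thresholds(
    dataset,
    make_segmenter,
    metric: str,
    grid: np.ndarray,
    seed: int = 0,
    tolerance_mm: float = 1.0,
) -> CalibrationCurve:
    """Run the simulation once per grid point and record correction fractions.

    The metric under study takes each grid value while the other threshold is
    fixed at zero.  The same RNG seed is reused at every grid point so the
    curve reflects threshold changes only, not resampled prompt jitter.
    """
    if metric not in ("dsc", "nsd"):
        raise ValueError("metric must be 'dsc' or 'nsd'")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid values must lie in [0, 1]")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending")
    raw = np.empty_like(grid)
    for i, tau in enumerate(grid):
        taus = {"tau_dsc": 0.0, "tau_nsd": 0.0, f"tau_{metric}": float(tau)}
        scenario = ScenarioSpec(name=f"sweep_{metric}", **taus)
        summary, _, _ = simulate_dataset(
            dataset, make_segmenter, scenario,
            rng=np.random.default_rng(seed), tolerance_mm=tolerance_mm,
        )
        raw[i] = summary.proportion_corrected
    adjusted = isotonic_regression(raw, increasing=True).x
    return CalibrationCurve(metric=metric, grid=grid,
                            corrected_fraction=np.clip(adjusted, 0.0, 1.0),
                            raw_fraction=raw)


def interpolate_tau(curve: CalibrationCurve, target_rate: float) -> float:
    """Piecewise-linear inverse of the monotone curve at ``target_rate``.

    Targets below the curve's minimum clamp to the grid minimum; above its
    maximum, to the grid maximum (both logged).  On plateaus the smallest
    threshold achieving the target is returned, minimizing user workload at
    equal quality.
    """
    if not 0.0 <= target_rate <= 1.0:
        raise ValueError("target_rate must lie in [0, 1]")
    y = curve.corrected_fraction
    x = curve.grid
    if y[-1] == y[0]:
        log.warning("flat calibration curve for %s; returning grid minimum", curve.metric)
        return float(x[0])
    if target_rate <= y[0]:
        if target_rate < y[0]:
            log.info("target %.3f below curve minimum %.3f; clamping to grid minimum",
                     target_rate, y[0])
        return float(x[0])
    if target_rate >= y[-1]:
        if target_rate > y[-1]:
            log.info("target %.3f above curve maximum %.3f; clamping to grid maximum",
                     target_rate, y[-1])
        return float(x[-1])
    i = int(np.searchsorted(y, target_rate, side="left"))
    if y[i] == target_rate and y[i - 1] < target_rate:
        pass  # interpolation below lands exactly on x[i] boundary handling
    x0, x1 = x[i - 1], x[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(x0)
    return float(x0 + (target_rate - y0) / (y1 - y0) * (x1 - x0))


def calibrate_scenarios(
    dataset,
    make_segmenter,
    grids: dict[str, np.ndarray],
    targets: dict[str, float] = DEFAULT_TARGETS,
    seed: int = 0,
    tolerance_mm: float = 1.0,
) -> dict[str, ScenarioSpec]:
    """Derive one ScenarioSpec per target correction rate.

    ``grids`` maps "dsc" and "nsd" to their candidate-threshold grids.  Each
    scenario's tau_dsc and tau_nsd come from the respective marginal sweep,
    interpolated at the scenario's target rate; the no-edits scenario is
    pinned to (0, 0) by definition.
    """
    curves = {
        metric: sweep_thresholds(dataset, make_segmenter, metric, grid,
                                 seed=seed, tolerance_mm=tolerance_mm)
        for metric, grid in grids.items()
    }
    scenarios = {}
    for name, rate in targets.items():
        if name == "no_edits" or rate == 0.0:
            scenarios[name] = ScenarioSpec(name=name, tau_dsc=0.0, tau_nsd=0.0)
            continue
        scenarios[name] = ScenarioSpec(
            name=name,
            tau_dsc=interpolate_tau(curves["dsc"], rate) if "dsc" in curves else 0.0,
            tau_nsd=interpolate_tau(curves["nsd"], rate) if "nsd" in curves else 0.0,
        )
    return scenarios
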