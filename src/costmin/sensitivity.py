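"""Deterministic scenario analysis: one-way and two-way sweeps, break-even.

Sweeps re-evaluate the model at point values with one (or two) parameters
overridden over a grid -- distributions are ignored, matching the usual
scenario-figure convention of decision-analytic costing studies.  Break-even
points (parameter values where the incremental cost crosses zero) are
located by a 64-point bracket pre-scan followed by bisection; all sign
changes found are refined and returned in ascending order, since synthetic
models need not be monotone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelDefinition, ModelError, evaluate_env, point_env, require_valid

DEFAULT_TOLERANCE = 1e-3
PRESCAN_POINTS = 64


@dataclass(frozen=True)
class SweepResult:
    """Grid trace of a one-way sweep plus detected break-even points."""

    parameter_id: str
    units: str
    values: np.ndarray
    tele_totals: np.ndarray
    conv_totals: np.ndarray
    incrementals: np.ndarray
    break_even: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "param_value": self.values,
            "tele_total": self.tele_totals,
            "conv_total": self.conv_totals,
            "incremental": self.incrementals,
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_break_even_csv(self, path: str | Path) -> None:
        pd.DataFrame({"break_even_value": list(self.break_even)}).to_csv(path, index=False)


@dataclass(frozen=True)
class TwoWaySweepResult:
    """Incremental-cost surface over a grid of two parameters.

    ``incrementals[i, j]`` is the incremental cost at
    ``(grid_a[i], grid_b[j])``; ``row_break_even`` holds, per value of
    parameter a, the break-even values of parameter b (empty tuple where the
    incremental does not cross zero along that row).
    """

    parameter_a: str
    parameter_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    incrementals: np.ndarray
    row_break_even: tuple[tuple[float, ...], ...]

    def to_frame(self) -> pd.DataFrame:
        a, b = np.meshgrid(self.grid_a, self.grid_b, indexing="ij")
        return pd.DataFrame({
            "a_value": a.ravel(),
            "b_value": b.ravel(),
            "incremental": self.incrementals.ravel(),
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_sweep_args(model: ModelDefinition, parameter_id: str,
                      lower: float, upper: float) -> None:
    require_valid(model)
    model.parameter(parameter_id)  # raises on unknown id
    if not lower < upper:
        raise ValueError(f"degenerate sweep range [{lower}, {upper}]")


def _incremental_on_grid(model: ModelDefinition, parameter_id: str,
                         values: np.ndarray,
                         fixed: dict | None = None) -> dict:
    env = point_env(model, fixed)
    env[parameter_id] = np.asarray(values, dtype=float)
    res = evaluate_env(model, env)
    ones = np.ones(len(values))
    tele = np.asarray(res["arm_totals"]["teledermatology"]) * ones
    conv = np.asarray(res["arm_totals"]["conventional"]) * ones
    if not (np.all(np.isfinite(tele)) and np.all(np.isfinite(conv))):
        raise ModelError(f"non-finite evaluation while sweeping {parameter_id!r}")
    return {"tele": tele, "conv": conv, "incr": tele - conv}


def one_way_sweep(model: ModelDefinition, parameter_id: str,
                  lower: float, upper: float, steps: int) -> SweepResult:
    """Evaluate the model over ``steps`` equally spaced values of one parameter.

    All other parameters stay at their point values.  Break-even points on
    the swept interval are refined by bisection at the default tolerance.
    """
    _check_sweep_args(model, parameter_id, lower, upper)
    if steps < 2:
        raise ValueError(f"steps must be >= 2, got {steps}")
    values = np.linspace(lower, upper, steps)
    out = _incremental_on_grid(model, parameter_id, values)
    roots = find_break_even(model, parameter_id, lower, upper, DEFAULT_TOLERANCE)
    return SweepResult(
        parameter_id=parameter_id,
        units=model.parameter(parameter_id).units,
        values=values,
        tele_totals=out["tele"],
        conv_totals=out["conv"],
        incrementals=out["incr"],
        break_even=tuple(roots),
    )


def find_break_even(model: ModelDefinition, parameter_id: str,
                    lower: float, upper: float,
                    tolerance: float = DEFAULT_TOLERANCE,
                    _fixed: dict | None = None) -> list[float]:
    """Locate all zero crossings of the incremental cost on [lower, upper].

    A 64-point pre-scan finds sign-change brackets; each bracket is bisected
    until its width is below ``tolerance`` (in parameter units).  Returns the
    roots sorted ascending; an empty list means the incremental cost does not
    change sign on the interval.
    """
    _check_sweep_args(model, parameter_id, lower, upper)
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")

    grid = np.linspace(lower, upper, PRESCAN_POINTS)
    incr = _incremental_on_grid(model, parameter_id, grid, _fixed)["incr"]

    def f(x: float) -> float:
        return float(_incremental_on_grid(model, parameter_id, np.array([x]), _fixed)["incr"][0])

    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = float(grid[i]), float(grid[i + 1])
        fa, fb = float(incr[i]), float(incr[i + 1])
        if fa == 0.0:
            roots.append(a)
            continue
        if fa * fb < 0.0:
            while b - a > tolerance:
                mid = 0.5 * (a + b)
                fm = f(mid)
                if fm == 0.0:
                    a = b = mid
                    break
                if fa * fm < 0.0:
                    b = mid
                else:
                    a, fa = mid, fm
            roots.append(0.5 * (a + b))
    if len(grid) and float(incr[-1]) == 0.0:
        roots.append(float(grid[-1]))
    # deduplicate near-identical roots from adjacent brackets
    deduped: list[float] = []
    for r in sorted(roots):
        if not deduped or r - deduped[-1] > tolerance:
            deduped.append(r)
    return deduped


def two_way_sweep(model: ModelDefinition, parameter_id_a: str, grid_a,
                  parameter_id_b: str, grid_b) -> TwoWaySweepResult:
    """Incremental cost over every (a, b) grid pair.

    The zero contour is reported as the per-row break-even values of
    parameter b, refined by bisection where the row's incremental changes
    sign.
    """
    if parameter_id_a == parameter_id_b:
        raise ValueError(f"two-way sweep needs distinct parameters, got {parameter_id_a!r} twice")
    require_valid(model)
    model.parameter(parameter_id_a)
    model.parameter(parameter_id_b)
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    if grid_a.size < 1 or grid_b.size < 1:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(grid_a) <= 0) or np.any(np.diff(grid_b) <= 0):
        raise ValueError("grids must be strictly increasing")

    incr = np.empty((grid_a.size, grid_b.size))
    rows: list[tuple[float, ...]] = []
    for i, a_val in enumerate(grid_a):
        fixed = {parameter_id_a: float(a_val)}
        incr[i] = _incremental_on_grid(model, parameter_id_b, grid_b, fixed)["incr"]
        if grid_b.size >= 2:
            roots = find_break_even(model, parameter_id_b,
                                    float(grid_b[0]), float(grid_b[-1]),
                                    DEFAULT_TOLERANCE, _fixed=fixed)
        else:
            roots = []
        rows.append(tuple(roots))
    return TwoWaySweepResult(
        parameter_a=parameter_id_a,
        parameter_b=parameter_id_b,
        grid_a=grid_a,
        grid_b=grid_b,
        incrementals=incr,
        row_break_even=tuple(rows),
    )
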