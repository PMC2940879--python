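"""Two-arm episode cost model: data model, validation, point evaluation.

A :class:`ModelDefinition` holds named :class:`Parameter` inputs and a set
of :class:`CostComponent` expressions, one arm each for the teledermatology
and the conventional referral process, every component belonging to one of
the five societal cost categories (investment, GP, dermatologist,
out-of-pocket, employer).  Point evaluation produces an
:class:`EpisodeCostBreakdown` with per-category and per-arm totals in euro
per care episode and the incremental cost (teledermatology minus
conventional).

Summation order is fixed -- components sorted lexicographically by id
within a category, categories in declaration order -- so results are
bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, InvalidDistributionError
from .expressions import Expr, evaluate, from_json, parameter_refs, to_json

SCHEMA_VERSION = 1

ARMS = ("teledermatology", "conventional")
CATEGORIES = ("investment", "gp", "dermatologist", "out_of_pocket", "employer")
FLAGS = ("uncertainty_analysis", "scenario_analysis")


class ModelError(ValueError):
    """Invalid model definition or evaluation request."""


@dataclass(frozen=True)
class Parameter:
    """A named model input.

    ``point_value`` is the deterministic base-case value; ``distribution``
    (required when flagged ``uncertainty_analysis``) describes its
    uncertainty for Monte Carlo analysis; ``sweep_range`` is the interval
    explored in scenario analysis.
    """

    id: str
    label: str = ""
    point_value: float = 0.0
    units: str = ""
    distribution: DistributionSpec | None = None
    sweep_range: tuple[float, float] | None = None
    flags: frozenset[str] = frozenset()

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "id": self.id,
            "label": self.label,
            "value": float(self.point_value),
            "units": self.units,
        }
        if self.distribution is not None:
            out["distribution"] = self.distribution.to_dict()
        if self.sweep_range is not None:
            out["range"] = [float(self.sweep_range[0]), float(self.sweep_range[1])]
        if self.flags:
            out["flags"] = sorted(self.flags)
        return out

    @staticmethod
    def from_dict(data: Mapping[str, Any]) -> "Parameter":
        allowed = {"id", "label", "value", "units", "distribution", "range", "flags"}
        unknown = set(data) - allowed
        if unknown:
            raise ModelError(f"unknown key(s) {sorted(unknown)} in parameter {data.get('id')!r}")
        if "id" not in data or "value" not in data:
            raise ModelError(f"parameter requires 'id' and 'value': {dict(data)!r}")
        dist = None
        if "distribution" in data and data["distribution"] is not None:
            dist = DistributionSpec.from_dict(data["distribution"])
        rng = None
        if "range" in data and data["range"] is not None:
            if len(data["range"]) != 2:
                raise ModelError(f"range of parameter {data['id']!r} must be [lower, upper]")
            rng = (float(data["range"][0]), float(data["range"][1]))
        flags = frozenset(data.get("flags", ()))
        return Parameter(
            id=str(data["id"]),
            label=str(data.get("label", "")),
            point_value=float(data["value"]),
            units=str(data.get("units", "")),
            distribution=dist,
            sweep_range=rng,
            flags=flags,
        )


@dataclass(frozen=True)
class CostComponent:
    """One cost term of one arm, assigned to a societal cost category."""

    id: str
    arm: str
    category: str
    expression: Expr

    def to_dict(self) -> dict[str, Any]:
        return {
            "id": self.id,
            "arm": self.arm,
            "category": self.category,
            "expression": to_json(self.expression),
        }

    @staticmethod
    def from_dict(data: Mapping[str, Any]) -> "CostComponent":
        allowed = {"id", "arm", "category", "expression"}
        unknown = set(data) - allowed
        if unknown:
            raise ModelError(f"unknown key(s) {sorted(unknown)} in component {data.get('id')!r}")
        missing = allowed - set(data)
        if missing:
            raise ModelError(f"component {data.get('id')!r} missing key(s) {sorted(missing)}")
        return CostComponent(
            id=str(data["id"]),
            arm=str(data["arm"]),
            category=str(data["category"]),
            expression=from_json(data["expression"]),
        )


@dataclass(frozen=True)
class ModelDefinition:
    """A complete two-arm cost model."""

    name: str
    parameters: tuple[Parameter, ...]
    components: tuple[CostComponent, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    @property
    def parameter_map(self) -> dict[str, Parameter]:
        return {p.id: p for p in self.parameters}

    def parameter(self, param_id: str) -> Parameter:
        try:
            return self.parameter_map[param_id]
        except KeyError:
            raise ModelError(f"unknown parameter {param_id!r}") from None

    def sampled_parameters(self) -> list[Parameter]:
        """Parameters flagged for uncertainty analysis, ordered by id."""
        return sorted(
            (p for p in self.parameters if "uncertainty_analysis" in p.flags),
            key=lambda p: p.id,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "metadata": dict(self.metadata),
            "parameters": [p.to_dict() for p in self.parameters],
            "components": [c.to_dict() for c in self.components],
        }

    @staticmethod
    def from_dict(data: Mapping[str, Any]) -> "ModelDefinition":
        allowed = {"schema_version", "name", "metadata", "parameters", "components"}
        unknown = set(data) - allowed
        if unknown:
            raise ModelError(f"unknown top-level key(s) {sorted(unknown)}")
        version = data.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ModelError(f"unsupported schema_version {version!r}")
        return ModelDefinition(
            name=str(data.get("name", "")),
            parameters=tuple(Parameter.from_dict(p) for p in data.get("parameters", [])),
            components=tuple(CostComponent.from_dict(c) for c in data.get("components", [])),
            metadata=dict(data.get("metadata", {})),
        )


@dataclass(frozen=True)
class EpisodeCostBreakdown:
    """Per-arm, per-category episode costs in euro.

    ``incremental_total`` is teledermatology minus conventional; negative
    incremental entries are legitimate (a category where teledermatology is
    cheaper) and are never clamped.
    """

    by_category: Mapping[str, Mapping[str, float]]  # arm -> category -> eur
    arm_totals: Mapping[str, float]
    incremental_by_category: Mapping[str, float]
    incremental_total: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"arm": arm, "category": cat, "cost_eur": self.by_category[arm][cat]}
            for arm in ARMS
            for cat in CATEGORIES
        ]
        return pd.DataFrame(rows, columns=["arm", "category", "cost_eur"])

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": "tele_total", "value_eur": self.arm_totals["teledermatology"]},
            {"quantity": "conv_total", "value_eur": self.arm_totals["conventional"]},
            {"quantity": "incremental_total", "value_eur": self.incremental_total},
        ]
        return pd.DataFrame(rows, columns=["quantity", "value_eur"])


# -- validation -----------------------------------------------------------

def validate_model(model: ModelDefinition) -> list[str]:
    """Validation report: an empty list for a valid model, otherwise one
    human-readable violation per problem, each naming the offending entity.
    """
    report: list[str] = []
    seen_params: set[str] = set()
    for p in model.parameters:
        if p.id in seen_params:
            report.append(f"parameter {p.id!r}: duplicate id")
        seen_params.add(p.id)
        if p.distribution is not None:
            try:
                p.distribution.validate()
            except InvalidDistributionError as exc:
                report.append(f"parameter {p.id!r}: {exc}")
        if "uncertainty_analysis" in p.flags and p.distribution is None:
            report.append(
                f"parameter {p.id!r}: flagged uncertainty_analysis but has no distribution"
            )
        for flag in p.flags:
            if flag not in FLAGS:
                report.append(f"parameter {p.id!r}: unknown flag {flag!r}")
        if p.sweep_range is not None:
            lo, hi = p.sweep_range
            if not lo < hi:
                report.append(f"parameter {p.id!r}: sweep range must have lower < upper")
            elif not (lo <= p.point_value <= hi):
                report.append(
                    f"parameter {p.id!r}: point value {p.point_value} outside "
                    f"sweep range [{lo}, {hi}]"
                )
        if not np.isfinite(p.point_value):
            report.append(f"parameter {p.id!r}: point value must be finite")

    seen_comps: set[str] = set()
    arms_present: set[str] = set()
    for c in model.components:
        if c.id in seen_comps:
            report.append(f"component {c.id!r}: duplicate id")
        seen_comps.add(c.id)
        if c.arm not in ARMS:
            report.append(f"component {c.id!r}: unknown arm {c.arm!r}")
        else:
            arms_present.add(c.arm)
        if c.category not in CATEGORIES:
            report.append(f"component {c.id!r}: unknown category {c.category!r}")
        for ref in sorted(parameter_refs(c.expression)):
            if ref not in seen_params:
                report.append(f"component {c.id!r}: references undeclared parameter {ref!r}")
    for arm in ARMS:
        if arm not in arms_present:
            report.append(f"model {model.name!r}: arm {arm!r} has no cost components")
    return report


def require_valid(model: ModelDefinition) -> None:
    report = validate_model(model)
    if report:
        raise ModelError("invalid model: " + "; ".join(report))


# -- evaluation -----------------------------------------------------------

def point_env(model: ModelDefinition,
              overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Environment of point values with overrides applied.

    Raises on an override for a parameter that does not exist.
    """
    env: dict[str, Any] = {p.id: p.point_value for p in model.parameters}
    if overrides:
        for key, value in overrides.items():
            if key not in env:
                raise ModelError(f"override for unknown parameter {key!r}")
            env[key] = value
    return env


def evaluate_env(model: ModelDefinition, env: Mapping[str, Any]) -> dict[str, Any]:
    """Evaluate every component against ``env`` (scalars or arrays).

    Returns a dict with ``by_category`` (arm -> category -> value),
    ``arm_totals`` and ``incremental``.  Components are summed in
    lexicographic id order within each category, categories in the fixed
    declaration order, so the result is bit-reproducible.
    """
    by_cat: dict[str, dict[str, Any]] = {arm: {cat: 0.0 for cat in CATEGORIES} for arm in ARMS}
    for comp in sorted(model.components, key=lambda c: c.id):
        value = evaluate(comp.expression, env)
        if np.ndim(value) == 0 and not np.all(np.isfinite(value)):
            raise ModelError(f"component {comp.id!r} evaluated to a non-finite value")
        by_cat[comp.arm][comp.category] = by_cat[comp.arm][comp.category] + value
    totals = {}
    for arm in ARMS:
        total = 0.0
        for cat in CATEGORIES:
            total = total + by_cat[arm][cat]
        totals[arm] = total
    incremental = totals["teledermatology"] - totals["conventional"]
    return {"by_category": by_cat, "arm_totals": totals, "incremental": incremental}


def evaluate_point(model: ModelDefinition,
                   overrides: Mapping[str, float] | None = None) -> EpisodeCostBreakdown:
    """Deterministic base-case evaluation at point values (plus overrides)."""
    require_valid(model)
    env = point_env(model, overrides)
    res = evaluate_env(model, env)
    for arm in ARMS:
        if not np.isfinite(res["arm_totals"][arm]):
            raise ModelError(f"arm {arm!r} total is non-finite")
    incr_by_cat = {
        cat: res["by_category"]["teledermatology"][cat] - res["by_category"]["conventional"][cat]
        for cat in CATEGORIES
    }
    return EpisodeCostBreakdown(
        by_category={arm: dict(res["by_category"][arm]) for arm in ARMS},
        arm_totals=dict(res["arm_totals"]),
        incremental_by_category=incr_by_cat,
        incremental_total=res["incremental"],
    )


# -- file IO --------------------------------------------------------------

def serialize_model(model: ModelDefinition) -> str:
    """Canonical JSON text (stable key order, 2-space indent)."""
    return json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n"


def save_model(model: ModelDefinition, path: str | Path) -> None:
    Path(path).write_text(serialize_model(model))


def load_model(path: str | Path) -> ModelDefinition:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"model file {path} is not valid JSON: {exc}") from exc
    return ModelDefinition.from_dict(data)


def write_breakdown_csv(breakdown: EpisodeCostBreakdown, path: str | Path) -> None:
    breakdown.to_frame().to_csv(path, index=False)


def write_summary_csv(breakdown: EpisodeCostBreakdown, path: str | Path) -> None:
    breakdown.summary_frame().to_csv(path, index=False)
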