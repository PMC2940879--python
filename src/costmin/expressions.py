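"""Arithmetic expression trees for cost components.

Component costs are arithmetic over model parameters.  The expression
language is deliberately total: constants, parameter references, and n-ary
add / subtract / multiply.  There is no division, so evaluation can never
fail on a zero denominator during a sweep; per-episode rates that would
need a parameter in a denominator are expressed as reciprocal-rate
parameters at model-build time.

Evaluation is array-aware: an environment may map parameter ids to scalars
or to equally-shaped numpy arrays, and the whole tree is evaluated
vectorised.  This is what makes 10,000-draw Monte Carlo runs and dense
scenario grids cheap.

Serialized form (inside model definition JSON files)::

    ["add", ["const", 21.3], ["mul", ["const", 2.5], ["param", "gp_minutes"]]]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

_OPS = ("add", "sub", "mul")
_LEAVES = ("const", "param")


class ExpressionError(ValueError):
    """Malformed expression tree or serialized form."""


@dataclass(frozen=True)
class Expr:
    """One node of an expression tree.

    ``kind`` is one of const / param / add / sub / mul.  ``sub`` is the
    first operand minus the sum of the rest.
    """

    kind: str
    value: float | None = None
    param_id: str | None = None
    operands: tuple["Expr", ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind == "const":
            if self.value is None or not np.isfinite(self.value):
                raise ExpressionError(f"const node needs a finite value, got {self.value!r}")
        elif self.kind == "param":
            if not self.param_id:
                raise ExpressionError("param node needs a non-empty parameter id")
        elif self.kind in _OPS:
            if len(self.operands) < 2:
                raise ExpressionError(f"{self.kind} node needs at least two operands")
        else:
            raise ExpressionError(f"unknown expression kind {self.kind!r}")


def const(x: float) -> Expr:
    return Expr("const", value=float(x))


def param(param_id: str) -> Expr:
    return Expr("param", param_id=str(param_id))


def add(*operands: Expr) -> Expr:
    return Expr("add", operands=tuple(operands))


def sub(*operands: Expr) -> Expr:
    return Expr("sub", operands=tuple(operands))


def mul(*operands: Expr) -> Expr:
    return Expr("mul", operands=tuple(operands))


def evaluate(expr: Expr, env: dict[str, Any]):
    """Evaluate an expression against ``env`` (scalars or numpy arrays)."""
    if expr.kind == "const":
        return expr.value
    if expr.kind == "param":
        try:
            return env[expr.param_id]
        except KeyError:
            raise ExpressionError(f"undeclared parameter {expr.param_id!r}") from None
    vals = [evaluate(op, env) for op in expr.operands]
    if expr.kind == "add":
        out = vals[0]
        for v in vals[1:]:
            out = out + v
        return out
    if expr.kind == "sub":
        out = vals[0]
        for v in vals[1:]:
            out = out - v
        return out
    # mul
    out = vals[0]
    for v in vals[1:]:
        out = out * v
    return out


def parameter_refs(expr: Expr) -> set[str]:
    """All parameter ids referenced anywhere in the tree."""
    if expr.kind == "param":
        return {expr.param_id}
    refs: set[str] = set()
    for op in expr.operands:
        refs |= parameter_refs(op)
    return refs


def to_json(expr: Expr) -> list:
    """Serialize to the nested-array form used in model definition files."""
    if expr.kind == "const":
        return ["const", expr.value]
    if expr.kind == "param":
        return ["param", expr.param_id]
    return [expr.kind] + [to_json(op) for op in expr.operands]


def from_json(data) -> Expr:
    """Parse the nested-array form; rejects anything malformed."""
    if not isinstance(data, (list, tuple)) or not data:
        raise ExpressionError(f"expression must be a non-empty array, got {data!r}")
    head = data[0]
    if head == "const":
        if len(data) != 2 or not isinstance(data[1], (int, float)) or isinstance(data[1], bool):
            raise ExpressionError(f"const expects one numeric argument, got {data!r}")
        return const(float(data[1]))
    if head == "param":
        if len(data) != 2 or not isinstance(data[1], str):
            raise ExpressionError(f"param expects one string argument, got {data!r}")
        return param(data[1])
    if head in _OPS:
        return Expr(head, operands=tuple(from_json(x) for x in data[1:]))
    raise ExpressionError(f"unknown expression operator {head!r}")
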