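"""Random model generators for property testing.

The original cost model behind the reference profiles had 282 variables of
which only a headline subset is published.  To exercise every pipeline
stage -- validation, evaluation, Monte Carlo, sweeps, break-even search,
importance ranking -- without any external data, this module generates
random but *valid* model definitions with known ground truth:

* :func:`generate_random_model` emits arbitrary parameter sets (point /
  triangular / beta-integral mix, values spread log-uniformly over three
  orders of magnitude like real unit costs) and random arithmetic component
  expressions, book-keeping the expected point totals as it goes;
* :func:`generate_linear_psa_fixture` builds a model whose incremental cost
  is an exact linear combination of independent unit-variance parameters,
  with the implied standardized regression coefficients computed in closed
  form -- the oracle for importance ranking;
* :func:`generate_monotone_breakeven_model` builds a model whose
  incremental cost is linear in one sweep parameter with a known root --
  the oracle for bisection break-even search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import expressions as ex
from .distributions import (
    BetaIntegralDistribution,
    PointDistribution,
    TriangularDistribution,
)
from .model import ARMS, CATEGORIES, CostComponent, ModelDefinition, Parameter

#: Half-width making a symmetric triangular distribution unit-variance
#: (variance of triangular(-s, 0, s) is s^2 / 6).
_UNIT_TRI_HALFWIDTH = math.sqrt(6.0)


@dataclass(frozen=True)
class SynthesisConfig:
    """Shape of a randomly generated model."""

    seed: int = 0
    n_parameters: int = 8
    n_components_per_arm: int = 3
    distribution_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)  # point, tri, beta
    expression_depth: int = 2

    def validate(self) -> None:
        if self.n_parameters < 1 or self.n_components_per_arm < 1:
            raise ValueError("n_parameters and n_components_per_arm must be >= 1")
        if self.expression_depth < 0:
            raise ValueError("expression_depth must be >= 0")
        if len(self.distribution_mix) != 3 or any(p < 0 for p in self.distribution_mix):
            raise ValueError("distribution_mix must be three non-negative proportions")
        if abs(sum(self.distribution_mix) - 1.0) > 1e-9:
            raise ValueError("distribution_mix proportions must sum to 1")


def _random_parameter(rng: np.random.Generator, pid: str,
                      mix: tuple[float, float, float]) -> Parameter:
    kind = rng.choice(("point", "triangular", "beta_integral"), p=mix)
    if kind == "beta_integral":
        n = int(rng.integers(5, 41))
        r = int(rng.integers(1, n))
        dist = BetaIntegralDistribution(r=r, n=n)
        value = r / n
    else:
        # log-uniform in [0.1, 100]: unit-cost scale heterogeneity
        value = float(10.0 ** rng.uniform(-1.0, 2.0))
        if kind == "point":
            dist = PointDistribution(value=value)
        else:
            lower = value * float(rng.uniform(0.3, 0.9))
            upper = value * float(rng.uniform(1.1, 3.0))
            dist = TriangularDistribution(lower=lower, mode=value, upper=upper)
    return Parameter(
        id=pid,
        label=f"synthetic parameter {pid}",
        point_value=value,
        units="",
        distribution=dist,
        flags=frozenset({"uncertainty_analysis"}),
    )


def _random_expression(rng: np.random.Generator, params: list[Parameter],
                       depth: int) -> tuple[ex.Expr, float]:
    """Random expression tree plus its independently book-kept point value."""
    if depth <= 0 or rng.random() < 0.3:
        if rng.random() < 0.5:
            c = float(10.0 ** rng.uniform(-1.0, 2.0))
            return ex.const(c), c
        p = params[int(rng.integers(len(params)))]
        return ex.param(p.id), p.point_value
    op = rng.choice(("add", "sub", "mul"))
    n_ops = int(rng.integers(2, 4))
    children = [_random_expression(rng, params, depth - 1) for _ in range(n_ops)]
    exprs = [c[0] for c in children]
    vals = [c[1] for c in children]
    if op == "add":
        return ex.add(*exprs), sum(vals)
    if op == "sub":
        return ex.sub(*exprs), vals[0] - sum(vals[1:])
    value = 1.0
    for v in vals:
        value *= v
    return ex.mul(*exprs), value


def generate_random_model(config: SynthesisConfig) -> tuple[ModelDefinition, dict[str, float]]:
    """Generate a random valid model plus its expected point arm totals.

    The expected totals are accumulated with plain float arithmetic while
    the expressions are emitted, giving an independent check on the
    evaluator.  Identical configs reproduce byte-identical models.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = [
        _random_parameter(rng, f"p{i:03d}", config.distribution_mix)
        for i in range(config.n_parameters)
    ]
    components: list[CostComponent] = []
    expected = {arm: 0.0 for arm in ARMS}
    idx = 0
    for arm in ARMS:
        for j in range(config.n_components_per_arm):
            expr, value = _random_expression(rng, params, config.expression_depth)
            components.append(
                CostComponent(
                    id=f"c{idx:03d}_{arm[:4]}",
                    arm=arm,
                    category=CATEGORIES[j % len(CATEGORIES)],
                    expression=expr,
                )
            )
            expected[arm] += value
            idx += 1
    model = ModelDefinition(
        name=f"synthetic-{config.seed}",
        parameters=tuple(params),
        components=tuple(components),
        metadata={"generator": "costmin.synthetic", "seed": str(config.seed)},
    )
    return model, expected


def generate_linear_psa_fixture(
    seed: int,
    coefficients,
    noise_sd: float = 0.0,
) -> tuple[ModelDefinition, pd.DataFrame]:
    """Model whose incremental cost is an exact linear form, with oracle.

    The teledermatology arm costs ``base + sum(c_i * x_i) [+ noise]`` with
    each ``x_i`` an independent unit-variance symmetric triangular variate;
    the conventional arm is a constant.  The expected standardized
    regression coefficient of ``x_i`` is ``c_i / sd(incremental)`` with
    ``sd(incremental) = sqrt(sum c_i^2 + noise_sd^2)`` -- closed form for
    independent covariates.

    Returns the model and a frame with columns ``parameter`` and
    ``std_coefficient`` (the noise parameter included when present).
    """
    coefficients = [float(c) for c in coefficients]
    if not coefficients:
        raise ValueError("at least one coefficient is required")
    rng = np.random.default_rng(seed)
    base_tele = float(rng.uniform(50, 150))
    base_conv = float(rng.uniform(50, 150))

    unit_tri = TriangularDistribution(-_UNIT_TRI_HALFWIDTH, 0.0, _UNIT_TRI_HALFWIDTH)
    params = [
        Parameter(f"x{i:02d}", f"planted covariate {i}", 0.0, "",
                  unit_tri, None, frozenset({"uncertainty_analysis"}))
        for i in range(len(coefficients))
    ]
    terms = [ex.const(base_tele)] + [
        ex.mul(ex.const(c), ex.param(p.id)) for c, p in zip(coefficients, params)
    ]
    all_coefs = list(coefficients)
    all_ids = [p.id for p in params]
    if noise_sd > 0.0:
        noise_tri = TriangularDistribution(
            -noise_sd * _UNIT_TRI_HALFWIDTH, 0.0, noise_sd * _UNIT_TRI_HALFWIDTH
        )
        params.append(Parameter("x_noise", "unplanted noise covariate", 0.0, "",
                                noise_tri, None, frozenset({"uncertainty_analysis"})))
        terms.append(ex.param("x_noise"))
        all_coefs.append(noise_sd)  # sd of the noise term, coefficient 1
        all_ids.append("x_noise")

    model = ModelDefinition(
        name=f"linear-psa-fixture-{seed}",
        parameters=tuple(params),
        components=(
            CostComponent("tele_linear", "teledermatology", "dermatologist",
                          ex.add(*terms)),
            CostComponent("conv_const", "conventional", "dermatologist",
                          ex.const(base_conv)),
        ),
        metadata={"generator": "costmin.synthetic.linear", "seed": str(seed)},
    )
    sd_y = math.sqrt(sum(c * c for c in all_coefs))
    expected = pd.DataFrame({
        "parameter": all_ids,
        "std_coefficient": [c / sd_y if sd_y > 0 else 0.0 for c in all_coefs],
    })
    return model, expected


def generate_monotone_breakeven_model(
    seed: int,
) -> tuple[ModelDefinition, str, float, float, float]:
    """Model with incremental cost linear in one parameter, root known.

    Returns ``(model, parameter_id, lower, upper, root)`` where the
    incremental cost changes sign exactly once at ``root`` inside
    ``(lower, upper)``.
    """
    rng = np.random.default_rng(seed)
    lower = float(rng.uniform(0, 10))
    upper = lower + float(rng.uniform(5, 200))
    root = float(rng.uniform(lower + 0.05 * (upper - lower),
                             upper - 0.05 * (upper - lower)))
    slope = float(rng.uniform(0.1, 10)) * (1.0 if rng.random() < 0.5 else -1.0)
    base_conv = float(rng.uniform(10, 400))
    point = float(rng.uniform(lower, upper))
    # tele(x) = conv + slope * (x - root): crosses conv exactly at x = root
    params = (
        Parameter("x_sweep", "swept parameter", point, "", None, (lower, upper),
                  frozenset({"scenario_analysis"})),
    )
    components = (
        CostComponent(
            "tele_linear", "teledermatology", "dermatologist",
            ex.add(ex.const(base_conv),
                   ex.mul(ex.const(slope), ex.sub(ex.param("x_sweep"), ex.const(root)))),
        ),
        CostComponent("conv_const", "conventional", "dermatologist", ex.const(base_conv)),
    )
    model = ModelDefinition(
        name=f"monotone-breakeven-{seed}",
        parameters=params,
        components=components,
        metadata={"generator": "costmin.synthetic.monotone", "seed": str(seed)},
    )
    return model, "x_sweep", lower, upper, root
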