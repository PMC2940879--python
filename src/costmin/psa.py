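"""Probabilistic sensitivity analysis by second-order Monte Carlo simulation.

Every parameter flagged ``uncertainty_analysis`` is drawn ``n_draws`` times
from its distribution (independent deterministic substreams per parameter);
all other parameters stay at their point values.  The whole draw matrix is
pushed through the cost model vectorised, giving per-draw arm totals and
the per-draw incremental cost, from which percentile summaries, the
probability that each arm is cheaper, and a histogram of the incremental
cost are computed.  Correlation between arms arises only through shared
parameters inside the component expressions -- the model structure itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import ModelDefinition, evaluate_env, point_env, require_valid
from .distributions import substream_rng


@dataclass(frozen=True)
class PSAConfig:
    """Monte Carlo settings: number of draws, root seed, interval level."""

    n_draws: int = 10_000
    seed: int = 0
    ci_level: float = 0.95

    def validate(self) -> None:
        if self.n_draws < 2:
            raise ValueError(f"n_draws must be >= 2, got {self.n_draws}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")


def _percentile_ci(x: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(x, [100 * alpha, 100 * (1 - alpha)], method="midpoint")
    return float(lo), float(hi)


@dataclass
class PSAResult:
    """Stored draws plus summaries of a probabilistic sensitivity analysis.

    ``draws`` has one row per simulation: the sampled parameter columns (in
    parameter-id order) followed by ``tele_total``, ``conv_total`` and
    ``incremental`` (all euro per episode).  Summaries are computed from the
    stored draws, never re-sampled.
    """

    config: PSAConfig
    parameter_ids: tuple[str, ...]
    draws: pd.DataFrame
    histogram_bins: int = 50
    summary: pd.DataFrame = field(init=False)
    prob_cost_saving: float = field(init=False)
    prob_conventional_cheaper: float = field(init=False)
    prob_tie: float = field(init=False)
    histogram_edges: np.ndarray = field(init=False)
    histogram_counts: np.ndarray = field(init=False)

    def __post_init__(self):
        incr = self.draws["incremental"].to_numpy()
        rows = []
        for name in ("tele_total", "conv_total", "incremental"):
            x = self.draws[name].to_numpy()
            lo, hi = _percentile_ci(x, self.config.ci_level)
            rows.append({"quantity": name, "mean": float(x.mean()),
                         "ci_lower": lo, "ci_upper": hi})
        self.summary = pd.DataFrame(rows, columns=["quantity", "mean", "ci_lower", "ci_upper"])
        n = len(incr)
        self.prob_cost_saving = float(np.count_nonzero(incr < 0) / n)
        self.prob_conventional_cheaper = float(np.count_nonzero(incr > 0) / n)
        self.prob_tie = float(np.count_nonzero(incr == 0) / n)
        lo, hi = float(incr.min()), float(incr.max())
        if lo == hi:  # degenerate: all draws identical
            lo, hi = lo - 0.5, hi + 0.5
        counts, edges = np.histogram(incr, bins=self.histogram_bins, range=(lo, hi))
        self.histogram_edges = edges
        self.histogram_counts = counts

    # -- writers ----------------------------------------------------------

    def write_draws_csv(self, path: str | Path) -> None:
        out = self.draws.copy()
        out.insert(0, "draw", np.arange(len(out)))
        out.to_csv(path, index=False)

    def write_summary_csv(self, path: str | Path) -> None:
        self.summary.to_csv(path, index=False)

    def write_histogram_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "bin_lower": self.histogram_edges[:-1],
            "bin_upper": self.histogram_edges[1:],
            "count": self.histogram_counts,
        }).to_csv(path, index=False)


def run_psa(model: ModelDefinition, config: PSAConfig | None = None) -> PSAResult:
    """Run the Monte Carlo uncertainty analysis.

    Deterministic for a given (model, seed, n_draws); with the same seed,
    the first half of a 2n-draw run equals an n-draw run (per-parameter
    substreams are prefix-stable).
    """
    config = config or PSAConfig()
    config.validate()
    require_valid(model)

    sampled = model.sampled_parameters()
    for p in sampled:
        if p.distribution is None:  # validate_model already rejects this
            raise ValueError(f"parameter {p.id!r} flagged for uncertainty analysis "
                             "but has no distribution")

    env = point_env(model)
    columns: dict[str, np.ndarray] = {}
    for p in sampled:
        draws = p.distribution.sample(config.n_draws, substream_rng(config.seed, p.id))
        env[p.id] = draws
        columns[p.id] = draws

    res = evaluate_env(model, env)
    ones = np.ones(config.n_draws)
    frame = pd.DataFrame(columns)
    # broadcast in case an arm is parameter-free (scalar total)
    frame["tele_total"] = np.asarray(res["arm_totals"]["teledermatology"]) * ones
    frame["conv_total"] = np.asarray(res["arm_totals"]["conventional"]) * ones
    frame["incremental"] = frame["tele_total"] - frame["conv_total"]
    return PSAResult(config=config, parameter_ids=tuple(p.id for p in sampled), draws=frame)


def prob_positive_gaussian(mean: float, interval: tuple[float, float],
                           level: float = 0.95) -> float:
    """Probability that a quantity exceeds zero, Gaussian approximation.

    Treats the quantity as normal with the given mean and a standard
    deviation recovered from a central ``level`` interval:
    ``sd = (upper - lower) / (2 z)`` with ``z`` the standard-normal quantile
    of ``(1 + level) / 2``.  Used as an independent analytic check on the
    simulated probability that one arm is cheaper.
    """
    lower, upper = interval
    if not lower < upper:
        raise ValueError(f"degenerate interval ({lower}, {upper})")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = norm.ppf((1.0 + level) / 2.0)
    sd = (upper - lower) / (2.0 * z)
    return float(norm.cdf(mean / sd))
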