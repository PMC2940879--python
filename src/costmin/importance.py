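"""Parameter importance ranking by standardized regression coefficients.

A linear regression of the per-draw incremental cost on the sampled
parameter draws -- the classic metamodel summary of a probabilistic
sensitivity analysis -- ranks parameters by the absolute value of their
standardized coefficients.  Response and covariates are z-scored (mean 0,
variance 1, ``n - 1`` denominator) before an ordinary least-squares fit, so
the coefficients are dimensionless and invariant under affine rescaling of
any input.  Zero-variance (point-mass) parameters cannot carry a
coefficient and are reported separately as excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .psa import PSAResult


@dataclass(frozen=True)
class ImportanceResult:
    """Standardized coefficients, ranks and fit quality.

    ``table`` has one row per included parameter with columns
    ``parameter``, ``std_coefficient`` and ``abs_rank`` (1 = most
    influential); ``excluded`` lists zero-variance parameters.
    """

    table: pd.DataFrame
    excluded: tuple[str, ...]
    r_squared: float

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def rank_importance(psa_result: PSAResult) -> ImportanceResult:
    """Rank the sampled parameters of a stored PSA by influence."""
    return rank_importance_from_frame(psa_result.draws, list(psa_result.parameter_ids))


def rank_importance_from_frame(draws: pd.DataFrame,
                               parameter_ids: list[str]) -> ImportanceResult:
    """Importance ranking from a draws table (one row per simulation).

    ``draws`` must contain one column per id in ``parameter_ids`` plus an
    ``incremental`` column.  Raises on fewer than two draws, on an
    all-constant design, and on rank deficiency (fewer draws than included
    covariates plus one) -- deficiency is reported, never silently
    regularized away.
    """
    if not parameter_ids:
        raise ValueError("at least one sampled parameter is required")
    n = len(draws)
    if n < 2:
        raise ValueError(f"importance ranking needs >= 2 draws, got {n}")

    y = draws["incremental"].to_numpy(dtype=float)
    included: list[str] = []
    excluded: list[str] = []
    cols: list[np.ndarray] = []
    for pid in parameter_ids:
        x = draws[pid].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:  # point mass: no variance to attribute
            excluded.append(pid)
        else:
            included.append(pid)
            cols.append((x - x.mean()) / x.std(ddof=1))
    if not included:
        raise ValueError("all covariates are constant; nothing to rank")
    if n < len(included) + 1:
        raise ValueError(
            f"rank-deficient design: {n} draws for {len(included)} covariates "
            "(need at least covariates + 1)"
        )

    if np.ptp(y) == 0.0:
        # Incremental cost has no variance; every coefficient is zero.
        coefs = np.zeros(len(included))
        r2 = 0.0
    else:
        y_std = (y - y.mean()) / y.std(ddof=1)
        design = sm.add_constant(np.column_stack(cols), has_constant="add")
        fit = sm.OLS(y_std, design).fit()
        coefs = np.asarray(fit.params[1:], dtype=float)
        r2 = float(fit.rsquared)

    order = sorted(range(len(included)), key=lambda i: (-abs(coefs[i]), included[i]))
    rank = {included[i]: r + 1 for r, i in enumerate(order)}
    table = pd.DataFrame({
        "parameter": included,
        "std_coefficient": coefs,
        "abs_rank": [rank[pid] for pid in included],
    }).sort_values("abs_rank", kind="stable").reset_index(drop=True)
    return ImportanceResult(table=table, excluded=tuple(excluded), r_squared=r2)
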