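"""Quality assessment: predictive R², UQ Spearman ρ, and rank sums.

Predictive performance is the cross-validated coefficient of
determination R² = 1 - Σ(y-ŷ)²/Σ(y-ȳ)², which can become negative when
the prediction errors exceed the total sum of squares.  UQ performance
is Spearman's ρ between the per-compound uncertainties and absolute
errors — Pearson's correlation on the ranks, with average ranks for
ties — measuring how well the uncertainty ranks predictions by error
magnitude.  Rank sums compare featurization x technique combinations
across datasets: within each dataset the best combination gets rank 1,
and ranks are summed over datasets (lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PerformancePair",
    "r_squared",
    "uq_spearman",
    "rank_sums",
    "diagnose_uncertainty",
]


@dataclass
class PerformancePair:
    """Predictive and UQ performance of one ensemble (n = evaluable compounds)."""

    r2: float
    rho: float
    n: int


def r_squared(y, yhat) -> float:
    """Coefficient of determination; errors on constant observed values."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def uq_spearman(uncertainties, abs_errors) -> float:
    """Spearman ρ between uncertainties and absolute errors.

    Pairs with a missing (NaN) entry on either side are excluded.  When
    all retained uncertainties are tied the ranking carries no signal
    and NaN is returned — the "comparable standard deviations for all
    predictions" degeneracy.
    """
    u = np.asarray(uncertainties, dtype=float)
    e = np.asarray(abs_errors, dtype=float)
    if u.shape != e.shape:
        raise ValueError("inputs must have the same shape")
    ok = np.isfinite(u) & np.isfinite(e)
    u, e = u[ok], e[ok]
    if u.size < 3:
        raise ValueError("need at least 3 evaluable pairs for Spearman rho")
    if np.all(u == u[0]) or np.all(e == e[0]):
        return float("nan")
    rho, _ = stats.spearmanr(u, e)
    return float(rho)


def rank_sums(table: pd.DataFrame, higher_is_better: bool = True) -> pd.DataFrame:
    """Within-dataset ranks (1 = best, average ranks on ties) and their sums.

    ``table`` has one row per dataset and one column per combination;
    every cell must be present.  Returns the rank table with an added
    ``rank_sum`` row summing each column over datasets.
    """
    if table.isna().any().any():
        bad = [(r, c) for r, c in zip(*np.where(table.isna().to_numpy()))]
        cells = [(table.index[r], table.columns[c]) for r, c in bad]
        raise ValueError(f"incomplete performance grid, missing cells: {cells}")
    sign = -1.0 if higher_is_better else 1.0
    ranks = table.apply(
        lambda row: stats.rankdata(sign * row.to_numpy(), method="average"),
        axis=1,
        result_type="broadcast",
    )
    out = ranks.copy()
    out.loc["rank_sum"] = ranks.sum(axis=0)
    return out


def diagnose_uncertainty(result, collapse_ratio: float = 0.1) -> str:
    """Flag pathological uncertainty patterns of an :class:`EnsembleResult`.

    Returns ``"bias_dominated"`` when the typical uncertainty is near
    zero relative to the typical error (members agree on wrong answers —
    the regime where ensembles fail entirely because bias dominates the
    error), ``"undefined"`` when too few compounds have an uncertainty,
    and ``"ok"`` otherwise.
    """
    u = np.asarray(result.uncertainty, dtype=float)
    e = np.asarray(result.abs_error, dtype=float)
    ok = np.isfinite(u) & np.isfinite(e)
    if ok.sum() < 3:
        return "undefined"
    med_u = float(np.median(u[ok]))
    med_e = float(np.median(e[ok]))
    if med_e > 0 and med_u < collapse_ratio * med_e:
        return "bias_dominated"
    return "ok"
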