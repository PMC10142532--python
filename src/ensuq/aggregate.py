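"""Collapse the member matrix into ensemble predictions and uncertainties.

The ensemble reports, per compound, the arithmetic mean of its member
predictions,

    y_bar = (1/M) * sum_i y_i ,

and quantifies its uncertainty as the population standard deviation of
the members,

    u = sqrt((1/M) * sum_i (y_i - y_bar)^2) ,

with the divisor equal to the member count M (not M - 1); a sample-std
variant is available by flag.  After outlier filtering, M is the
per-compound retained count — predictions are eliminated, compounds are
not.  A compound with fewer than 2 retained members has an undefined
uncertainty (NaN); with 0 retained members both quantities are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .subsampling import MemberPredictionMatrix

__all__ = ["EnsembleResult", "aggregate"]


@dataclass
class EnsembleResult:
    """Per-compound ensemble estimates plus bookkeeping."""

    ids: list[str]
    y: np.ndarray
    yhat: np.ndarray
    uncertainty: np.ndarray
    abs_error: np.ndarray
    n_retained: np.ndarray
    n_members: int

    @property
    def n(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "y": self.y,
                "yhat": self.yhat,
                "uncertainty": self.uncertainty,
                "abs_error": self.abs_error,
                "n_members_retained": self.n_retained,
            }
        )

    def r2(self) -> float:
        from .metrics import r_squared

        ok = np.isfinite(self.yhat)
        return r_squared(self.y[ok], self.yhat[ok])

    def uq_spearman(self) -> float:
        from .metrics import uq_spearman

        return uq_spearman(self.uncertainty, self.abs_error)


def aggregate(
    mpm: MemberPredictionMatrix,
    y,
    ids: list[str] | None = None,
    subset=None,
    population: bool = True,
) -> EnsembleResult:
    """Ensemble mean and std over (a subset of) members, mask-aware.

    ``subset`` selects member columns (all by default); it must contain
    at least one member.  Masked entries are excluded and the divisor is
    the per-compound retained count.  ``population=False`` switches the
    uncertainty to the sample standard deviation (divisor count - 1).
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != mpm.n:
        raise ValueError("y length does not match member matrix")
    cols = np.arange(mpm.n_members) if subset is None else np.asarray(subset, dtype=int)
    if cols.size < 1:
        raise ValueError("subset must contain at least one member")
    vals = mpm.values[:, cols]
    msk = mpm.mask[:, cols]
    cnt = msk.sum(axis=1).astype(float)

    safe = np.where(msk, vals, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        yhat = np.where(cnt > 0, safe.sum(axis=1) / cnt, np.nan)
        dev2 = np.where(msk, (vals - yhat[:, None]) ** 2, 0.0).sum(axis=1)
        if population:
            var = np.where(cnt >= 2, dev2 / cnt, np.nan)
        else:
            var = np.where(cnt >= 2, dev2 / np.maximum(cnt - 1.0, 1.0), np.nan)
    uncertainty = np.sqrt(var)
    abs_error = np.abs(yhat - y)
    return EnsembleResult(
        ids=ids if ids is not None else [str(i) for i in range(mpm.n)],
        y=y,
        yhat=yhat,
        uncertainty=uncertainty,
        abs_error=abs_error,
        n_retained=msk.sum(axis=1),
        n_members=int(cols.size),
    )
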