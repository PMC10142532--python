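"""Growing-ensemble analysis: cumulative curves and saturation detection.

Performance is tracked while members are accumulated one at a time —
first member, first two, first three, and so on — giving a cumulative
member curve of R² (from size 1) or of UQ ρ (from size 2, the minimum
to compute a standard deviation).  Because such a curve depends on the
arbitrary order in which members were generated, the member order is
randomly permuted many times (200 by default) and the per-size median
(or mean, by flag) over the permuted curves is taken; this removes the
ordering bias and smooths the curve.

A Michaelis–Menten-type saturation function with an additive offset,

    f(m) = a + b * m / (c + m),

is least-squares fitted through the median curve (the offset is needed
because curves start at a nonzero single-model performance).  The first
member-wise step of the *fitted* curve whose gain f(m+1) - f(m) falls
below 0.0001 — a change beyond the fourth decimal place — marks the
saturation size m*: the smallest ensemble size beyond which additional
members no longer pay off.  For b > 0 the step gains decrease strictly
in m, so m* is unique.  Flat, decreasing or noisy curves are flagged
instead of yielding a size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .metrics import r_squared, uq_spearman
from .subsampling import MemberPredictionMatrix

__all__ = [
    "CumulativeCurve",
    "SaturationFit",
    "cumulative_curve",
    "permutation_median_curve",
    "michaelis_menten",
    "fit_saturation",
    "summarize_saturation",
]

GAIN_THRESHOLD = 1e-4


@dataclass
class CumulativeCurve:
    """Performance as a function of ensemble size."""

    metric: str  # "r2" or "rho"
    sizes: np.ndarray
    values: np.ndarray
    variant: str = "raw"  # "raw" or "permutation_median"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.sizes.shape != self.values.shape:
            raise ValueError("sizes and values must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "value": self.values,
                "metric": self.metric,
                "variant": self.variant,
            }
        )


@dataclass
class SaturationFit:
    """Fitted saturation law and the detected minimal useful ensemble size."""

    a: float
    b: float
    c: float
    residual: float
    m_star: int | None
    flag: str  # ok | flat | noisy | decreasing
    threshold: float = GAIN_THRESHOLD


def _cumulative_stats(mpm: MemberPredictionMatrix, order: np.ndarray):
    """Running mask-aware mean and population std over member prefixes."""
    vals = mpm.values[:, order]
    msk = mpm.mask[:, order]
    # center per row by the full-matrix retained mean: keeps the running
    # variance numerically stable (exactly 0 for identical members)
    tot = msk.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        center = np.where(tot > 0, np.where(msk, vals, 0.0).sum(axis=1) / tot, 0.0)
    dev = np.where(msk, vals - center[:, None], 0.0)
    C = np.cumsum(msk, axis=1).astype(float)
    S1 = np.cumsum(dev, axis=1)
    S2 = np.cumsum(dev**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dev = np.where(C > 0, S1 / C, np.nan)
        mean = center[:, None] + mean_dev
        var = np.where(C >= 2, np.maximum(S2 / C - mean_dev**2, 0.0), np.nan)
    return mean, np.sqrt(var), C


def cumulative_curve(
    mpm: MemberPredictionMatrix, y, metric: str = "r2", order=None
) -> CumulativeCurve:
    """Metric of the aggregate over the first s members, for each size s."""
    y = np.asarray(y, dtype=float)
    M = mpm.n_members
    if order is None:
        order = np.arange(M)
    order = np.asarray(order, dtype=int)
    if sorted(order.tolist()) != list(range(M)):
        raise ValueError("order must be a permutation of all member indices")
    if metric not in ("r2", "rho"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "rho" and M < 2:
        raise ValueError("UQ curve needs at least 2 members")
    start = 1 if metric == "r2" else 2
    mean, std, C = _cumulative_stats(mpm, order)
    sizes = np.arange(start, M + 1)
    values = np.full(sizes.shape, np.nan)
    for j, s in enumerate(sizes):
        col = s - 1
        if metric == "r2":
            ok = C[:, col] > 0
            if ok.sum() < 2:
                continue
            try:
                values[j] = r_squared(y[ok], mean[ok, col])
            except ValueError:
                values[j] = np.nan
        else:
            err = np.abs(mean[:, col] - y)
            try:
                values[j] = uq_spearman(std[:, col], err)
            except ValueError:
                values[j] = np.nan
    return CumulativeCurve(metric=metric, sizes=sizes, values=values, variant="raw")


def permutation_median_curve(
    mpm: MemberPredictionMatrix,
    y,
    metric: str = "r2",
    n_permutations: int = 200,
    seed: int = 0,
    center: str = "median",
) -> CumulativeCurve:
    """Per-size median (or mean) over randomly permuted member orders."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    curves = []
    sizes = None
    for _ in range(n_permutations):
        order = rng.permutation(mpm.n_members)
        c = cumulative_curve(mpm, y, metric=metric, order=order)
        curves.append(c.values)
        sizes = c.sizes
    stack = np.vstack(curves)
    if np.all(np.isnan(stack)):
        values = np.full(sizes.shape, np.nan)
    elif center == "median":
        values = np.nanmedian(stack, axis=0)
    elif center == "mean":
        values = np.nanmean(stack, axis=0)
    else:
        raise ValueError(f"unknown center {center!r}")
    return CumulativeCurve(metric=metric, sizes=sizes, values=values, variant="permutation_median")


def michaelis_menten(m, a, b, c):
    """Saturation law with offset: f(m) = a + b*m/(c+m)."""
    return a + b * m / (c + m)


def fit_saturation(
    curve: CumulativeCurve,
    gain_threshold: float = GAIN_THRESHOLD,
    noisy_rmse_fraction: float = 0.2,
) -> SaturationFit:
    """Least-squares Michaelis–Menten fit and saturation-size detection.

    The saturation size m* is the smallest integer size m (within the
    curve's size range) with f(m+1) - f(m) < ``gain_threshold`` on the
    fitted curve.  Quality flags: ``flat`` (negligible span; m* at the
    first evaluable step), ``decreasing`` (b < 0; no size reported),
    ``noisy`` (failed convergence or residual large relative to the
    curve span; no size reported), else ``ok``.
    """
    sizes = curve.sizes.astype(float)
    values = curve.values
    ok = np.isfinite(values)
    if ok.sum() < 4:
        raise ValueError("need at least 4 finite curve points to fit saturation")
    sizes, values = sizes[ok], values[ok]
    span = float(values.max() - values.min())
    M = int(curve.sizes.max())
    first = int(curve.sizes.min())

    if span < 1e-10:
        return SaturationFit(
            a=float(values.mean()), b=0.0, c=1.0, residual=0.0,
            m_star=first, flag="flat", threshold=gain_threshold,
        )

    p0 = (values[0], values[-1] - values[0], max(M / 10.0, 1.0))
    try:
        popt, _ = curve_fit(
            michaelis_menten,
            sizes,
            values,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return SaturationFit(
            a=float("nan"), b=float("nan"), c=float("nan"), residual=float("nan"),
            m_star=None, flag="noisy", threshold=gain_threshold,
        )
    a, b, c = (float(v) for v in popt)
    resid = values - michaelis_menten(sizes, a, b, c)
    rmse = float(np.sqrt(np.mean(resid**2)))

    if b < 0:
        return SaturationFit(a=a, b=b, c=c, residual=rmse, m_star=None,
                             flag="decreasing", threshold=gain_threshold)
    if rmse > noisy_rmse_fraction * max(span, 1e-12):
        return SaturationFit(a=a, b=b, c=c, residual=rmse, m_star=None,
                             flag="noisy", threshold=gain_threshold)

    # step gain of the fitted curve: b*c/((c+m)(c+m+1)), strictly decreasing
    m_star = None
    for m in range(first, M):
        gain = michaelis_menten(m + 1.0, a, b, c) - michaelis_menten(float(m), a, b, c)
        if gain < gain_threshold:
            m_star = m
            break
    flag = "ok" if m_star is not None else "noisy"
    if abs(b) < 1e-8:
        flag = "flat"
        m_star = first
    return SaturationFit(a=a, b=b, c=c, residual=rmse, m_star=m_star,
                         flag=flag, threshold=gain_threshold)


def summarize_saturation(fits: pd.DataFrame, group_cols=("combination",)) -> pd.DataFrame:
    """Median detected saturation size per group, with exclusion counts.

    ``fits`` needs the grouping columns plus ``m_star`` (NaN/None where
    no saturation was detected).  Groups without any successful fit are
    reported with a missing median, not raised.  Medians of even-sized
    groups may be half-integers.
    """
    df = fits.copy()
    df["m_star"] = pd.to_numeric(df["m_star"], errors="coerce")
    rows = []
    for key, grp in df.groupby(list(group_cols), dropna=False, sort=True):
        detected = grp["m_star"].dropna()
        rows.append(
            {
                **dict(zip(group_cols, key if isinstance(key, tuple) else (key,))),
                "median_m_star": float(detected.median()) if len(detected) else float("nan"),
                "n_detected": int(len(detected)),
                "n_excluded": int(len(grp) - len(detected)),
            }
        )
    return pd.DataFrame(rows)
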