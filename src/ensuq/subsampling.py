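"""Ensemble-member generation by repeated k-fold CV (or bootstrap).

One ensemble *member* is one full CV repetition: at k = 2 the pair of
fold models of a repetition jointly provides exactly one out-of-sample
prediction for every compound, so an ensemble of M members requires
M * k model fits (the reference configuration of M = 200 repetitions
at k = 2 fits 400 models).  The bootstrap alternative trains one model
per member on n draws with replacement and predicts the out-of-bag
compounds; entries where a compound was in-bag stay undefined.

Feature scaling is fitted on the training partition of every split and
applied to both partitions, so no test-partition statistics ever reach
a model.  Each member derives its own child seed from (plan seed,
repetition index); results are therefore independent of scheduling.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adapters import RegressorSpec, fit as fit_adapter, predict as predict_adapter
from .featurize import FeatureMatrix, apply_scaler, fit_scaler

__all__ = [
    "SplitPlan",
    "MemberPredictionMatrix",
    "make_split_plan",
    "run_members",
    "filter_outlier_predictions",
]


@dataclass
class SplitPlan:
    """Reproducible description of M subsampling repetitions.

    For ``kfold``, ``fold_assignments[m, i]`` is the fold index of
    compound i in repetition m (every compound is in the test set of
    exactly one fold per repetition; fold sizes differ by at most 1).
    For ``bootstrap``, ``bags[m]`` holds the n training draws (with
    replacement) of member m; its test set is the out-of-bag indices.
    """

    scheme: str
    n: int
    k: int
    n_repetitions: int
    seed: int
    fold_assignments: np.ndarray | None = None
    bags: np.ndarray | None = None

    @property
    def n_fits(self) -> int:
        """Number of model fits the plan implies (M*k for kfold, M for bootstrap)."""
        return self.n_repetitions * (self.k if self.scheme == "kfold" else 1)

    def member_seed(self, m: int) -> int:
        """Child seed of repetition m, independent of execution order."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(m,))
        return int(ss.generate_state(1)[0] % (2**31))


def make_split_plan(
    n: int,
    scheme: str = "kfold",
    k: int = 2,
    n_repetitions: int = 200,
    seed: int = 0,
) -> SplitPlan:
    """Draw M independent shuffled partitions (balanced k-fold) or bags."""
    if n_repetitions < 1:
        raise ValueError("need at least one repetition")
    rng = np.random.default_rng(seed)
    if scheme == "kfold":
        if not 2 <= k <= n:
            raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
        assignments = np.empty((n_repetitions, n), dtype=np.int32)
        for m in range(n_repetitions):
            perm = rng.permutation(n)
            for f, chunk in enumerate(np.array_split(perm, k)):
                assignments[m, chunk] = f
        return SplitPlan(
            scheme="kfold", n=n, k=k, n_repetitions=n_repetitions, seed=seed,
            fold_assignments=assignments,
        )
    if scheme == "bootstrap":
        bags = rng.integers(0, n, size=(n_repetitions, n), dtype=np.int64)
        return SplitPlan(
            scheme="bootstrap", n=n, k=1, n_repetitions=n_repetitions, seed=seed, bags=bags
        )
    raise ValueError(f"unknown subsampling scheme {scheme!r}")


@dataclass
class MemberPredictionMatrix:
    """Out-of-sample member predictions: compounds x members.

    ``values[i, m]`` is compound i's prediction from the repetition-m
    model whose test set contained it (NaN where undefined, e.g. in-bag
    under bootstrap).  ``mask`` marks entries retained after outlier
    filtering; it only ever shrinks.  ``train_ranges[m, f]`` is the
    [y_min, y_max] of the model that produced fold f of member m, and
    ``fold_of[m, i]`` maps each entry back to that model.
    """

    values: np.ndarray
    mask: np.ndarray
    train_ranges: np.ndarray
    scheme: str = "kfold"
    fold_of: np.ndarray | None = None
    errors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_members(self) -> int:
        return self.values.shape[1]

    def retained_counts(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    # -- serialization (wide CSV + sidecar JSON), the inter-stage cache unit --

    def write(self, path: str | os.PathLike, ids: list[str] | None = None) -> None:
        path = os.fspath(path)
        ids = ids if ids is not None else [str(i) for i in range(self.n)]
        df = pd.DataFrame(self.values, columns=[f"member_{m}" for m in range(self.n_members)])
        df.insert(0, "id", ids)
        df.to_csv(path, index=False)
        sidecar = {
            "scheme": self.scheme,
            "train_ranges": self.train_ranges.tolist(),
            "mask": self.mask.astype(int).tolist(),
            "fold_of": None if self.fold_of is None else self.fold_of.tolist(),
            "errors": [list(map(str, e)) for e in self.errors],
        }
        with open(path + ".meta.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def read(cls, path: str | os.PathLike) -> "MemberPredictionMatrix":
        path = os.fspath(path)
        df = pd.read_csv(path, float_precision="round_trip")
        values = df.drop(columns=["id"]).to_numpy(dtype=float)
        with open(path + ".meta.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(
            values=values,
            mask=np.asarray(meta["mask"], dtype=bool),
            train_ranges=np.asarray(meta["train_ranges"], dtype=float),
            scheme=meta["scheme"],
            fold_of=None if meta["fold_of"] is None else np.asarray(meta["fold_of"]),
        )


def run_members(
    X,
    y,
    spec: RegressorSpec,
    plan: SplitPlan,
    feature_kind: str = "learned",
    feature_names: list[str] | None = None,
    continue_on_error: bool = False,
    store_models: bool = False,
    fit_callback=None,
):
    """Fit all members of a plan and collect out-of-sample predictions.

    Per repetition and fold: fit the scaler on the training partition,
    scale both partitions, fit the regressor (child seed derived from
    the plan seed and repetition index), record the training target
    range, and predict the test partition.

    Returns the :class:`MemberPredictionMatrix`; with ``store_models``
    also a list of ``(repetition, fold, scaler, FittedModel, test_idx)``
    tuples.  ``fit_callback`` (if given) is invoked as
    ``fit_callback(repetition, fold)`` before each fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != plan.n or y.shape[0] != plan.n:
        raise ValueError("plan size does not match data")
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    n, M = plan.n, plan.n_repetitions
    values = np.full((n, M), np.nan)
    train_ranges = np.full((M, plan.k, 2), np.nan)
    errors: list = []
    models: list = []

    for m in range(M):
        child_seed = plan.member_seed(m)
        for f in range(plan.k):
            if plan.scheme == "kfold":
                test_idx = np.flatnonzero(plan.fold_assignments[m] == f)
                train_idx = np.flatnonzero(plan.fold_assignments[m] != f)
            else:
                train_idx = plan.bags[m]
                test_idx = np.setdiff1d(np.arange(n), np.unique(train_idx))
            if fit_callback is not None:
                fit_callback(m, f)
            spec_mf = dataclasses.replace(
                spec, seed=int((child_seed + f) % (2**31)), hyperparameters=dict(spec.hyperparameters)
            )
            try:
                train_fm = FeatureMatrix(X[train_idx], feature_kind, names)
                scaler = fit_scaler(train_fm)
                Xtr = apply_scaler(train_fm, scaler).values
                Xte = apply_scaler(FeatureMatrix(X[test_idx], feature_kind, names), scaler).values
                model = fit_adapter(spec_mf, Xtr, y[train_idx])
                values[test_idx, m] = predict_adapter(model, Xte)
                train_ranges[m, f] = (model.y_min, model.y_max)
                if store_models:
                    models.append((m, f, scaler, model, test_idx))
            except Exception as exc:
                errors.append((m, f, exc))
                if not continue_on_error:
                    raise RuntimeError(
                        f"member fit failed at repetition {m}, fold {f}: {exc}"
                    ) from exc

    mask = np.isfinite(values)
    mpm = MemberPredictionMatrix(
        values=values,
        mask=mask,
        train_ranges=train_ranges,
        scheme=plan.scheme,
        fold_of=plan.fold_assignments if plan.scheme == "kfold" else None,
        errors=errors,
    )
    return (mpm, models) if store_models else mpm


def filter_outlier_predictions(
    mpm: MemberPredictionMatrix, factor: float = 2.0
) -> MemberPredictionMatrix:
    """Mask predictions outside ``factor`` times the training output range.

    The acceptance interval is the closed interval of width
    ``factor * w`` centered on the producing model's training range
    [y_min, y_max] (w = y_max - y_min); with factor 2 this is
    [y_min - w/2, y_max + w/2].  A degenerate range (w = 0) retains only
    predictions equal to the training constant.  The mask is monotone:
    already-masked entries are never unmasked.  Compounds losing all
    members are recorded in ``errors`` as flagged.
    """
    mask = mpm.mask.copy()
    for m in range(mpm.n_members):
        if mpm.scheme == "kfold":
            for f in range(mpm.train_ranges.shape[1]):
                idx = np.flatnonzero(mpm.fold_of[m] == f)
                if idx.size == 0:
                    continue
                y_min, y_max = mpm.train_ranges[m, f]
                w = y_max - y_min
                lo, hi = y_min - (factor - 1.0) * w / 2.0, y_max + (factor - 1.0) * w / 2.0
                v = mpm.values[idx, m]
                mask[idx, m] &= (v >= lo) & (v <= hi)
        else:
            y_min, y_max = mpm.train_ranges[m, 0]
            w = y_max - y_min
            lo, hi = y_min - (factor - 1.0) * w / 2.0, y_max + (factor - 1.0) * w / 2.0
            v = mpm.values[:, m]
            with np.errstate(invalid="ignore"):
                mask[:, m] &= (v >= lo) & (v <= hi)
    out = MemberPredictionMatrix(
        values=mpm.values,
        mask=mask,
        train_ranges=mpm.train_ranges,
        scheme=mpm.scheme,
        fold_of=mpm.fold_of,
        errors=list(mpm.errors),
    )
    lost = np.flatnonzero(mask.sum(axis=1) == 0)
    for i in lost:
        out.errors.append(("all_members_masked", int(i), "compound lost to outlier filter"))
    return out
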