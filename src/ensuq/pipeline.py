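"""Configuration-driven orchestration of featurization x technique grids.

A run configuration enumerates datasets (file paths or synthetic
specs), featurizations and modeling techniques; the study runs the
subsampling ensemble for every cell of the Cartesian product, assesses
predictive (R²) and UQ (Spearman ρ) performance, optionally performs
the growing-ensemble saturation analysis per cell, and compares
against single-model baselines with built-in UQ (random-forest tree
variance, MC dropout).  Failed or degenerate cells never abort the
grid — they carry a quality flag in the report instead, since the
success of ensembles must always be validated per setting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .adapters import (
    RegressorSpec,
    fit as fit_adapter,
    internal_uq,
    internal_uq_capability,
)
from .aggregate import EnsembleResult, aggregate
from .data import MolecularDataset, load_dataset
from .featurize import FEATURIZATIONS, FeatureMatrix, apply_scaler, featurize_dataset, fit_scaler
from .growth import fit_saturation, permutation_median_curve, summarize_saturation
from .metrics import diagnose_uncertainty, rank_sums, uq_spearman
from .subsampling import filter_outlier_predictions, make_split_plan, run_members
from .synthetic import SyntheticSpec, make_dataset

__all__ = [
    "RunConfig",
    "enumerate_grid",
    "run_study",
    "run_single_model_baseline",
    "compare_ensemble_vs_baseline",
]

logger = logging.getLogger("ensuq")


@dataclass
class RunConfig:
    """Validated description of a full study grid."""

    datasets: list  # file paths (str) or SyntheticSpec / dict spec sections
    featurizations: list = field(default_factory=lambda: ["precomputed"])
    techniques: list = field(default_factory=lambda: ["rf"])
    scheme: str = "kfold"
    k: int = 2
    n_repetitions: int = 200
    growth: bool = False
    growth_permutations: int = 200
    baselines: bool = False
    baseline_folds: int = 10
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.datasets or not self.featurizations or not self.techniques:
            raise ValueError("configuration error: empty dataset/featurization/technique selection")
        unknown = [f for f in self.featurizations if f not in FEATURIZATIONS]
        if unknown:
            raise ValueError(f"configuration error: unknown featurization(s) {unknown}")
        for d in self.datasets:
            if isinstance(d, str) and not os.path.exists(d):
                raise ValueError(f"configuration error: dataset path {d!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def hash(self) -> str:
        """Stable short hash of the configuration, embedded in outputs."""
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _dataset_name(entry, idx: int) -> str:
    if isinstance(entry, str):
        return os.path.splitext(os.path.basename(entry))[0]
    if isinstance(entry, SyntheticSpec):
        return f"synthetic_{idx}"
    if isinstance(entry, dict):
        return entry.get("name", f"synthetic_{idx}")
    return f"dataset_{idx}"


def enumerate_grid(cfg: RunConfig) -> list[tuple[str, str, str]]:
    """Dataset-major Cartesian product of (dataset, featurization, technique)."""
    return [
        (_dataset_name(d, i), feat, tech)
        for i, d in enumerate(cfg.datasets)
        for feat in cfg.featurizations
        for tech in cfg.techniques
    ]


def _materialize(entry, idx: int, seed: int) -> MolecularDataset:
    if isinstance(entry, MolecularDataset):
        return entry
    if isinstance(entry, str):
        return load_dataset(entry)
    if isinstance(entry, SyntheticSpec):
        return make_dataset(entry)
    if isinstance(entry, dict):
        d = {k: v for k, v in entry.items() if k != "name"}
        d.setdefault("seed", seed + idx)
        return make_dataset(SyntheticSpec(**d))
    raise TypeError(f"cannot interpret dataset entry of type {type(entry).__name__}")


def _cell_seed(base: int, ds_name: str, feat: str, tech: str) -> int:
    h = hashlib.sha256(f"{base}|{ds_name}|{feat}|{tech}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_study(cfg: RunConfig):
    """Execute the full grid; returns (performance table, saturation table).

    The performance table has one row per cell with columns dataset,
    featurization, technique, combination, r2, rho, uq_flag, n and
    seconds.  The saturation table (when ``cfg.growth``) adds one row
    per (cell, metric) with the fitted parameters, the detected size
    m_star and the quality flag.  With ``cfg.outdir`` set, all result
    artifacts are written under ``outdir/<config hash>/``.
    """
    out_rows = []
    sat_rows = []
    outdir = None
    if cfg.outdir:
        outdir = os.path.join(cfg.outdir, cfg.hash())
        os.makedirs(outdir, exist_ok=True)

    for i, entry in enumerate(cfg.datasets):
        ds_name = _dataset_name(entry, i)
        ds = _materialize(entry, i, cfg.seed)
        for feat in cfg.featurizations:
            fm = featurize_dataset(ds, feat)
            for tech in cfg.techniques:
                t0 = time.time()
                seed = _cell_seed(cfg.seed, ds_name, feat, tech)
                spec = RegressorSpec(technique=tech, seed=seed)
                plan = make_split_plan(
                    ds.n, scheme=cfg.scheme, k=cfg.k, n_repetitions=cfg.n_repetitions, seed=seed
                )
                mpm = run_members(
                    fm.values, ds.targets, spec, plan,
                    feature_kind=fm.kind, continue_on_error=True,
                )
                mpm = filter_outlier_predictions(mpm)
                result = aggregate(mpm, ds.targets, ids=ds.identifiers)
                try:
                    rho = result.uq_spearman()
                except ValueError:
                    rho = float("nan")
                row = {
                    "dataset": ds_name,
                    "featurization": feat,
                    "technique": tech,
                    "combination": f"{feat}|{tech}",
                    "r2": result.r2(),
                    "rho": rho,
                    "uq_flag": diagnose_uncertainty(result),
                    "n": ds.n,
                    "seconds": round(time.time() - t0, 2),
                }
                out_rows.append(row)
                logger.info(
                    "cell %s/%s/%s: r2=%.3f rho=%s (%.1fs)",
                    ds_name, feat, tech, row["r2"], row["rho"], row["seconds"],
                )
                if outdir:
                    result.to_frame().to_csv(
                        os.path.join(outdir, f"{ds_name}__{feat}__{tech}__ensemble.csv"),
                        index=False,
                    )
                if cfg.growth:
                    for metric in ("r2", "rho"):
                        curve = permutation_median_curve(
                            mpm, ds.targets, metric=metric,
                            n_permutations=cfg.growth_permutations, seed=seed,
                        )
                        try:
                            sf = fit_saturation(curve)
                            sat_rows.append(
                                {
                                    "dataset": ds_name,
                                    "combination": f"{feat}|{tech}",
                                    "metric": metric,
                                    "a": sf.a, "b": sf.b, "c": sf.c,
                                    "residual": sf.residual,
                                    "m_star": sf.m_star,
                                    "flag": sf.flag,
                                }
                            )
                        except ValueError as exc:
                            sat_rows.append(
                                {
                                    "dataset": ds_name,
                                    "combination": f"{feat}|{tech}",
                                    "metric": metric,
                                    "a": None, "b": None, "c": None,
                                    "residual": None, "m_star": None,
                                    "flag": f"error: {exc}",
                                }
                            )

    perf = pd.DataFrame(out_rows)
    sat = pd.DataFrame(sat_rows)
    if outdir:
        meta = {"config_hash": cfg.hash(), "seed": cfg.seed}
        perf.assign(**meta).to_csv(os.path.join(outdir, "performance.csv"), index=False)
        if not sat.empty:
            sat.assign(**meta).to_csv(os.path.join(outdir, "saturation.csv"), index=False)
        with open(os.path.join(outdir, "config.json"), "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(cfg), fh, default=str, indent=2)
    return perf, sat


def performance_rank_sums(perf: pd.DataFrame, metric: str = "r2") -> pd.DataFrame:
    """Rank-sum table (datasets x combinations) from a study performance table."""
    wide = perf.pivot(index="dataset", columns="combination", values=metric)
    return rank_sums(wide, higher_is_better=True)


def study_saturation_summary(sat: pd.DataFrame, metric: str = "r2") -> pd.DataFrame:
    """Median saturation sizes per combination for one metric."""
    return summarize_saturation(sat[sat["metric"] == metric], group_cols=("combination",))


def run_single_model_baseline(
    X, y, spec: RegressorSpec, folds: int = 10, seed: int = 0,
    feature_kind: str = "learned", n_passes: int = 100,
) -> EnsembleResult:
    """Single 10-fold CV with the technique's built-in UQ measure.

    One out-of-sample prediction and one internal uncertainty per
    compound (tree variance for forests, MC dropout with 100 passes for
    dropout networks), shaped like an :class:`EnsembleResult` so the
    same metrics apply downstream.
    """
    if internal_uq_capability(spec.technique) == "none":
        raise ValueError(
            f"technique {spec.technique!r} has no built-in UQ; baseline unavailable"
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    yhat = np.full(n, np.nan)
    unc = np.full(n, np.nan)
    names = [f"f{j}" for j in range(X.shape[1])]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for f, (train_idx, test_idx) in enumerate(kf.split(X)):
        train_fm = FeatureMatrix(X[train_idx], feature_kind, names)
        scaler = fit_scaler(train_fm)
        Xtr = apply_scaler(train_fm, scaler).values
        Xte = apply_scaler(FeatureMatrix(X[test_idx], feature_kind, names), scaler).values
        spec_f = dataclasses.replace(
            spec, seed=int((seed + f) % (2**31)), hyperparameters=dict(spec.hyperparameters)
        )
        model = fit_adapter(spec_f, Xtr, y[train_idx])
        uq = internal_uq(model, Xte, seed=spec_f.seed, n_passes=n_passes)
        yhat[test_idx] = uq.prediction
        unc[test_idx] = uq.uncertainty
    return EnsembleResult(
        ids=[str(i) for i in range(n)],
        y=y,
        yhat=yhat,
        uncertainty=unc,
        abs_error=np.abs(yhat - y),
        n_retained=np.ones(n, dtype=int),
        n_members=1,
    )


def compare_ensemble_vs_baseline(
    ensemble: dict[str, tuple[float, float]],
    baseline: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Paired per-case comparison of (r2, rho) between two approaches.

    Inputs map case identifiers to (r2, rho).  Returns a table with
    per-case deltas (ensemble minus baseline) plus a summary row of win
    counts and medians of |delta|.
    """
    if set(ensemble) != set(baseline):
        diff = set(ensemble) ^ set(baseline)
        raise ValueError(f"mismatched case sets, differing cases: {sorted(diff)}")
    rows = []
    for case in sorted(ensemble):
        er2, erho = ensemble[case]
        br2, brho = baseline[case]
        rows.append(
            {
                "case": case,
                "delta_r2": er2 - br2,
                "delta_rho": erho - brho,
                "ensemble_wins_r2": er2 > br2,
                "ensemble_wins_rho": erho > brho,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["summary"] = {
        "n_cases": len(df),
        "ensemble_wins_r2": int(df["ensemble_wins_r2"].sum()),
        "ensemble_wins_rho": int(df["ensemble_wins_rho"].sum()),
        "median_abs_delta_r2": float(df["delta_r2"].abs().median()),
        "median_abs_delta_rho": float(df["delta_rho"].abs().median()),
    }
    return df
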