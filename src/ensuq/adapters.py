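"""Uniform regressor contract plus the two built-in UQ baselines.

Any object with ``fit``/``predict`` plugs into the ensembling engine;
five reference techniques ship here (random forest, gradient-boosted
trees, support-vector regression, and shallow/deep dropout networks),
all at library default hyperparameters — no tuning schedule is ever
attached.  Each fitted model records the training target range, which
the prediction-outlier filter needs downstream.

Built-in uncertainty mechanisms:

* random forest — population standard deviation across the individual
  trees (capability flag ``tree_variance``);
* dropout networks — Monte Carlo dropout: repeated stochastic forward
  passes with weights randomly dropped, mean as prediction and
  population standard deviation as uncertainty (``mc_dropout``).

Custom techniques can be registered via :func:`register_technique`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "RegressorSpec",
    "FittedModel",
    "InternalUQResult",
    "TECHNIQUES",
    "internal_uq_capability",
    "register_technique",
    "build_regressor",
    "fit",
    "predict",
    "rf_internal_uq",
    "mc_dropout_uq",
    "internal_uq",
]

TECHNIQUES = ("rf", "xgb", "svm", "snn", "dnn")

#: capability flag per built-in technique
_CAPABILITY = {
    "rf": "tree_variance",
    "xgb": "none",
    "svm": "none",
    "snn": "mc_dropout",
    "dnn": "mc_dropout",
}

_REGISTRY: dict[str, Callable] = {}


@dataclass
class RegressorSpec:
    """A technique at default hyperparameters plus a seed — nothing else."""

    technique: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES and self.technique not in _REGISTRY:
            raise ValueError(f"unrecognized technique {self.technique!r}")


@dataclass
class FittedModel:
    """Opaque fitted-estimator handle plus the training target range."""

    estimator: object
    technique: str
    y_min: float
    y_max: float
    spec: RegressorSpec | None = None


@dataclass
class InternalUQResult:
    """Per-compound prediction and built-in uncertainty (always >= 0)."""

    prediction: np.ndarray
    uncertainty: np.ndarray


def register_technique(name: str, factory: Callable, capability: str = "none") -> None:
    """Register a custom adapter: ``factory(hyperparameters, seed) -> estimator``."""
    _REGISTRY[name] = factory
    _CAPABILITY[name] = capability


def internal_uq_capability(technique: str) -> str:
    return _CAPABILITY.get(technique, "none")


def build_regressor(spec: RegressorSpec):
    """Instantiate the unfitted estimator a spec describes."""
    hp = dict(spec.hyperparameters)
    if spec.technique in _REGISTRY:
        return _REGISTRY[spec.technique](hp, spec.seed)
    if spec.technique == "rf":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(random_state=spec.seed, **hp)
    if spec.technique == "xgb":
        from xgboost import XGBRegressor

        hp.setdefault("n_jobs", 1)
        hp.setdefault("verbosity", 0)
        return XGBRegressor(random_state=spec.seed, **hp)
    if spec.technique == "svm":
        from sklearn.svm import SVR

        return SVR(**hp)
    if spec.technique in ("snn", "dnn"):
        from .mlp import DropoutMLPRegressor

        hp.setdefault("hidden_layer_sizes", (128,) if spec.technique == "snn" else (256, 128, 16))
        hp.setdefault("dropout_rate", 0.2)
        hp.setdefault("epochs", 1000)
        return DropoutMLPRegressor(random_state=spec.seed, **hp)
    raise ValueError(f"unrecognized technique {spec.technique!r}")


def fit(spec: RegressorSpec, X, y) -> FittedModel:
    """Fit a spec on (X, y); the training target range is recorded."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("training targets must be finite")
    est = build_regressor(spec)
    try:
        est.fit(X, y)
    except Exception as exc:  # surface technique context with the failure
        raise RuntimeError(f"fitting technique {spec.technique!r} failed: {exc}") from exc
    return FittedModel(
        estimator=est,
        technique=spec.technique,
        y_min=float(np.min(y)),
        y_max=float(np.max(y)),
        spec=spec,
    )


def predict(model: FittedModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0)
    n_in = getattr(model.estimator, "n_features_in_", None)
    if n_in is not None and X.shape[1] != n_in:
        raise ValueError(f"feature count mismatch: model expects {n_in}, got {X.shape[1]}")
    return np.asarray(model.estimator.predict(X), dtype=float)


def rf_internal_uq(model: FittedModel, X) -> InternalUQResult:
    """Tree-level mean and population std of a fitted random forest."""
    if model.technique != "rf":
        raise ValueError("tree-variance UQ requires a random-forest model")
    trees = getattr(model.estimator, "estimators_", None)
    if trees is None:
        raise ValueError("model has no per-tree sub-estimators")
    X = np.asarray(X, dtype=float)
    per_tree = np.stack([np.asarray(t.predict(X), dtype=float) for t in trees])
    return InternalUQResult(
        prediction=per_tree.mean(axis=0),
        uncertainty=per_tree.std(axis=0),  # population std over trees
    )


def mc_dropout_uq(
    model: FittedModel,
    X,
    n_passes: int = 100,
    dropout_rate: float | None = None,
    seed: int = 0,
) -> InternalUQResult:
    """Monte Carlo dropout: mean and population std over stochastic passes."""
    if n_passes < 2:
        raise ValueError("MC dropout needs n_passes >= 2 (std undefined otherwise)")
    est = model.estimator
    if not hasattr(est, "predict_stochastic"):
        raise ValueError("model does not support stochastic dropout passes")
    rng = np.random.default_rng(seed)
    passes = est.predict_stochastic(np.asarray(X, dtype=float), n_passes, rng, dropout_rate)
    return InternalUQResult(
        prediction=passes.mean(axis=0),
        uncertainty=passes.std(axis=0),
    )


def internal_uq(model: FittedModel, X, seed: int = 0, n_passes: int = 100) -> InternalUQResult:
    """Dispatch to the technique's built-in UQ mechanism."""
    cap = internal_uq_capability(model.technique)
    if cap == "tree_variance":
        return rf_internal_uq(model, X)
    if cap == "mc_dropout":
        return mc_dropout_uq(model, X, n_passes=n_passes, seed=seed)
    raise ValueError(f"technique {model.technique!r} has no built-in UQ mechanism")
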