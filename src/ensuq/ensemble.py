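"""The subsampling-ensemble regressor, scikit-learn style.

:class:`SubsamplingEnsembleRegressor` wraps the whole pipeline —
split planning, per-partition feature scaling, member fitting,
prediction-outlier filtering and mean/std aggregation — behind the
familiar ``fit``/``predict`` contract, so it composes with sklearn
pipelines and model selection.  Fitting stores the out-of-sample member
prediction matrix (each training compound predicted once per
repetition by the fold model that did not see it), from which the
cross-validated performance metrics and the growing-ensemble analysis
are derived.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .adapters import RegressorSpec, predict as predict_adapter
from .aggregate import EnsembleResult, aggregate
from .subsampling import filter_outlier_predictions, make_split_plan, run_members

__all__ = ["SubsamplingEnsembleRegressor"]


class SubsamplingEnsembleRegressor(RegressorMixin, BaseEstimator):
    """Ensemble of repeated k-fold CV members with built-in UQ.

    Parameters
    ----------
    technique : str
        Member regressor: ``rf``, ``xgb``, ``svm``, ``snn``, ``dnn`` or a
        registered custom technique (default hyperparameters only).
    hyperparameters : dict or None
        Passed through to the member regressor.
    k : int
        Folds per repetition; 2 balances member diversity against the
        training-set size of each fold model.
    n_repetitions : int
        Ensemble size M; the reference configuration uses 200 (hence
        400 fold models at k=2).
    scheme : {"kfold", "bootstrap"}
        Subsampling scheme for member generation.
    feature_kind : str
        Featurization kind; decides the split-wise scaler (per-sample
        unit norm for count kinds, train-statistics standardization
        otherwise).
    filter_outliers : bool
        Mask out-of-sample predictions outside ``outlier_factor`` times
        the producing model's training target range.
    population_std : bool
        Divisor M (population) in the uncertainty; the printed-form
        definition.  Set False for the sample variant.
    random_state : int
        Seed for the split plan and member child seeds.

    Attributes
    ----------
    plan_ : SplitPlan
    member_matrix_ : MemberPredictionMatrix
        Out-of-sample member predictions after optional filtering.
    oos_result_ : EnsembleResult
        Aggregated out-of-sample prediction/uncertainty per training
        compound.
    r2_, uq_spearman_ : float
        Cross-validated predictive and UQ performance.
    """

    def __init__(
        self,
        technique: str = "rf",
        hyperparameters: dict | None = None,
        k: int = 2,
        n_repetitions: int = 200,
        scheme: str = "kfold",
        feature_kind: str = "learned",
        filter_outliers: bool = True,
        outlier_factor: float = 2.0,
        population_std: bool = True,
        continue_on_error: bool = False,
        store_models: bool = True,
        random_state: int = 0,
    ):
        self.technique = technique
        self.hyperparameters = hyperparameters
        self.k = k
        self.n_repetitions = n_repetitions
        self.scheme = scheme
        self.feature_kind = feature_kind
        self.filter_outliers = filter_outliers
        self.outlier_factor = outlier_factor
        self.population_std = population_std
        self.continue_on_error = continue_on_error
        self.store_models = store_models
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        spec = RegressorSpec(
            technique=self.technique,
            hyperparameters=dict(self.hyperparameters or {}),
            seed=int(self.random_state),
        )
        self.plan_ = make_split_plan(
            n=X.shape[0],
            scheme=self.scheme,
            k=self.k,
            n_repetitions=self.n_repetitions,
            seed=int(self.random_state),
        )
        out = run_members(
            X,
            y,
            spec,
            self.plan_,
            feature_kind=self.feature_kind,
            continue_on_error=self.continue_on_error,
            store_models=self.store_models,
        )
        if self.store_models:
            mpm, self.models_ = out
        else:
            mpm, self.models_ = out, []
        if self.filter_outliers:
            mpm = filter_outlier_predictions(mpm, factor=self.outlier_factor)
        self.member_matrix_ = mpm
        self.oos_result_ = aggregate(mpm, y, population=self.population_std)
        self.r2_ = self.oos_result_.r2()
        try:
            self.uq_spearman_ = self.oos_result_.uq_spearman()
        except ValueError:
            self.uq_spearman_ = float("nan")
        self.n_features_in_ = X.shape[1]
        return self

    def _member_predictions(self, X):
        """(n, M) member predictions on new data.

        A member's prediction for an unseen compound is the mean of its
        k fold models (each applying its own training-partition scaler).
        """
        check_is_fitted(self, "member_matrix_")
        if not self.models_:
            raise RuntimeError("models were not stored; refit with store_models=True")
        X = check_array(X)
        M = self.plan_.n_repetitions
        sums = np.zeros((X.shape[0], M))
        counts = np.zeros(M)
        from .featurize import FeatureMatrix, apply_scaler

        names = [f"f{j}" for j in range(X.shape[1])]
        for m, _f, scaler, model, _test_idx in self.models_:
            Xs = apply_scaler(FeatureMatrix(X, self.feature_kind, names), scaler).values
            sums[:, m] += predict_adapter(model, Xs)
            counts[m] += 1
        return sums / counts[None, :]

    def predict(self, X):
        """Ensemble mean over all members for new compounds."""
        return self._member_predictions(X).mean(axis=1)

    def predict_with_uncertainty(self, X):
        """(mean, population std) over member predictions for new compounds."""
        preds = self._member_predictions(X)
        return preds.mean(axis=1), preds.std(axis=1)

    def oos_ensemble_result(self) -> EnsembleResult:
        check_is_fitted(self, "oos_result_")
        return self.oos_result_
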