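"""Molecular featurizations and split-wise feature scaling.

Three classical featurizations are provided:

* **MACCS counts** — the 167-position MACCS substructure key set with
  occurrence counts instead of bits (position 0 is unused by convention;
  keys without a SMARTS definition stay 0).
* **Morgan counts** — hashed circular-substructure occurrence counts
  (extended-connectivity style), radius 3, 2048 bins by default.
* **Physicochemical descriptors** — the toolkit's full default descriptor
  collection; realized descriptor names are recorded rather than a fixed
  length asserted, because the set is toolkit-version dependent.

Scaling is always fitted on the training partition of a split only:
count-based featurizations are normalized per sample to unit Euclidean
norm (so all entries of a non-negative count vector land in [0, 1]);
continuous featurizations are standardized to column mean 0 / std 1
using training statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FeatureMatrix",
    "maccs_counts",
    "morgan_counts",
    "physchem_descriptors",
    "featurize_dataset",
    "PerSampleNormalizer",
    "TrainStandardizer",
    "fit_scaler",
    "apply_scaler",
    "scaler_for_kind",
    "COUNT_KINDS",
    "FEATURIZATIONS",
]

COUNT_KINDS = ("substructure_counts", "circular_counts")
FEATURIZATIONS = ("maccs", "morgan_counts", "physchem", "precomputed")


@dataclass
class FeatureMatrix:
    """A featurized compound set: (n, p) values plus kind and names."""

    values: np.ndarray
    kind: str
    feature_names: list[str]
    flagged: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match number of columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def _mols_from_smiles(smiles_list):
    from rdkit import Chem

    mols = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is None:
            raise ValueError(f"unparsable SMILES at index {i}: {smi!r}")
        mols.append(mol)
    return mols


_MACCS_PATTERNS = None


def _maccs_patterns():
    """Compiled (position, SMARTS query) pairs of the MACCS key set."""
    global _MACCS_PATTERNS
    if _MACCS_PATTERNS is None:
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys

        pats = []
        for pos, (smarts, _threshold) in MACCSkeys.smartsPatts.items():
            if smarts == "?":
                continue
            query = Chem.MolFromSmarts(smarts)
            if query is not None:
                pats.append((pos, query))
        _MACCS_PATTERNS = pats
    return _MACCS_PATTERNS


def maccs_counts(smiles_list) -> FeatureMatrix:
    """MACCS substructure keys with occurrence counts summed up."""
    mols = _mols_from_smiles(smiles_list)
    n_pos = 167
    X = np.zeros((len(mols), n_pos), dtype=float)
    pats = _maccs_patterns()
    for i, mol in enumerate(mols):
        for pos, query in pats:
            X[i, pos] = len(mol.GetSubstructMatches(query, uniquify=True))
    names = [f"maccs_{j}" for j in range(n_pos)]
    return FeatureMatrix(values=X, kind="substructure_counts", feature_names=names)


def morgan_counts(smiles_list, radius: int = 3, n_bins: int = 2048) -> FeatureMatrix:
    """Hashed circular-substructure (Morgan) occurrence counts."""
    from rdkit.Chem import rdFingerprintGenerator

    mols = _mols_from_smiles(smiles_list)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bins)
    X = np.zeros((len(mols), n_bins), dtype=float)
    for i, mol in enumerate(mols):
        fp = gen.GetCountFingerprint(mol)
        for bit, count in fp.GetNonzeroElements().items():
            X[i, bit] = count
    names = [f"mfc_{j}" for j in range(n_bins)]
    return FeatureMatrix(values=X, kind="circular_counts", feature_names=names)


def physchem_descriptors(smiles_list) -> FeatureMatrix:
    """Full default physicochemical/fragment descriptor vector per compound.

    Descriptors evaluating to a non-finite value are recorded in
    ``flagged`` (compound index -> descriptor names); values are kept
    as computed and not clipped — outlier handling happens on the
    prediction side.
    """
    from rdkit.Chem import Descriptors

    mols = _mols_from_smiles(smiles_list)
    names: list[str] | None = None
    rows = []
    flagged: dict[int, list[str]] = {}
    for i, mol in enumerate(mols):
        d = Descriptors.CalcMolDescriptors(mol)
        if names is None:
            names = list(d.keys())
        row = np.array([float(d[k]) for k in names], dtype=float)
        bad = [names[j] for j in np.flatnonzero(~np.isfinite(row))]
        if bad:
            flagged[i] = bad
            row[~np.isfinite(row)] = 0.0
        rows.append(row)
    return FeatureMatrix(
        values=np.vstack(rows), kind="physchem", feature_names=list(names or []), flagged=flagged
    )


def featurize_dataset(ds, featurization: str) -> FeatureMatrix:
    """Apply a named featurization to a dataset (or pass through precomputed)."""
    if featurization == "precomputed":
        if ds.features is None:
            raise ValueError("dataset carries no precomputed feature matrix")
        return FeatureMatrix(
            values=ds.features,
            kind=ds.feature_kind or "learned",
            feature_names=ds.feature_names or [f"f{j}" for j in range(ds.features.shape[1])],
        )
    if any(s == "" for s in ds.smiles):
        raise ValueError("dataset has empty SMILES; structure featurization unavailable")
    if featurization == "maccs":
        return maccs_counts(ds.smiles)
    if featurization == "morgan_counts":
        return morgan_counts(ds.smiles)
    if featurization == "physchem":
        return physchem_descriptors(ds.smiles)
    raise ValueError(f"unknown featurization {featurization!r}")


class PerSampleNormalizer(TransformerMixin, BaseEstimator):
    """Scale each row to unit Euclidean norm; all-zero rows pass unchanged.

    Stateless by construction — fitting only records the expected column
    count, so no information from any partition leaks into another.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature count mismatch: fitted on {self.n_features_in_}, got {X.shape[1]}"
            )
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return X / norms


class TrainStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise (x - mean) / std with training-partition statistics.

    The population standard deviation is used.  Zero-variance columns get
    a divisor of 1 (so they pass through centered at 0) and are listed in
    ``flagged_columns_`` instead of being dropped mid-split.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)  # population (ddof=0)
        self.flagged_columns_ = np.flatnonzero(std == 0.0)
        std = np.where(std == 0.0, 1.0, std)
        self.scale_ = std
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature count mismatch: fitted on {self.n_features_in_}, got {X.shape[1]}"
            )
        return (X - self.mean_) / self.scale_


def scaler_for_kind(kind: str):
    """Unfitted scaler appropriate for a featurization kind."""
    return PerSampleNormalizer() if kind in COUNT_KINDS else TrainStandardizer()


def fit_scaler(train_features: FeatureMatrix):
    """Fit the kind-appropriate scaler on a training-partition matrix."""
    scaler = scaler_for_kind(train_features.kind)
    scaler.fit(train_features.values)
    scaler.kind_ = train_features.kind
    return scaler


def apply_scaler(features: FeatureMatrix, scaler) -> FeatureMatrix:
    """Apply a fitted scaler; the kind and column count must match."""
    fitted_kind = getattr(scaler, "kind_", None)
    if fitted_kind is not None and fitted_kind != features.kind:
        raise ValueError(f"scaler fitted on kind {fitted_kind!r}, got {features.kind!r}")
    return FeatureMatrix(
        values=scaler.transform(features.values),
        kind=features.kind,
        feature_names=features.feature_names,
        flagged=dict(features.flagged),
    )
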