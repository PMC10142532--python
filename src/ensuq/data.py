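"""Reading, curation and serialization of compound-target tables.

Input tables are CSV/TSV files with a header; the column mapping
(``id_col``, ``smiles_col``, ``target_col``) is configurable.  Learned
representations (e.g. a precomputed 512-dimensional CDDD matrix) are
ingested through a separate feature-matrix file aligned row-by-row with
the compound table; such records may carry an empty SMILES field, in
which case structure-based featurization is unavailable for them.

Curation implements the duplicate policy used throughout: multiple
measurements of the same structure are collapsed to one record whose
target is the arithmetic mean of the group and whose identifier is the
first one seen in input order.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "MolecularDataset",
    "load_dataset",
    "canonical_smiles",
    "deduplicate_and_average",
    "write_results",
    "read_ensemble_result",
    "read_saturation_fit",
    "read_curve",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: identifier, SMILES and a (log-scale) target value."""

    identifier: str
    smiles: str
    target: float


@dataclass
class MolecularDataset:
    """An ordered collection of compounds, optionally featurized.

    Attributes
    ----------
    identifiers, smiles : lists of length n
    targets : float array of length n
    features : optional (n, p) matrix once a featurization was computed
        or a precomputed representation was loaded.
    feature_names : column names of ``features``.
    feature_kind : one of ``substructure_counts``, ``circular_counts``,
        ``physchem``, ``learned`` (set by the featurize module or loader).
    extras : free-form per-dataset metadata (e.g. synthetic ground truth).
    """

    identifiers: list[str]
    smiles: list[str]
    targets: np.ndarray
    features: np.ndarray | None = None
    feature_names: list[str] | None = None
    feature_kind: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if not (len(self.identifiers) == len(self.smiles) == len(self.targets)):
            raise ValueError("identifiers, smiles and targets must have equal length")
        if self.targets.size and not np.all(np.isfinite(self.targets)):
            raise ValueError("targets must be finite")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape[0] != len(self.targets):
                raise ValueError("feature matrix row count does not match record count")

    @property
    def n(self) -> int:
        return len(self.targets)

    @property
    def records(self) -> list[CompoundRecord]:
        return [
            CompoundRecord(i, s, float(t))
            for i, s, t in zip(self.identifiers, self.smiles, self.targets)
        ]

    def check_splittable(self, k: int) -> None:
        """Require n >= 2k so that every fold of a k-fold plan can train."""
        if self.n < 2 * k:
            raise ValueError(f"dataset of size {self.n} too small for k={k} cross-validation")


def load_dataset(
    path: str | os.PathLike,
    id_col: str = "id",
    smiles_col: str | None = "smiles",
    target_col: str = "target",
    features_path: str | os.PathLike | None = None,
    sep: str | None = None,
) -> MolecularDataset:
    """Read a compound table (CSV/TSV) into a :class:`MolecularDataset`.

    ``sep`` is inferred from the file extension (``.tsv`` -> tab) when not
    given.  If ``features_path`` is provided the file is read as an aligned
    numeric matrix (one row per compound, header of feature names) and a
    missing ``smiles_col`` is tolerated (records then carry empty SMILES).
    """
    path = os.fspath(path)
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no records in {path}") from None
    if df.empty:
        raise ValueError(f"no records in {path}")

    required = [id_col, target_col]
    if features_path is None:
        if smiles_col is None:
            raise ValueError("smiles_col is required when no feature matrix is supplied")
        required.append(smiles_col)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"configuration error: column(s) {missing} not found in {path}")

    raw = df[target_col]
    targets = pd.to_numeric(raw, errors="coerce")
    bad = targets.isna() & raw.notna() | raw.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unparsable target value in row {row} of {path}: {raw.iloc[row]!r}")

    if smiles_col is not None and smiles_col in df.columns:
        smiles = df[smiles_col].fillna("").astype(str).tolist()
    else:
        smiles = [""] * len(df)
    if features_path is None and any(s == "" for s in smiles):
        raise ValueError("empty SMILES encountered and no feature matrix supplied")

    ds = MolecularDataset(
        identifiers=df[id_col].astype(str).tolist(),
        smiles=smiles,
        targets=targets.to_numpy(dtype=float),
    )
    if features_path is not None:
        fdf = pd.read_csv(os.fspath(features_path), sep=sep)
        if len(fdf) != ds.n:
            raise ValueError(
                f"feature matrix has {len(fdf)} rows but table has {ds.n} records"
            )
        ds.features = fdf.to_numpy(dtype=float)
        ds.feature_names = list(fdf.columns)
        ds.feature_kind = "learned"
    return ds


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES via RDKit; the stable structure key used for dedup."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def deduplicate_and_average(ds: MolecularDataset) -> MolecularDataset:
    """Collapse duplicate structures: mean target, first identifier kept.

    Structure identity is the canonical SMILES string.  Records with an
    empty SMILES field (precomputed-feature path) are treated as unique.
    Output order is the order of first appearance, so the operation is
    idempotent and preserves the weighted sum of targets.
    """
    keys: list[object] = []
    for i, s in enumerate(ds.smiles):
        keys.append(canonical_smiles(s) if s else ("__row__", i))

    first_index: dict[object, int] = {}
    groups: dict[object, list[int]] = {}
    order: list[object] = []
    for i, key in enumerate(keys):
        if key not in groups:
            groups[key] = []
            first_index[key] = i
            order.append(key)
        groups[key].append(i)

    identifiers, smiles, targets = [], [], []
    feat_rows = []
    for key in order:
        idx = groups[key]
        i0 = first_index[key]
        identifiers.append(ds.identifiers[i0])
        smiles.append(ds.smiles[i0])
        targets.append(float(np.mean(ds.targets[idx])))
        feat_rows.append(i0)
    out = MolecularDataset(
        identifiers=identifiers,
        smiles=smiles,
        targets=np.asarray(targets),
        features=None if ds.features is None else ds.features[feat_rows],
        feature_names=ds.feature_names,
        feature_kind=ds.feature_kind,
        extras=dict(ds.extras),
    )
    return out


# -- result serialization -----------------------------------------------------

def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(result, path: str | os.PathLike, fmt: str | None = None) -> str:
    """Write a result object to CSV or JSON; values round-trip exactly.

    Floats are serialized through Python's shortest-round-trip repr, so
    reading the file back reconstructs the stored values bit-for-bit.
    """
    from .aggregate import EnsembleResult
    from .growth import CumulativeCurve, SaturationFit

    path = os.fspath(path)
    if fmt is None:
        fmt = "json" if path.endswith(".json") else "csv"
    try:
        if isinstance(result, EnsembleResult):
            result.to_frame().to_csv(path, index=False)
        elif isinstance(result, CumulativeCurve):
            result.to_frame().to_csv(path, index=False)
        elif isinstance(result, SaturationFit):
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(dataclasses.asdict(result), fh, default=_json_default, indent=2)
        elif isinstance(result, pd.DataFrame):
            if fmt == "json":
                result.to_json(path, orient="table", index=False)
            else:
                result.to_csv(path, index=False)
        elif isinstance(result, dict):
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(result, fh, default=_json_default, indent=2)
        else:
            raise TypeError(f"cannot serialize result of type {type(result).__name__}")
    except OSError as exc:
        raise OSError(f"failed writing results to {path}: {exc}") from exc
    return path


def read_ensemble_result(path: str | os.PathLike):
    from .aggregate import EnsembleResult

    df = pd.read_csv(os.fspath(path), float_precision="round_trip")
    return EnsembleResult(
        ids=df["id"].astype(str).tolist(),
        y=df["y"].to_numpy(),
        yhat=df["yhat"].to_numpy(),
        uncertainty=df["uncertainty"].to_numpy(),
        abs_error=df["abs_error"].to_numpy(),
        n_retained=df["n_members_retained"].to_numpy(dtype=int),
        n_members=int(df.attrs.get("n_members", df["n_members_retained"].max())),
    )


def read_saturation_fit(path: str | os.PathLike):
    from .growth import SaturationFit

    with open(os.fspath(path), encoding="utf-8") as fh:
        d = json.load(fh)
    return SaturationFit(**d)


def read_curve(path: str | os.PathLike):
    from .growth import CumulativeCurve

    df = pd.read_csv(os.fspath(path), float_precision="round_trip")
    return CumulativeCurve(
        metric=str(df["metric"].iloc[0]),
        sizes=df["size"].to_numpy(dtype=int),
        values=df["value"].to_numpy(dtype=float),
        variant=str(df["variant"].iloc[0]),
    )
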