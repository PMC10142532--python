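"""Synthetic data with known ground truth for every pipeline stage.

Three generators, all pure functions of their parameters and seed:

* :func:`make_dataset` — regression datasets emulating featurized
  compound collections: a low-rank latent structure (X = Z W), a smooth
  nonlinear latent-to-target map (sum of sigmoids), heteroscedastic
  Gaussian noise whose per-compound scale grows with a stored difficulty
  score, and an optional fraction of duplicated records (jittered
  targets) to exercise the deduplication path.
* :func:`make_member_matrix` — member prediction matrices synthesized
  directly as y_i + b_i + eta_im with per-compound bias b_i and member
  noise eta_im ~ N(0, tau_i); tau and b are returned as ground truth, so
  the true ensemble uncertainty and error structure are known.  Setting
  a large bias with tiny tau reproduces the regime where ensemble
  uncertainty collapses while errors stay large.
* :func:`make_curve` — saturation-law curves with optional Gaussian
  noise, for exercising the Michaelis–Menten fitting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MolecularDataset
from .growth import CumulativeCurve, michaelis_menten
from .subsampling import MemberPredictionMatrix

__all__ = ["SyntheticSpec", "make_dataset", "make_member_matrix", "make_curve"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic regression dataset.

    Defaults emulate a mid-sized assay dataset: 300 compounds, 64
    observed features spanned by a rank-4 latent space, noise scale 0.3
    (log-unit targets with spread of order 1), homoscedastic unless the
    heteroscedasticity coefficient h is raised, and no duplicates.
    """

    n: int = 300
    p: int = 64
    r: int = 4
    sigma: float = 0.3
    h: float = 0.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r > self.p:
            raise ValueError("latent rank r must not exceed feature count p")
        if not (0.0 <= self.duplicate_fraction < 1.0):
            raise ValueError("duplicate_fraction must be in [0, 1)")
        if self.sigma < 0 or self.h < 0:
            raise ValueError("noise parameters must be non-negative")


def _synthetic_smiles(i: int) -> str:
    """Unique, RDKit-parsable linear-alkane SMILES for compound i."""
    return "C" * (i + 1)


def make_dataset(spec: SyntheticSpec) -> MolecularDataset:
    """Generate a featurized dataset with stored ground truth.

    ``extras`` carries ``difficulty`` (per-compound score s >= 0, the
    squared normalized latent norm), ``noise_sd`` (the realized
    per-compound noise scale sigma * (1 + h * s)), and ``y_clean`` (the
    noise-free targets).  Duplicated rows share the SMILES of their
    original and get a small target jitter.
    """
    if spec.n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(spec.seed)
    Z = rng.standard_normal((spec.n, spec.r))
    W = rng.standard_normal((spec.r, spec.p)) / np.sqrt(spec.r)
    X = Z @ W
    # smooth nonlinear map: sum of sigmoids of the latent coordinates
    g = (4.0 / np.sqrt(spec.r)) * (1.0 / (1.0 + np.exp(-1.5 * Z))).sum(axis=1)
    # difficulty: squared normalized latent norm — heavy-tailed, so a large
    # h separates easy from hard compounds clearly
    s = ((Z**2).sum(axis=1) / spec.r) ** 2
    noise_sd = spec.sigma * (1.0 + spec.h * s)
    y = g + rng.normal(0.0, 1.0, spec.n) * noise_sd

    identifiers = [f"SYN-{i:05d}" for i in range(spec.n)]
    smiles = [_synthetic_smiles(i) for i in range(spec.n)]
    features = X
    targets = y
    difficulty = s.copy()
    sds = noise_sd.copy()
    y_clean = g.copy()

    n_dup = int(np.floor(spec.duplicate_fraction * spec.n))
    if n_dup:
        dup_idx = rng.choice(spec.n, size=n_dup, replace=False)
        jitter = rng.normal(0.0, 0.05, n_dup)
        identifiers = identifiers + [f"SYN-{i:05d}-dup" for i in dup_idx]
        smiles = smiles + [smiles[i] for i in dup_idx]
        features = np.vstack([features, X[dup_idx]])
        targets = np.concatenate([targets, y[dup_idx] + jitter])
        difficulty = np.concatenate([difficulty, s[dup_idx]])
        sds = np.concatenate([sds, noise_sd[dup_idx]])
        y_clean = np.concatenate([y_clean, g[dup_idx]])

    return MolecularDataset(
        identifiers=identifiers,
        smiles=smiles,
        targets=targets,
        features=features,
        feature_names=[f"x{j}" for j in range(spec.p)],
        feature_kind="learned",
        extras={
            "difficulty": difficulty,
            "noise_sd": sds,
            "y_clean": y_clean,
            "spec": spec,
        },
    )


def make_member_matrix(
    n: int,
    M: int,
    tau=(0.1, 1.0),
    bias_sd: float = 0.0,
    y_sd: float = 1.0,
    seed: int = 0,
):
    """Directly synthesize member predictions with known error structure.

    Member m's prediction for compound i is y_i + b_i + eta_im with
    b_i ~ N(0, bias_sd) and eta_im ~ N(0, tau_i).  ``tau`` is either a
    scalar (constant member spread — no rank signal for UQ) or a
    (low, high) pair sampled log-uniformly per compound.  Training
    ranges are set wide enough that the outlier filter is a no-op.

    Returns ``(mpm, y, truth)`` with ``truth = {"tau", "bias"}``.
    """
    if M < 2:
        raise ValueError("need M >= 2 members")
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, y_sd, n)
    if np.isscalar(tau):
        tau_i = np.full(n, float(tau))
    else:
        lo, hi = float(tau[0]), float(tau[1])
        tau_i = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    b_i = rng.normal(0.0, bias_sd, n) if bias_sd > 0 else np.zeros(n)
    values = y[:, None] + b_i[:, None] + rng.standard_normal((n, M)) * tau_i[:, None]

    lo_r = float(values.min() - 10.0 * (tau_i.max() + 1.0))
    hi_r = float(values.max() + 10.0 * (tau_i.max() + 1.0))
    mpm = MemberPredictionMatrix(
        values=values,
        mask=np.ones((n, M), dtype=bool),
        train_ranges=np.tile(np.array([[lo_r, hi_r]]), (M, 1, 1)),
        scheme="synthetic",
        fold_of=None,
    )
    return mpm, y, {"tau": tau_i, "bias": b_i}


def make_curve(
    a: float,
    b: float,
    c: float,
    M: int,
    sigma: float = 0.0,
    seed: int = 0,
    start: int = 1,
    metric: str = "r2",
) -> CumulativeCurve:
    """Saturation-law curve sampled at integer sizes, plus optional noise."""
    if c <= 0:
        raise ValueError("half-saturation size c must be positive")
    if M < 4:
        raise ValueError("need M >= 4 points")
    rng = np.random.default_rng(seed)
    sizes = np.arange(start, M + 1)
    values = michaelis_menten(sizes.astype(float), a, b, c)
    if sigma > 0:
        values = values + rng.normal(0.0, sigma, sizes.size)
    return CumulativeCurve(
        metric=metric,
        sizes=sizes,
        values=values,
        variant="permutation_median",
        extras={"a": a, "b": b, "c": c, "sigma": sigma},
    )
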