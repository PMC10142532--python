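# Methods

## The model

`ensuq` quantifies the uncertainty of regression predictions on molecular data
with *subsampling ensembles*. An ensemble of M members is built by running M
independent k-fold cross-validation repetitions over one dataset; one member is
one full repetition, whose k fold models jointly provide exactly one
out-of-sample prediction per compound. The ensemble's point estimate for a
compound is the arithmetic mean of its member predictions,

    ŷ̄ = (1/M) Σᵢ ŷᵢ ,

and its uncertainty is the population standard deviation of the members,

    û = √( (1/M) Σᵢ (ŷᵢ − ŷ̄)² ) .

The divisor is M, not M−1 (a sample-std variant is available via
`population=False` / `population_std=False`). The spread across members
estimates the epistemic component of the prediction uncertainty: compounds on
which independently subsampled models disagree are compounds the data do not
pin down.

Defaults follow the reference configuration: k = 2 (maximal member diversity at
acceptable per-model training size; M·k = 400 fold models at M = 200) and
M = 200 repetitions. A bootstrap scheme (one model per member, out-of-bag
evaluation; undefined in-bag entries stay masked) is available as an
alternative subsampling strategy.

### Prediction-outlier elimination

Some featurizations contain a few extreme descriptor values; non-interpolating
learners (networks) can then produce wildly erroneous predictions when such
compounds fall into the test fold. Member predictions outside `factor` (default
2) times the producing model's training target range are therefore eliminated
before aggregation. The acceptance region is formalized as the closed interval
of width `factor·w` centered on the training range [y_min, y_max]
(w = y_max − y_min), i.e. [y_min − w/2, y_max + w/2] at factor 2. The phrase
"two times the training output range" admits other geometries (e.g.
[y_min − w, y_max + w]); the centered reading is symmetric and reduces to the
training range at factor 1, and the factor is configurable. Elimination removes
predictions, never compounds: the per-compound divisor M becomes the retained
count, a compound with < 2 retained members has an undefined uncertainty, and a
fully masked compound is reported missing and flagged.

## Quality assessment

Predictive performance is the cross-validated coefficient of determination
R² = 1 − Σ(y−ŷ̄)²/Σ(y−ȳ)² (negative when errors exceed the total sum of
squares; undefined for constant observed values). UQ performance is Spearman's
ρ between û and the absolute error |ŷ̄ − y| — Pearson's correlation on average
ranks (standard tie convention; the source material does not state its own) —
measuring how well the uncertainty *ranks* predictions by error magnitude.
Compounds with a missing uncertainty are excluded pairwise, with the evaluable
count reported; all-tied uncertainties make ρ undefined (NaN plus a
diagnostic), which is itself an informative failure mode.

Combination grids (featurization × technique over several datasets) are
compared by rank sums: within each dataset the best combination receives rank
1, ties get average ranks, and ranks are summed over datasets. Without ties the
grand total over C combinations and D datasets is D·C·(C+1)/2, a conservation
property used as a self-check.

## Growing-ensemble analysis

Cumulative member curves track R² (sizes 1..M) and ρ (sizes 2..M) as members
are accumulated in some order. To remove the ordering bias, the member order is
permuted `n_permutations = 200` times and the per-size median over the permuted
curves is taken. (The source material alternates between "average" and "median
curve"; the median is the default here for robustness, the mean is available
via `center="mean"`.) The cumulative mean/std are computed with a running,
row-centered formulation, so a degenerate matrix of identical members yields an
exactly-zero spread rather than floating-point noise.

A Michaelis–Menten-type law with an additive offset,

    f(m) = a + b·m/(c + m),    c > 0,

is least-squares fitted through the median curve (`scipy.optimize.curve_fit`,
initialization a = first value, b = last − first, c = M/10). The offset is
required because cumulative curves start at a nonzero single-model performance.
The saturation size m* is the first integer step of the *fitted* curve with
gain f(m+1) − f(m) < 1e-4 (changes beyond the fourth decimal place are deemed
irrelevant; threshold configurable). For b, c > 0 the step gain
b·c/((c+m)(c+m+1)) is strictly decreasing in m, so the first crossing is
unique. Quality flags: `flat` (negligible span or b ≈ 0; m* at the first
evaluable size), `decreasing` (b < 0; no size), `noisy` (no convergence or RMSE
> 20 % of the curve span; no size), else `ok`. Medians of m* per combination
exclude undetected fits and report exclusion counts; with even group sizes they
may be half-integers.

## Featurizations and scaling

* MACCS counts: occurrence counts of the 167-position MACCS SMARTS key set
  (position 0 unused; keys without a SMARTS definition 0). RDKit only exposes
  the binary variant, so counts are obtained by substructure-match counting
  over RDKit's own key definitions; the binary keys serve as a test oracle.
* Morgan counts: hashed circular-substructure counts, radius 3, 2048 bins
  (RDKit Morgan generator). Folding preserves total occurrence counts, which
  the tests check against the unhashed enumeration.
* Physicochemical descriptors: RDKit's full default descriptor collection; the
  realized names are recorded rather than a fixed length asserted, because the
  set is toolkit-version dependent (210 with the RDKit in use). Non-finite
  descriptor values are flagged per compound and zero-filled; extreme values
  are *not* clipped — outlier handling lives on the prediction side.
* Learned representations (e.g. 512-dimensional CDDD vectors) are ingested as
  precomputed matrices aligned with the compound table; the encoder itself is
  out of scope.

Scaling is fitted per training partition of every split and applied to both
partitions (no leakage). Count featurizations are normalized per sample to unit
Euclidean norm — for non-negative count vectors all entries land in [0, 1],
which reconciles "unit norm" with "values ∈ [0, 1]"; a per-feature min–max
reading of that phrase would also satisfy the bracket and was rejected as not
being a norm. Continuous featurizations are standardized to column mean 0 /
population std 1; zero-variance columns divide by 1 and are flagged rather
than dropped mid-split.

## Model adapters

Any object with `fit`/`predict` plugs into the engine (`register_technique`);
five reference techniques ship at default hyperparameters (no tuning anywhere):
scikit-learn RandomForestRegressor and SVR, XGBRegressor, and two dropout
networks — shallow (one hidden layer of 128 ReLU units) and deep (256/128/16),
linear output, dropout rate 20 % in every hidden layer, 1000 training epochs.
The networks are implemented as a compact numpy feed-forward regressor
(`DropoutMLPRegressor`) with inverted dropout and mini-batch Adam; training
details the reference configuration leaves open default to Adam at rate 1e-3,
batch 32, mean-squared-error loss, recorded in the spec so runs reproduce.

Built-in UQ baselines, evaluated via a single 10-fold CV producing one
prediction and one uncertainty per compound:

* random forest — mean and population std over the individual trees (the
  forest's `predict` equals the tree mean, a consistency the tests assert);
* dropout networks — Monte Carlo dropout: 100 stochastic forward passes with
  freshly sampled masks (seeded), mean as prediction, population std as
  uncertainty. With the rate forced to 0 all passes coincide and the
  uncertainty vanishes, a degenerate case under test.

Determinism: rf/xgb/svm are bitwise reproducible given the spec seed; each
ensemble member derives a child seed from (plan seed, repetition index) via
`SeedSequence`, so results are independent of execution order.

## Synthetic data

The generator stands in for curated assay datasets and makes every stage
testable without downloads. Features are X = Z·W with Z (n×r) standard normal
and W fixed by seed (latent low-rank structure, default r = 4, p = 64);
targets are a sum of sigmoids of the latent coordinates (smooth, nonlinear,
learnable) plus Gaussian noise of scale σ·(1 + h·s), where the difficulty
score s is the squared normalized latent norm ((‖Z‖²/r)², heavy-tailed so a
large h separates easy from hard compounds clearly) and is stored as ground
truth. Defaults n = 300, σ = 0.3, h = 0 emulate a mid-sized, moderately noisy
dataset. An optional duplicate fraction repeats rows with jittered targets
(SMILES shared with the original; identifiers are unique linear-alkane SMILES)
to exercise deduplication. What the generator does **not** emulate: activity
cliffs, censored values, non-normal target distributions, covariate shift —
passing tests show the machinery is correct, not that real assay data will
reach any particular performance.

`make_member_matrix` bypasses model fitting entirely: member predictions are
synthesized as yᵢ + bᵢ + ηᵢₘ with known per-compound bias bᵢ and member noise
scale τᵢ, so the estimator of û can be checked against its analytic target
(population std over M draws estimates τ·√(1−1/M)). Two failure regimes are
reproduced by construction: constant τ (uncertainties carry no rank signal,
ρ centered at 0) and dominant bias with τ→0 (û collapses while errors stay
large — ensembles fail entirely when bias dominates the error; flagged by
`diagnose_uncertainty` when the median û falls below 10 % of the median
error).

## Problem sizes used in the checks

The self-contained study grid runs 5 synthetic datasets (n = 300, σ = 0.3) ×
{rf, svm, xgb} at M = 20, k = 2 with the full 200-permutation growth analysis
— chosen as the package's own scaled-down demonstration completing in a few
minutes on one CPU. Saturation recovery uses the analytic fixture a = 0.5,
b = 0.3, c = 5 at M = 200, whose first sub-threshold step gain lies at
m* = 117, with σ = 0.005 replicates for the noisy case. Failure-mode checks
use 100 seeds of 200-compound, 20-member matrices.

## Known limitations

* Random subsampling only; scaffold/cluster/time splits are out of scope, so
  all performance estimates are random-split estimates.
* No calibration of û into prediction intervals (no conformal wrapping); û is
  a ranking score, not a variance estimate with coverage guarantees.
* The centered outlier-filter geometry is one defensible reading of a
  2×-range rule; results are insensitive for well-behaved learners but the
  factor and geometry matter for heavy-tailed prediction errors.
* The numpy network adapter favors transparency over speed; for large p or
  long training it is substantially slower than a GPU-backed framework.
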