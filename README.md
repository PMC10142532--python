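# ensuq

Subsampling-ensemble uncertainty quantification for molecular property
regression.

Most regression techniques used in QSAR modeling — support-vector regression,
gradient boosting, generic neural networks — report a number but say nothing
about how much to trust it. `ensuq` implements a model-agnostic remedy: build
an ensemble of M members by running M independent k-fold cross-validation
repetitions over the dataset (one member = one full repetition; at the
reference setting k = 2, M = 200 this means 400 fold models), report per
compound the ensemble mean

    ŷ̄ = (1/M) Σᵢ ŷᵢ

as the prediction and the population standard deviation of the members

    û = √( (1/M) Σᵢ (ŷᵢ − ŷ̄)² )

as its uncertainty. Predictive quality is assessed by the cross-validated R²,
UQ quality by Spearman's ρ between û and the absolute error (does the
uncertainty *rank* predictions by how wrong they are?), and combinations of
featurization × technique are compared across datasets by rank sums. A
growing-ensemble analysis — cumulative member curves, smoothed over 200 random
member orders and fitted with a Michaelis–Menten saturation law
f(m) = a + b·m/(c+m) — detects the smallest ensemble size m* beyond which the
per-member gain drops below 1e-4, i.e. the point where more members stop
paying off. Built-in UQ baselines (random-forest tree variance, Monte Carlo
dropout with 100 masks at 20 % rate) are included for benchmarking.

The package is for computational chemists and ML practitioners who want
uncertainty estimates for techniques that have none, and a principled way to
decide how many ensemble members they actually need.

## Worked example

```python
from ensuq import SubsamplingEnsembleRegressor, SyntheticSpec, make_dataset
from ensuq.growth import permutation_median_curve, fit_saturation

ds = make_dataset(SyntheticSpec(n=300, sigma=0.3, seed=7))
est = SubsamplingEnsembleRegressor(
    technique="rf", n_repetitions=20, k=2, random_state=0
).fit(ds.features, ds.targets)
print(f"cross-validated R^2 : {est.r2_:.3f}")
print(f"UQ Spearman rho     : {est.uq_spearman_:.3f}")

curve = permutation_median_curve(
    est.member_matrix_, ds.targets, metric="r2", n_permutations=200, seed=0
)
sat = fit_saturation(curve)
print(f"saturation size m*  : {sat.m_star} (flag: {sat.flag})")
```

prints

```
cross-validated R^2 : 0.897
UQ Spearman rho     : 0.107
saturation size m*  : 14 (flag: ok)
```

A 20-member random-forest ensemble explains ~90 % of the target variance out
of sample on this synthetic dataset; its member spread ranks the errors weakly
but positively (ρ ≈ 0.11 — UQ ranking values are typically much smaller than
R², and more members help ρ long after R² has saturated); and the fitted
cumulative R² curve saturates at 14 members, so for pure predictive
performance a much smaller ensemble than M = 200 would suffice here.

Estimators follow scikit-learn conventions (`get_params`/`set_params`,
`fit`/`predict`, fitted attributes with trailing underscores), and every stage
is also available as plain functions (`make_split_plan`, `run_members`,
`filter_outlier_predictions`, `aggregate`, `cumulative_curve`,
`fit_saturation`, …). A `ensuq` CLI wraps the pipeline (`synth`, `featurize`,
`run`, `growth`, `baseline`, `report`) for configuration-driven grids.

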