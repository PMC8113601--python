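# radstack

Predicting binary radiotherapy response (radiation-sensitive vs
radiation-resistant) from multi-omics data with a **dataset-independent
stacked ensemble**, interpreting the predictions with **Shapley additive
attributions**, and screening constraint-based metabolic models for
**metabolite-production differences** between response groups.

The package is aimed at computational oncology / systems-biology groups who
have per-patient feature tables from several modalities (clinical
covariates, gene expression, somatic mutations, model-predicted metabolite
production rates) and want per-patient predictions *and* per-patient
explanations of which modality carried the prediction.

## The model

**Labels.** RECIST records map to labels by the first course of radiation:
complete/partial response → sensitive (y = 0), stable/progressive disease →
resistant (y = 1). The class weight w_R = (#sensitive)/(#resistant)
compensates the cohort imbalance.

**Base learners.** One gradient-boosted tree classifier (XGBoost) per
dataset d outputs p_d, the predicted probability of resistance from that
dataset alone. Training minimises the weighted log loss

    L = (1/N) Σᵢ −[ w_R yᵢ log pᵢ + (1 − yᵢ) log(1 − pᵢ) ]

with early stopping on a stratified 87.5/12.5 fit/stop partition, and
Bayesian optimization (Gaussian-process surrogate, expected-improvement
acquisition) over eight hyperparameters, scoring each proposal by
stratified 5-fold cross-validation and selecting by mean validation loss
plus one standard error.

**Meta-learner.** An N_d-class gradient-boosted classifier is trained on
pooled out-of-fold predictions to predict, from the multi-omics features
themselves, which base learner is most accurate per sample
(argmin_k |p_{i,k} − yᵢ|); it is tuned under the same protocol with the
multiclass log loss. Its output w₁…w_{N_d} (summing to 1) weights the
fusion

    p = w₁ p₁ + w₂ p₂ + … + w_{N_d} p_{N_d},

with p > 0.5 called resistant. A combined-dataset baseline (all tables
concatenated into one classifier, identical tuning) is trained alongside
for architecture comparison.

**Attribution.** Each prediction is decomposed into per-feature ΔP values
(change in predicted resistance probability). Exact mode computes
interventional Shapley values by subset enumeration on small tree
ensembles; approximate mode rescales path-dependent tree contributions
into probability space. Attributions are aggregated across outer splits
with weights ∝ 1/(test weighted log loss); features are called significant
by the 95% cumulative-sum rule on mean |ΔP|; per-sample dataset
contributions are clustered (k-means, gap statistic) into Low/Medium/High
groups.

**FBA screen.** For each candidate metabolite, an artificial sink
`1 met[all] → ∅` is added in every compartment holding it; maximizing the
summed sink flux under S v = 0 and the flux bounds (HiGHS LP) gives the
maximal production rate. Candidates in the growth media or unproducible by
any model in the cohort are excluded; group differences are reported as
log₂ ratios of mean production with two-sided t-tests.

## Worked example

```python
from radstack import (CohortConfig, ExperimentConfig,
                      generate_multiomics_cohort, run_experiment)
from radstack.attribution import significant_features, dataset_contributions

cfg = CohortConfig.block_cohort(n_samples=240, seed=7)
bundle, labels, truth = generate_multiomics_cohort(cfg)
result = run_experiment(bundle, labels,
                        ExperimentConfig(n_outer=2, n_iter=8, seed=11))
print(result.metrics_frame()[["split", "model", "weighted_log_loss",
                              "auroc", "balanced_accuracy"]].round(3))

attr = result.aggregated_attributions()
sig = significant_features(attr.mean_abs(), coverage=0.95)
print(f"{len(sig)} of {attr.values.shape[1]} features cover 95% "
      "of total mean |dP|")
print(dataset_contributions(attr).fractions.mean().round(3))
```

prints

```
 split    model  weighted_log_loss  auroc  balanced_accuracy
     0 ensemble              0.724  0.976              0.650
     0 combined              0.286  0.989              0.987
     1 ensemble              0.603  1.000              0.850
     1 combined              0.387  0.989              0.987
66 of 240 features cover 95% of total mean |dP|
expression    0.522
metabolite    0.478
```

The cohort here is a synthetic two-dataset "block" design: two latent
patient subgroups, each predictable only from its own dataset. Both
architectures discriminate well (AUROC ≈ 0.98–1.0); the per-sample
meta-learner weights recover which dataset matters for each patient (the
`w_*` columns of `result.splits[k].predictions`), which is the quantity
the stacked design exists to expose. The significant-feature count and
the near-even dataset contributions reflect the planted symmetric signal.
Note that on cohorts this cleanly learnable the pooled single classifier
attains the lower weighted log loss — see `docs/methods.md` for when each
architecture is preferable.

A command-line interface mirrors the stages:

```bash
radstack simulate --out cohort/ --seed 1 --block
radstack train --config run.json --out run/ --seed 1
radstack attribute --run-dir run/ --out interp/
radstack fba-screen --models models/ --media media.txt \
    --candidates candidates.txt --groups groups.tsv --out screen/
radstack audit --plan run/split_plan.json
```

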