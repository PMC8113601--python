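# Methods

## Problem and model

The package predicts a binary radiotherapy response from several
per-patient feature tables ("datasets"): clinical covariates, gene
expression, somatic mutations, and constraint-based-model-predicted
metabolite production rates. Cohorts of this kind are imbalanced (the
emulated cohort ratio is 716 sensitive : 199 resistant) and heterogeneous:
which modality is informative differs between patients. The architecture
addresses both.

### Labels and class weighting

RECIST response records are reduced to one label per patient using the
record with the lowest course index: complete or partial response maps to
sensitive (0), stable or progressive disease to resistant (1). All losses
weight resistant samples by w_R = (#sensitive)/(#resistant), computed on
the training+validation cohort of each outer split and held fixed through
that split's tuning and evaluation (recomputing w_R per fold would make
fold losses incommensurable).

### Splitting protocol

Outer stratified shuffle splits (80% training+validation / 20% test,
repeated `n_outer` times, default 20); inner stratified 5-fold
cross-validation on the training+validation set for hyperparameter
scoring; a stratified 87.5/12.5 fit/stop partition of every training set
for early stopping. Stratified rounding is largest-remainder per class, so
every subset's class counts are within one sample of the exact proportion.
Plans serialize to JSON for exact replay, and `audit_no_leakage` verifies
zero id intersections at every level.

### Base learners, tuning, early stopping

Each base learner is an XGBoost binary classifier consuming missing values
natively (no imputation; a one-hot-encoded missing category is encoded as
missing in all derived indicators so trees can branch on absence). Eight
hyperparameters are searched: learning rate [0.01, 0.3] (log), tree depth
{2..8}, minimum child weight [1, 20], row and column subsampling [0.5, 1],
minimum split loss [0, 5], L1 and L2 penalties [1e−3, 10] (log). The
optimizer is sequential model-based: a Gaussian-process surrogate (Matern
5/2 over the unit-cube image of the space) with expected-improvement
acquisition over a seeded uniform candidate pool, initialised with random
evaluations (a quarter of the budget). Each proposal is scored by the mean
5-fold validation weighted log loss **plus one standard error** (sample SD
over √5); the evaluated point minimizing that criterion wins. The default
budget is 256 iterations per learner; reduced budgets are configurable and
used in the test-scale experiments. Early stopping monitors the stop
partition with a patience of 10 rounds and a cap of 200 boosting rounds
(default); probabilities are clipped at 1e−15 before logs.

### Meta-learner and fusion

For every training+validation sample, each dataset's out-of-fold
prediction is compared with the truth; the sample's "optimal dataset"
label is argmin_k |p_{i,k} − y_i| with ties resolved by the canonical
dataset order (clinical, expression, mutation, metabolite). The
meta-learner is an N_d-class XGBoost model trained on those labels with
inverse-class-frequency sample weights, using only features with non-zero
mean |ΔP| in their base learner, tuned and early-stopped exactly like a
base learner but under the multiclass log loss. Out-of-fold construction
guarantees no sample's meta row was used to fit the base learner that
produced its prediction. At prediction time the fusion is
p = Σ_k w_k p_k; the boundary p = 0.5 is assigned to the sensitive class
(the strict-inequality rules leave it unassigned; the conservative call is
the majority class). If one dataset is optimal for every pooled sample,
the router degenerates to a constant one-hot weight vector rather than a
trained classifier.

### When the stacked architecture helps — and when it does not

The combined-dataset baseline (feature concatenation, identical tuning) is
trained for comparison. A structural caveat the test suite makes explicit:
the pooled model receives strictly more information than any base learner,
and boosted trees represent "use dataset A's features only for subgroup-A
patients" natively as shallow interactions. On synthetic cohorts whose
signal is cleanly learnable, the pooled baseline therefore matches the
stacked ensemble on discrimination and beats it on weighted log loss —
convex probability mixing with soft routing weights cannot out-score a
well-calibrated single model. The stacked design's practical value is
orthogonal and is what the attribution layer exposes: per-sample,
per-dataset routing weights that state *which modality the prediction
rests on* (e.g. whether clinical data alone suffices for a patient), and
robustness when single pooled models miscalibrate on very
high-dimensional, heterogeneous real data — a regime the clean generator
deliberately does not emulate.

## Attribution

ΔP_ij is the change in predicted resistance probability of sample i
attributed to feature j; attribution is done in probability space, not
log-odds, because the quantity interpreted downstream is the probability
shift.

* **Exact mode** (small tree ensembles, ≤14 features, ≤512 leaves):
  interventional Shapley values by full subset enumeration, with the
  coalition value defined as the mean prediction over composites drawn
  from a background set. Satisfies local accuracy
  Σ_j ΔP_ij = p_i − prior with prior the mean background prediction;
  verified against an independent permutation-enumeration oracle at
  1e−8 tolerance.
* **Approximate mode** (pipeline scale): the booster's path-dependent
  per-feature contributions (margin space) rescaled linearly per sample so
  the row sums to p_i − prior, with prior the resistant-class frequency of
  the training cohort. The rescaling preserves within-sample relative
  credit but inherits the path-dependent traversal's bias; exact mode is
  the reference.
* **Ensemble level**: because p = Σ_k w_k p_k is linear in the base
  outputs, final-probability attributions are the base attributions scaled
  by the sample's routing weight w_k; rows still sum to p − prior.

Cross-split aggregation weights each outer split ∝ 1/(test weighted log
loss), after dividing each sample's row by its prior-to-posterior gap;
samples with |p − prior| ≤ 1e−6 are flagged and left unnormalized.
Significant features are the shortest descending-sorted prefix reaching
95% of total mean |ΔP|. Per-sample dataset contributions (fractions of
total |ΔP| per dataset) are clustered with k-means (10 restarts,
k-means++, fixed seed); the cluster number maximizes the gap statistic
against B = 50 uniform reference draws over the observed range; clusters
are named Low/Medium/High by ascending mean. Enrichment of significant
features uses the χ² test with Yates' continuity correction (clamped at
zero); set-overlap reporting uses the representation factor
observed/(|A||B|/N) with a two-sided Fisher exact p.

## FBA metabolite-production screen

Models are compartmentalized stoichiometric networks (SBML L3/fbc or a
JSON dialect) with flux bounds already set. Media application opens uptake
only for exchanges of media metabolites — keeping an already-negative
lower bound, since it encodes the model's own uptake capacity — and closes
all other uptakes. The production objective adds one irreversible
unbounded sink per non-external compartment holding the metabolite and
maximizes the **sum** of sink fluxes (the alternative reading, a single
multi-compartment reaction, would force equal consumption in every
compartment and is strictly smaller). LPs are solved with HiGHS;
infeasible/unbounded statuses are reported explicitly, never coerced to 0.
Candidates are dropped if present in the media or not producible by every
model (flux ≤ 1e−9, an exposed tolerance). Contrasts are
log₂((mean_R + ε)/(mean_S + ε)) with ε = 1e−6 (a numerical guard only —
unproducible metabolites were already screened out) and a two-sided
two-sample t-test; identical zero-variance groups report ratio 0, p = 1.

## Synthetic study conditions

The generator produces what the method assumes, so every stage is testable
offline; defaults are the package's study conditions:

* **Multi-omics cohort** — 240 samples at the 716:199 imbalance; clinical
  tables mix numeric and categorical columns with 10% missingness;
  expression is log-normal; mutations are sparse binary (base rate 0.02);
  metabolite features are continuous. Latent subgroups partition the
  cohort; an informative feature carries a +2 SD resistant shift inside
  its subgroup only. Two structures encode the routing problem: marker
  features (label-independent subgroup indicators, +2 SD) and a context
  confound — informative features hold the same elevated values for all
  out-of-subgroup samples regardless of label, so the feature's meaning is
  conditional on patient context (a Simpson-type reversal; the scenario in
  which per-sample dataset routing is the right tool, and what makes the
  per-sample optimal-dataset labels near-deterministic). The manifest
  records every planted feature; a per-feature AUC screen in the tests
  confirms no undeclared signal. What the generator does **not** emulate:
  gene–gene correlation, batch effects, real missingness mechanisms, and
  the miscalibration of pooled models on tens of thousands of real
  features — so passing tests certify the machinery, not real-data
  superiority of either architecture.
* **Toy metabolic cohorts** — a two-compartment network (glucose →
  lactate, yield 2; glutamine → citrate) with disjoint pathways, an
  unproducible species and a media species as planted ineligible
  candidates. Group-specific uptake multipliers give closed-form planted
  log₂ ratios by LP homogeneity; optional log-normal bound jitter
  (σ = 0.05) models inter-patient variation.
* **Chain-bundle networks** — random acyclic "bundles of chains" (≤8
  reactions, integer stoichiometry 1–2) whose optimum decomposes per
  chain, making an independent closed-form capacity oracle exact.
* **Tiny tree forests** — random probability-leaf trees (depth ≤ 3) small
  enough for exhaustive Shapley enumeration.

## Numerical choices and degenerate inputs

Probability clip 1e−15; meta-weight sum tolerance 1e−6; producibility
tolerance 1e−9; attribution-normalization guard 1e−6; ROC by threshold
sweep with trapezoidal area (ties get half credit); Youden threshold ties
resolve to the lower threshold; all-equal contribution vectors cluster as
a single "Low" group; single-class fit sets, empty annotation sets, empty
eligible candidate sets and missing out-of-fold predictions raise typed
errors naming the offender. Test-scale experiments use 5 outer splits, 32
optimizer iterations and a 150-round cap — sizes chosen so the planted
structure is comfortably recoverable on a single CPU; the defaults
(20/256/200) remain the protocol's reference settings.

## Known limitations

Approximate attribution mode is biased relative to exact interventional
Shapley values (documented above). The gap statistic uses the uniform
reference over the observed range only. The FBA layer does not generate
personalized bounds from expression/mutation data — models arrive with
bounds set — and does not implement flux-variability or thermodynamic
analysis. The CLI's `train` stores aggregate artifacts (metrics,
predictions, plans, attributions) rather than re-loadable model binaries.
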