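"""Dataset-independent stacked ensemble of gradient-boosted learners.

One XGBoost base learner per -omics dataset predicts the probability of
radiation resistance from that dataset alone; a second-stage meta-learner
(an N_d-class gradient-boosted classifier) predicts, from the multi-omics
features themselves, which base learner is most accurate for each sample.
The final probability is the meta-weighted average of the base-learner
probabilities,  p = w_1 p_1 + ... + w_Nd p_Nd.

Hyperparameters (eight per learner) are chosen by Bayesian optimization —
a Gaussian-process surrogate with an expected-improvement acquisition —
where each proposal is scored by stratified 5-fold cross-validation and
the selection criterion is the mean validation loss plus one standard
error.  The loss is the resistant-weighted log loss for binary learners
and the multiclass log loss for the meta-learner.  Early stopping uses a
stratified 87.5/12.5 fit/stop partition of each training set.

A combined-dataset baseline (all feature tables concatenated into one
classifier, tuned under the identical protocol) is provided for the
architecture comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .core_data import DataError, LabelVector, OmicsDataset
from .splits_metrics import (
    OuterSplit,
    SplitPlan,
    auroc,
    confusion_from_predictions,
    confusion_metrics,
    make_split_plan,
    mean_plus_se,
    multiclass_log_loss,
    weighted_log_loss,
    youden_threshold,
)
from . import attribution as attr_mod

__all__ = [
    "ParamSpec",
    "default_space",
    "HyperparameterSet",
    "bayes_minimize",
    "TrainedBaseLearner",
    "TrainedMetaLearner",
    "MetaTrainingSet",
    "EnsembleModel",
    "ExperimentConfig",
    "ExperimentResult",
    "tune_hyperparameters",
    "train_base_learner",
    "build_meta_training_set",
    "train_meta_learner",
    "predict_ensemble",
    "train_combined_baseline",
    "run_experiment",
]

CANONICAL_ORDER = ("clinical", "expression", "mutation", "metabolite")
DEFAULT_NUM_ROUNDS = 200
EARLY_STOP_PATIENCE = 10   # rounds without stop-set improvement


# ---------------------------------------------------------------------------
# Hyperparameter space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamSpec:
    name: str
    low: float
    high: float
    scale: str = "linear"       # "linear" | "log"
    integer: bool = False

    def from_unit(self, u: float):
        if self.scale == "log":
            x = math.exp(
                math.log(self.low) + u * (math.log(self.high) - math.log(self.low))
            )
        else:
            x = self.low + u * (self.high - self.low)
        if self.integer:
            return int(round(min(max(x, self.low), self.high)))
        return float(min(max(x, self.low), self.high))

    def contains(self, x) -> bool:
        return self.low - 1e-12 <= x <= self.high + 1e-12


def default_space() -> list:
    """The eight gradient-boosting hyperparameters under optimization."""
    return [
        ParamSpec("learning_rate", 0.01, 0.3, scale="log"),
        ParamSpec("max_depth", 2, 8, integer=True),
        ParamSpec("min_child_weight", 1.0, 20.0),
        ParamSpec("subsample", 0.5, 1.0),
        ParamSpec("colsample_bytree", 0.5, 1.0),
        ParamSpec("min_split_loss", 0.0, 5.0),
        ParamSpec("reg_alpha", 1e-3, 10.0, scale="log"),
        ParamSpec("reg_lambda", 1e-3, 10.0, scale="log"),
    ]


@dataclass
class HyperparameterSet:
    values: dict
    space: list = field(default_factory=default_space)

    def __post_init__(self) -> None:
        by_name = {p.name: p for p in self.space}
        for name, v in self.values.items():
            spec = by_name.get(name)
            if spec is None:
                raise DataError(f"unknown hyperparameter {name!r}")
            if not spec.contains(v):
                raise DataError(
                    f"hyperparameter {name}={v} outside [{spec.low}, {spec.high}]"
                )


# ---------------------------------------------------------------------------
# Bayesian optimization (GP surrogate + expected improvement)
# ---------------------------------------------------------------------------


def bayes_minimize(objective, space, n_iter: int, seed: int = 0,
                   n_init: int | None = None, n_candidates: int = 256):
    """Sequential model-based minimization over the unit-cube image of the
    search space.

    Starts from ``n_init`` quasi-random evaluations, then repeatedly fits a
    Gaussian-process surrogate (Matern 5/2) to the observed losses and
    evaluates the candidate maximizing expected improvement among
    ``n_candidates`` seeded uniform draws.  Returns
    ``(best_params, history)`` with history a list of (params, loss);
    fully deterministic for a fixed seed.
    """
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    if n_iter < 1:
        raise DataError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    d = len(space)
    if n_init is None:
        n_init = min(n_iter, max(4, n_iter // 4))

    U: list[np.ndarray] = []
    history: list[tuple[dict, float]] = []

    def eval_unit(u: np.ndarray) -> None:
        params = {p.name: p.from_unit(float(ui)) for p, ui in zip(space, u)}
        val = float(objective(params))
        U.append(np.asarray(u, dtype=float))
        history.append((params, val))

    for _ in range(n_init):
        eval_unit(rng.random(d))

    while len(history) < n_iter:
        y = np.array([v for _, v in history])
        finite = np.isfinite(y)
        if not finite.any():
            raise DataError("all hyperparameter evaluations were non-finite")
        Xo = np.array(U)[finite]
        yo = y[finite]
        mu0, sd0 = yo.mean(), yo.std() + 1e-12
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0, (1e-3, 1e3))
            * Matern(length_scale=[0.3] * d, nu=2.5,
                     length_scale_bounds=(1e-2, 1e2)),
            alpha=1e-6,
            normalize_y=False,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(Xo, (yo - mu0) / sd0)
            cand = rng.random((n_candidates, d))
            mu, sigma = gp.predict(cand, return_std=True)
        best = (yo.min() - mu0) / sd0
        xi = 0.01
        z = (best - mu - xi) / np.maximum(sigma, 1e-12)
        ei = (best - mu - xi) * norm.cdf(z) + sigma * norm.pdf(z)
        ei[sigma < 1e-12] = 0.0
        eval_unit(cand[int(np.argmax(ei))])

    vals = np.array([v for _, v in history])
    vals[~np.isfinite(vals)] = np.inf
    best_params = history[int(np.argmin(vals))][0]
    return best_params, history


# ---------------------------------------------------------------------------
# XGBoost learners
# ---------------------------------------------------------------------------


def _xgb_params(hp: dict, seed: int, num_class: int | None = None) -> dict:
    params = {
        "eta": hp.get("learning_rate", 0.1),
        "max_depth": int(hp.get("max_depth", 4)),
        "min_child_weight": hp.get("min_child_weight", 1.0),
        "subsample": hp.get("subsample", 1.0),
        "colsample_bytree": hp.get("colsample_bytree", 1.0),
        "gamma": hp.get("min_split_loss", 0.0),
        "alpha": hp.get("reg_alpha", 0.0),
        "lambda": hp.get("reg_lambda", 1.0),
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(seed) % (2**31 - 1),
    }
    if num_class is None:
        params.update(objective="binary:logistic", eval_metric="logloss",
                      base_score=0.5)
    else:
        params.update(objective="multi:softprob", eval_metric="mlogloss",
                      num_class=int(num_class))
    return params


def _frame_of(dataset) -> pd.DataFrame:
    return dataset.values if isinstance(dataset, OmicsDataset) else dataset


def _dmatrix(X: pd.DataFrame, y=None, w=None) -> xgb.DMatrix:
    return xgb.DMatrix(
        X.to_numpy(dtype=float), label=y, weight=w,
        feature_names=[str(c) for c in X.columns], missing=np.nan,
    )


@dataclass
class TrainedBaseLearner:
    """A fitted binary gradient-boosted learner for one dataset."""

    dataset_name: str
    booster_: xgb.Booster
    feature_names: list
    hp: dict
    best_iteration: int
    w_R: float
    provenance: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != list(self.feature_names):
            X = X[self.feature_names]
        dm = _dmatrix(X)
        return np.asarray(
            self.booster_.predict(dm, iteration_range=(0, self.best_iteration + 1))
        )


@dataclass
class TrainedMetaLearner:
    booster_: xgb.Booster
    feature_names: list
    n_classes: int
    hp: dict
    best_iteration: int

    def predict_weights(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != list(self.feature_names):
            X = X[self.feature_names]
        dm = _dmatrix(X)
        W = np.asarray(
            self.booster_.predict(dm, iteration_range=(0, self.best_iteration + 1))
        )
        return W.reshape(len(X), self.n_classes)


def _fit_booster(X, y, w, params, fit_ids, stop_ids,
                 num_rounds=DEFAULT_NUM_ROUNDS, patience=EARLY_STOP_PATIENCE):
    Xf, Xs = X.loc[fit_ids], X.loc[stop_ids]
    yf, ys = y.loc[fit_ids], y.loc[stop_ids]
    if yf.nunique() < 2:
        raise DataError("fit set contains a single class")
    wf = w.loc[fit_ids] if w is not None else None
    ws = w.loc[stop_ids] if w is not None else None
    dtrain = _dmatrix(Xf, yf.to_numpy(), None if wf is None else wf.to_numpy())
    dstop = _dmatrix(Xs, ys.to_numpy(), None if ws is None else ws.to_numpy())
    bst = xgb.train(
        params, dtrain, num_boost_round=num_rounds,
        evals=[(dstop, "stop")], early_stopping_rounds=patience,
        verbose_eval=False,
    )
    best_it = bst.best_iteration if bst.best_iteration is not None else num_rounds - 1
    return bst, int(best_it)


def train_base_learner(dataset, labels: LabelVector, hp, fit_ids, stop_ids,
                       seed: int = 0, num_rounds: int = DEFAULT_NUM_ROUNDS,
                       patience: int = EARLY_STOP_PATIENCE,
                       name: str | None = None) -> TrainedBaseLearner:
    """Fit one binary learner on ``fit_ids`` with the boosting round chosen
    by the weighted log loss on ``stop_ids``.  Missing values are consumed
    natively; resistant samples carry weight w_R from ``labels``."""
    hp_values = hp.values if isinstance(hp, HyperparameterSet) else dict(hp)
    X = _frame_of(dataset)
    y = labels.to_series()
    w = pd.Series(np.where(y.to_numpy() == 1, labels.w_R, 1.0), index=y.index)
    bst, best_it = _fit_booster(
        X, y, w, _xgb_params(hp_values, seed), fit_ids, stop_ids,
        num_rounds, patience,
    )
    return TrainedBaseLearner(
        dataset_name=name or getattr(dataset, "name", "dataset"),
        booster_=bst,
        feature_names=[str(c) for c in X.columns],
        hp=hp_values,
        best_iteration=best_it,
        w_R=labels.w_R,
        provenance={"n_fit": len(fit_ids), "n_stop": len(stop_ids), "seed": seed},
    )


def tune_hyperparameters(dataset, labels: LabelVector, folds, space=None,
                         n_iter: int = 256, seed: int = 0,
                         num_rounds: int = DEFAULT_NUM_ROUNDS,
                         patience: int = EARLY_STOP_PATIENCE):
    """Bayesian search for the hyperparameters minimizing the 5-fold mean
    validation weighted log loss plus one standard error."""
    space = space or default_space()
    X = _frame_of(dataset)
    y = labels.to_series()

    def objective(params: dict) -> float:
        losses = []
        for f in folds:
            learner = train_base_learner(
                X, labels, params, f.fit_ids, f.stop_ids, seed=seed,
                num_rounds=num_rounds, patience=patience,
            )
            p = learner.predict(X.loc[f.validation_ids])
            losses.append(
                weighted_log_loss(y.loc[f.validation_ids].to_numpy(), p, labels.w_R)
            )
        return mean_plus_se(losses)

    best, history = bayes_minimize(objective, space, n_iter=n_iter, seed=seed)
    return HyperparameterSet(best, space), history


# ---------------------------------------------------------------------------
# Meta-learner
# ---------------------------------------------------------------------------


@dataclass
class MetaTrainingSet:
    """Pooled out-of-fold rows labelled with the index of the base learner
    closest to the truth for each sample."""

    X: pd.DataFrame
    labels: np.ndarray
    dataset_order: list
    feature_origin: dict            # prefixed feature -> dataset name

    @property
    def n_classes(self) -> int:
        return len(self.dataset_order)

    def class_weights(self) -> np.ndarray:
        counts = np.bincount(self.labels, minlength=self.n_classes).astype(float)
        w = np.where(counts > 0, counts.sum() / np.maximum(counts, 1), 0.0)
        return w / w[w > 0].min() if (w > 0).any() else w


def build_meta_training_set(bundle, dataset_order, oof: pd.DataFrame,
                            labels: LabelVector, mean_abs_by_dataset: dict
                            ) -> MetaTrainingSet:
    """Assemble the meta-learner's training matrix.

    ``oof`` holds one out-of-fold probability per (sample, dataset).  The
    label of sample i is the index of the dataset whose prediction is
    closest to y_i (argmin |p_{i,k} − y_i|; ties break to the canonical
    dataset order).  Feature columns are the union over datasets of the
    features with non-zero mean |ΔP| in the corresponding base learner,
    prefixed ``dataset:feature``.
    """
    missing = oof.isna()
    if missing.to_numpy().any():
        i = missing.stack().idxmax()
        raise DataError(f"missing out-of-fold prediction for sample {i[0]!r}, "
                        f"dataset {i[1]!r}")
    y = labels.subset(list(oof.index)).y
    err = np.abs(oof[list(dataset_order)].to_numpy(float) - y[:, None])
    meta_labels = np.argmin(err, axis=1)  # argmin takes the first (canonical) min

    pieces = []
    origin = {}
    for d in dataset_order:
        ma = mean_abs_by_dataset[d]
        feats = [f for f in ma.index if ma[f] > 0]
        if not feats:
            continue
        block = _frame_of(bundle[d]).loc[oof.index, feats]
        block = block.rename(columns={f: f"{d}:{f}" for f in feats})
        origin.update({f"{d}:{f}": d for f in feats})
        pieces.append(block)
    if not pieces:
        raise DataError("no dataset contributed features with non-zero mean |ΔP|")
    X = pd.concat(pieces, axis=1)
    return MetaTrainingSet(X=X, labels=meta_labels,
                           dataset_order=list(dataset_order),
                           feature_origin=origin)


def train_meta_learner(meta_set: MetaTrainingSet, hp, fit_ids, stop_ids,
                       seed: int = 0, num_rounds: int = DEFAULT_NUM_ROUNDS,
                       patience: int = EARLY_STOP_PATIENCE) -> TrainedMetaLearner:
    """Fit the N_d-class learner minimizing the multiclass log loss, with
    inverse-class-frequency sample weights and the usual early stopping."""
    if len(np.unique(meta_set.labels)) < 2:
        raise DataError("meta training set contains a single optimal-dataset class")
    hp_values = hp.values if isinstance(hp, HyperparameterSet) else dict(hp)
    y = pd.Series(meta_set.labels, index=meta_set.X.index)
    cw = meta_set.class_weights()
    w = pd.Series(cw[meta_set.labels], index=meta_set.X.index)
    fit_ids = [s for s in fit_ids if s in meta_set.X.index]
    stop_ids = [s for s in stop_ids if s in meta_set.X.index]
    bst, best_it = _fit_booster(
        meta_set.X, y, w,
        _xgb_params(hp_values, seed, num_class=meta_set.n_classes),
        fit_ids, stop_ids, num_rounds, patience,
    )
    return TrainedMetaLearner(
        booster_=bst,
        feature_names=[str(c) for c in meta_set.X.columns],
        n_classes=meta_set.n_classes,
        hp=hp_values,
        best_iteration=best_it,
    )


def tune_meta_hyperparameters(meta_set: MetaTrainingSet, folds, space=None,
                              n_iter: int = 256, seed: int = 0,
                              num_rounds: int = DEFAULT_NUM_ROUNDS,
                              patience: int = EARLY_STOP_PATIENCE):
    """Same protocol as the base learners with the multiclass log loss."""
    space = space or default_space()
    Y_onehot = np.eye(meta_set.n_classes)[meta_set.labels]
    y_index = {s: i for i, s in enumerate(meta_set.X.index)}

    def objective(params: dict) -> float:
        losses = []
        for f in folds:
            fit = [s for s in f.fit_ids if s in y_index]
            stop = [s for s in f.stop_ids if s in y_index]
            val = [s for s in f.validation_ids if s in y_index]
            if not val:
                continue
            try:
                learner = train_meta_learner(
                    meta_set, params, fit, stop, seed=seed,
                    num_rounds=num_rounds, patience=patience,
                )
            except DataError:
                return float("inf")
            P = learner.predict_weights(meta_set.X.loc[val])
            rows = [y_index[s] for s in val]
            losses.append(multiclass_log_loss(Y_onehot[rows], P))
        return mean_plus_se(losses)

    best, history = bayes_minimize(objective, space, n_iter=n_iter, seed=seed)
    return HyperparameterSet(best, space), history


# ---------------------------------------------------------------------------
# Full ensemble
# ---------------------------------------------------------------------------


@dataclass
class EnsembleModel:
    """Trained base learners in canonical dataset order plus the meta-learner."""

    base_learners: dict
    meta_learner: TrainedMetaLearner | None
    dataset_order: list
    prior: float                     # resistant-class frequency of the training cohort
    meta_features: dict              # dataset -> unprefixed features fed to the meta-learner
    w_R: float
    constant_weights: list | None = None   # used when the router is degenerate

    def meta_matrix(self, bundle, sample_ids) -> pd.DataFrame:
        pieces = []
        for d in self.dataset_order:
            feats = self.meta_features.get(d, [])
            if not feats:
                continue
            block = _frame_of(bundle[d]).loc[sample_ids, feats]
            pieces.append(block.rename(columns={f: f"{d}:{f}" for f in feats}))
        return pd.concat(pieces, axis=1)


def predict_ensemble(model: EnsembleModel, bundle, sample_ids) -> pd.DataFrame:
    """Final probability p = sum_k w_k p_k with the meta output as weights.

    Returns a frame with p, the predicted class (resistant iff p > 0.5;
    the boundary goes to sensitive), and every p_k and w_k.
    """
    ids = list(sample_ids)
    P = np.column_stack([
        model.base_learners[d].predict(_frame_of(bundle[d]).loc[ids])
        for d in model.dataset_order
    ])
    if len(model.dataset_order) == 1:
        W = np.ones((len(ids), 1))
    elif model.meta_learner is None:
        W = np.tile(np.asarray(model.constant_weights, float), (len(ids), 1))
    else:
        W = model.meta_learner.predict_weights(model.meta_matrix(bundle, ids))
    if np.any(np.abs(W.sum(axis=1) - 1.0) > 1e-6):
        raise DataError("meta weights do not sum to 1")
    p = (W * P).sum(axis=1)
    out = pd.DataFrame({"p": p}, index=ids)
    out["class"] = np.where(p > 0.5, "resistant", "sensitive")
    for k, d in enumerate(model.dataset_order):
        out[f"p_{d}"] = P[:, k]
    for k, d in enumerate(model.dataset_order):
        out[f"w_{d}"] = W[:, k]
    return out


def train_combined_baseline(bundle, dataset_order, labels: LabelVector,
                            split: OuterSplit, space=None, n_iter: int = 32,
                            seed: int = 0, num_rounds: int = DEFAULT_NUM_ROUNDS,
                            patience: int = EARLY_STOP_PATIENCE):
    """Concatenate all datasets (features prefixed by dataset name) and
    train a single classifier under the identical tuning protocol."""
    pieces = []
    seen = set()
    for d in dataset_order:
        X = _frame_of(bundle[d])
        renamed = X.rename(columns={c: f"{d}:{c}" for c in X.columns})
        clash = seen & set(renamed.columns)
        if clash:
            raise DataError(f"duplicate prefixed feature names: {sorted(clash)[:3]}")
        seen |= set(renamed.columns)
        pieces.append(renamed)
    combined = pd.concat(pieces, axis=1)
    labels_tv = labels.subset(split.trainval_ids)
    hp, _ = tune_hyperparameters(
        combined.loc[split.trainval_ids], labels_tv, split.inner_folds,
        space=space, n_iter=n_iter, seed=seed,
        num_rounds=num_rounds, patience=patience,
    )
    learner = train_base_learner(
        combined.loc[split.trainval_ids], labels_tv, hp,
        split.fit_ids, split.stop_ids, seed=seed,
        num_rounds=num_rounds, patience=patience, name="combined",
    )
    return learner, combined


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    n_outer: int = 20
    n_iter: int = 256               # Bayesian-optimization iterations per learner
    seed: int = 0
    num_rounds: int = DEFAULT_NUM_ROUNDS
    patience: int = EARLY_STOP_PATIENCE
    train_combined: bool = True
    dataset_order: list | None = None
    space: list | None = None

    def resolved_order(self, bundle) -> list:
        if self.dataset_order is not None:
            return list(self.dataset_order)
        named = [d for d in CANONICAL_ORDER if d in bundle]
        extra = [d for d in bundle if d not in named]
        return named + sorted(extra)


@dataclass
class SplitResult:
    split_index: int
    model: EnsembleModel
    predictions: pd.DataFrame
    metrics_ensemble: dict
    metrics_combined: dict | None
    attributions: "attr_mod.AttributionMatrix"
    meta_labels: pd.Series           # planted/derived optimal dataset per trainval sample


@dataclass
class ExperimentResult:
    plan: SplitPlan
    splits: list
    config: ExperimentConfig

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.splits:
            row = {"split": s.split_index, "model": "ensemble"}
            row.update(s.metrics_ensemble)
            rows.append(row)
            if s.metrics_combined is not None:
                row = {"split": s.split_index, "model": "combined"}
                row.update(s.metrics_combined)
                rows.append(row)
        return pd.DataFrame(rows)

    def aggregated_attributions(self) -> "attr_mod.AttributionMatrix":
        mats = [s.attributions for s in self.splits]
        losses = [s.metrics_ensemble["weighted_log_loss"] for s in self.splits]
        return attr_mod.aggregate_across_splits(mats, losses)


def _score(y, p, w_R) -> dict:
    counts = confusion_from_predictions(y, p)
    cm = confusion_metrics(counts)
    rep = youden_threshold(y, p)
    return {
        "weighted_log_loss": weighted_log_loss(y, p, w_R),
        "auroc": auroc(y, p),
        "balanced_accuracy": cm["balanced_accuracy"],
        "sensitivity": cm["sensitivity"],
        "specificity": cm["specificity"],
        "ppv": cm["ppv"],
        "npv": cm["npv"],
        "youden_threshold": rep.threshold,
        "youden_J": rep.J,
    }


def _ensemble_attributions(model: EnsembleModel, bundle, sample_ids,
                           predictions: pd.DataFrame) -> "attr_mod.AttributionMatrix":
    """Attribution of the final ensemble probability: each base learner's
    probability-space attributions scaled by that sample's meta weight.
    Because p = sum_k w_k p_k and every base matrix row sums to p_k − prior,
    the combined rows sum to p − prior (local accuracy at ensemble level)."""
    pieces = []
    dataset_of = {}
    for d in model.dataset_order:
        learner = model.base_learners[d]
        X = _frame_of(bundle[d]).loc[list(sample_ids)]
        m = attr_mod.shap_values(learner, X, mode="approximate",
                                 prior=model.prior)
        scaled = m.values.mul(predictions[f"w_{d}"], axis=0)
        scaled = scaled.rename(columns={c: f"{d}:{c}" for c in scaled.columns})
        dataset_of.update({f"{d}:{c}": d for c in m.values.columns})
        pieces.append(scaled)
    values = pd.concat(pieces, axis=1)
    return attr_mod.AttributionMatrix(
        values=values, prior=model.prior, dataset_of=dataset_of,
        mode="approximate",
    )


def run_experiment(bundle, labels: LabelVector,
                   config: ExperimentConfig | None = None) -> ExperimentResult:
    """Run the full nested protocol: for every outer split, tune and train
    per-dataset base learners, assemble and train the meta-learner on
    pooled out-of-fold predictions, score the held-out test set, and
    (optionally) train the combined-dataset baseline for comparison."""
    config = config or ExperimentConfig()
    order = config.resolved_order(bundle)
    space = config.space or default_space()
    plan = make_split_plan(labels, n_outer=config.n_outer, seed=config.seed)
    seed_rng = np.random.default_rng(config.seed)
    results = []
    for s_idx, split in enumerate(plan.outer_splits):
        sub = int(seed_rng.integers(2**31 - 1))
        labels_tv = LabelVector.from_labels(
            split.trainval_ids, labels.subset(split.trainval_ids).y
        )
        prior = float(labels_tv.y.mean())

        base_final: dict = {}
        oof = pd.DataFrame(index=split.trainval_ids, columns=order, dtype=float)
        mean_abs: dict = {}
        for k, d in enumerate(order):
            Xtv = _frame_of(bundle[d]).loc[split.trainval_ids]
            hp, _ = tune_hyperparameters(
                Xtv, labels_tv, split.inner_folds, space=space,
                n_iter=config.n_iter, seed=sub + k,
                num_rounds=config.num_rounds, patience=config.patience,
            )
            final = train_base_learner(
                Xtv, labels_tv, hp, split.fit_ids, split.stop_ids,
                seed=sub + k, num_rounds=config.num_rounds,
                patience=config.patience, name=d,
            )
            base_final[d] = final
            for f in split.inner_folds:
                fold_learner = train_base_learner(
                    Xtv, labels_tv, hp, f.fit_ids, f.stop_ids,
                    seed=sub + k, num_rounds=config.num_rounds,
                    patience=config.patience, name=d,
                )
                oof.loc[f.validation_ids, d] = fold_learner.predict(
                    Xtv.loc[f.validation_ids]
                )
            m = attr_mod.shap_values(final, Xtv, mode="approximate", prior=prior)
            mean_abs[d] = m.mean_abs()

        constant_w = None
        if len(order) > 1:
            meta_set = build_meta_training_set(
                {d: _frame_of(bundle[d]).loc[split.trainval_ids] for d in order},
                order, oof, labels_tv, mean_abs,
            )
            meta_features = {
                d: [f for f in mean_abs[d].index if mean_abs[d][f] > 0]
                for d in order
            }
            meta_label_series = pd.Series(
                [order[i] for i in meta_set.labels], index=meta_set.X.index
            )
            classes = np.unique(meta_set.labels)
            if len(classes) < 2:
                # one dataset is optimal for every pooled sample: the router
                # degenerates to a constant one-hot weight vector
                meta = None
                constant_w = [1.0 if k == classes[0] else 0.0
                              for k in range(len(order))]
            else:
                hp_meta, _ = tune_meta_hyperparameters(
                    meta_set, split.inner_folds, space=space,
                    n_iter=config.n_iter, seed=sub + len(order),
                    num_rounds=config.num_rounds, patience=config.patience,
                )
                meta = train_meta_learner(
                    meta_set, hp_meta, split.fit_ids, split.stop_ids,
                    seed=sub + len(order), num_rounds=config.num_rounds,
                    patience=config.patience,
                )
        else:
            meta, meta_features = None, {order[0]: list(mean_abs[order[0]].index)}
            meta_label_series = pd.Series(order[0], index=split.trainval_ids)
            constant_w = [1.0]

        model = EnsembleModel(
            base_learners=base_final, meta_learner=meta, dataset_order=order,
            prior=prior, meta_features=meta_features, w_R=labels_tv.w_R,
            constant_weights=constant_w,
        )
        preds = predict_ensemble(model, bundle, split.test_ids)
        y_test = labels.subset(split.test_ids).y
        metrics_e = _score(y_test, preds["p"].to_numpy(), labels_tv.w_R)

        metrics_c = None
        if config.train_combined:
            comb, comb_X = train_combined_baseline(
                bundle, order, labels, split, space=space,
                n_iter=config.n_iter, seed=sub + len(order) + 1,
                num_rounds=config.num_rounds, patience=config.patience,
            )
            p_c = comb.predict(comb_X.loc[split.test_ids])
            metrics_c = _score(y_test, p_c, labels_tv.w_R)

        attrs = _ensemble_attributions(model, bundle, split.test_ids, preds)
        results.append(SplitResult(
            split_index=s_idx, model=model, predictions=preds,
            metrics_ensemble=metrics_e, metrics_combined=metrics_c,
            attributions=attrs, meta_labels=meta_label_series,
        ))
    return ExperimentResult(plan=plan, splits=results, config=config)
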