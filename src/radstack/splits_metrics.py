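"""Nested stratified data splitting and classifier performance metrics.

The splitting protocol is: outer stratified shuffle splits into
training+validation (80%) and testing (20%), repeated ``n_outer`` times;
within each training+validation set, stratified 5-fold cross-validation for
hyperparameter selection; within each fold's training set, a stratified
87.5% / 12.5% partition whose held-out part decides the early-stopping
iteration.  Stratification keeps the sensitive:resistant proportion of every
subset within one sample per class of the cohort proportion, using
largest-remainder rounding.

Metrics: the imbalance-weighted binary log loss (resistant-class weight
w_R), the multiclass log loss used by the meta-learner, balanced accuracy,
sensitivity/specificity/PPV/NPV, AUROC (threshold sweep with trapezoidal
area, equal to the Mann-Whitney statistic with half credit for ties) and
the Youden J threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core_data import DataError, LabelVector

__all__ = [
    "InnerFold",
    "OuterSplit",
    "SplitPlan",
    "ConfusionCounts",
    "ThresholdReport",
    "make_split_plan",
    "weighted_log_loss",
    "multiclass_log_loss",
    "confusion_metrics",
    "confusion_from_predictions",
    "auroc",
    "youden_threshold",
    "mean_plus_se",
]

PROB_CLIP = 1e-15  # guard before logs


# ---------------------------------------------------------------------------
# Split plan
# ---------------------------------------------------------------------------


@dataclass
class InnerFold:
    train_ids: list
    validation_ids: list
    fit_ids: list    # 87.5% of train_ids, used to fit
    stop_ids: list   # 12.5% of train_ids, decides the early-stop iteration


@dataclass
class OuterSplit:
    trainval_ids: list
    test_ids: list
    inner_folds: list
    fit_ids: list    # early-stop partition of trainval for the final refit
    stop_ids: list


@dataclass
class SplitPlan:
    outer_splits: list
    seed: int
    n_inner: int = 5

    def to_json(self, path=None) -> str:
        obj = {
            "seed": self.seed,
            "n_inner": self.n_inner,
            "outer_splits": [
                {
                    "trainval_ids": s.trainval_ids,
                    "test_ids": s.test_ids,
                    "fit_ids": s.fit_ids,
                    "stop_ids": s.stop_ids,
                    "inner_folds": [
                        {
                            "train_ids": f.train_ids,
                            "validation_ids": f.validation_ids,
                            "fit_ids": f.fit_ids,
                            "stop_ids": f.stop_ids,
                        }
                        for f in s.inner_folds
                    ],
                }
                for s in self.outer_splits
            ],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SplitPlan":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        splits = [
            OuterSplit(
                trainval_ids=s["trainval_ids"],
                test_ids=s["test_ids"],
                fit_ids=s["fit_ids"],
                stop_ids=s["stop_ids"],
                inner_folds=[InnerFold(**f) for f in s["inner_folds"]],
            )
            for s in obj["outer_splits"]
        ]
        return cls(outer_splits=splits, seed=obj["seed"], n_inner=obj["n_inner"])


def _largest_remainder_counts(class_sizes, fraction, rng) -> list:
    """Per-class holdout counts: quotas fraction*n_c rounded so the total is
    round(fraction*N), distributing remainders by largest fractional part
    (ties broken randomly but seedably)."""
    quotas = np.asarray(class_sizes, dtype=float) * fraction
    base = np.floor(quotas).astype(int)
    total = int(round(sum(class_sizes) * fraction))
    short = total - base.sum()
    frac = quotas - base
    order = np.lexsort((rng.random(len(frac)), -frac))
    counts = base.copy()
    for i in order[:max(short, 0)]:
        counts[i] += 1
    return counts.tolist()


def _stratified_holdout(ids_by_class, fraction, rng):
    """Shuffle each class and hold out a largest-remainder share of it.
    Returns (kept_ids, held_ids), each ordered class-by-class."""
    sizes = [len(v) for v in ids_by_class]
    counts = _largest_remainder_counts(sizes, fraction, rng)
    kept, held = [], []
    for ids, k in zip(ids_by_class, counts):
        ids = list(ids)
        rng.shuffle(ids)
        held.extend(ids[:k])
        kept.extend(ids[k:])
    return kept, held


def _stratified_kfold(ids_by_class, n_folds, rng):
    """Stratified k-fold: per class, shuffle and deal into folds as evenly
    as possible, rotating which folds receive the remainder."""
    folds = [[] for _ in range(n_folds)]
    for ids in ids_by_class:
        ids = list(ids)
        rng.shuffle(ids)
        offset = int(rng.integers(n_folds))
        chunks = np.array_split(np.arange(len(ids)), n_folds)
        for j, chunk in enumerate(chunks):
            fold = (j + offset) % n_folds
            folds[fold].extend(ids[i] for i in chunk)
    return folds


def _by_class(ids, label_of):
    classes = sorted({label_of[s] for s in ids})
    return [[s for s in ids if label_of[s] == c] for c in classes]


def make_split_plan(
    labels: LabelVector,
    n_outer: int = 20,
    seed: int = 0,
    n_inner: int = 5,
    test_fraction: float = 0.2,
    stop_fraction: float = 0.125,
) -> SplitPlan:
    """Build the full nested split layout.  Deterministic for a fixed seed."""
    if n_outer < 1:
        raise DataError("n_outer must be >= 1")
    label_of = dict(zip(labels.sample_ids, labels.y.tolist()))
    classes, counts = np.unique(labels.y, return_counts=True)
    if len(classes) < 2:
        raise DataError("both classes must be present")
    if counts.min() < n_inner:
        raise DataError(
            f"class with {counts.min()} samples cannot support "
            f"{n_inner}-fold stratification"
        )
    rng = np.random.default_rng(seed)
    outer = []
    for _ in range(n_outer):
        trainval, test = _stratified_holdout(
            _by_class(labels.sample_ids, label_of), test_fraction, rng
        )
        tv_by_class = _by_class(trainval, label_of)
        fit_ids, stop_ids = _stratified_holdout(tv_by_class, stop_fraction, rng)
        folds = _stratified_kfold(tv_by_class, n_inner, rng)
        inner = []
        for k in range(n_inner):
            val = folds[k]
            train = [s for j, f in enumerate(folds) if j != k for s in f]
            f_fit, f_stop = _stratified_holdout(
                _by_class(train, label_of), stop_fraction, rng
            )
            inner.append(InnerFold(train, val, f_fit, f_stop))
        outer.append(OuterSplit(trainval, test, inner, fit_ids, stop_ids))
    return SplitPlan(outer_splits=outer, seed=seed, n_inner=n_inner)


def audit_no_leakage(plan: SplitPlan) -> int:
    """Count id intersections across every two-sided split in the plan
    (0 means no leakage anywhere)."""
    bad = 0
    for s in plan.outer_splits:
        bad += len(set(s.trainval_ids) & set(s.test_ids))
        bad += len(set(s.fit_ids) & set(s.stop_ids))
        for f in s.inner_folds:
            bad += len(set(f.train_ids) & set(f.validation_ids))
            bad += len(set(f.fit_ids) & set(f.stop_ids))
            bad += len(set(f.validation_ids) & set(s.test_ids))
    return bad


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def weighted_log_loss(y, p, w_R: float) -> float:
    """Imbalance-weighted binary cross-entropy.

    (1/N_s) sum_i -( w_R * y_i * log p_i + (1 - y_i) * log(1 - p_i) ),
    with probabilities clipped to [1e-15, 1 - 1e-15] before the logs.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise DataError(f"y and p length mismatch: {y.shape} vs {p.shape}")
    if w_R <= 0:
        raise DataError("w_R must be positive")
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(np.mean(-(w_R * y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def multiclass_log_loss(Y, P, row_sum_tol: float = 1e-6) -> float:
    """-(1/N_s) sum_i sum_k y_{i,k} log p_{i,k} for one-hot Y."""
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    if Y.shape != P.shape:
        raise DataError(f"Y and P shape mismatch: {Y.shape} vs {P.shape}")
    sums = P.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > row_sum_tol):
        i = int(np.argmax(np.abs(sums - 1.0)))
        raise DataError(f"probability row {i} sums to {sums[i]:.6g}, not 1")
    P = np.clip(P, PROB_CLIP, 1.0)
    return float(-np.mean(np.sum(Y * np.log(P), axis=1)))


def mean_plus_se(values) -> float:
    """Mean plus one standard error (SD/sqrt(n), sample SD) across CV folds."""
    v = np.asarray(values, dtype=float)
    if v.size == 1:
        return float(v[0])
    return float(v.mean() + v.std(ddof=1) / np.sqrt(v.size))


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise DataError("confusion counts must be nonnegative")


def confusion_from_predictions(y, p, threshold: float = 0.5) -> ConfusionCounts:
    """Counts under the rule: resistant (positive) iff p > threshold.
    The boundary p == threshold is assigned to the sensitive class."""
    y = np.asarray(y, dtype=int)
    pred = (np.asarray(p, dtype=float) > threshold).astype(int)
    return ConfusionCounts(
        TP=int(((pred == 1) & (y == 1)).sum()),
        FP=int(((pred == 1) & (y == 0)).sum()),
        TN=int(((pred == 0) & (y == 0)).sum()),
        FN=int(((pred == 0) & (y == 1)).sum()),
    )


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Balanced accuracy, sensitivity, specificity, PPV, NPV.

    A metric whose denominator is zero is reported as nan and listed under
    the ``"undefined"`` key rather than silently coerced to 0.
    """
    out: dict = {}
    undefined = []

    def ratio(name, num, den):
        if den == 0:
            out[name] = float("nan")
            undefined.append(name)
        else:
            out[name] = num / den

    ratio("sensitivity", counts.TP, counts.TP + counts.FN)
    ratio("specificity", counts.TN, counts.TN + counts.FP)
    ratio("ppv", counts.TP, counts.TP + counts.FP)
    ratio("npv", counts.TN, counts.TN + counts.FN)
    if "sensitivity" in undefined or "specificity" in undefined:
        out["balanced_accuracy"] = float("nan")
        undefined.append("balanced_accuracy")
    else:
        out["balanced_accuracy"] = 0.5 * (out["sensitivity"] + out["specificity"])
    out["undefined"] = undefined
    return out


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def _roc_points(y, p):
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if y.min() == y.max():
        raise DataError("both classes required for ROC analysis")
    order = np.argsort(-p, kind="mergesort")
    y, p = y[order], p[order]
    # group tied scores so ties move diagonally, giving half credit
    distinct = np.where(np.diff(p))[0]
    idx = np.r_[distinct, y.size - 1]
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(1 - y)[idx]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    thresholds = np.r_[np.inf, p[idx]]
    return fpr, tpr, thresholds


def auroc(y, p) -> float:
    """Area under the ROC curve via threshold sweep + trapezoid."""
    fpr, tpr, _ = _roc_points(y, p)
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class ThresholdReport:
    threshold: float
    J: float
    sensitivity: float
    specificity: float


def youden_threshold(y, p) -> ThresholdReport:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the unique scores; a sample is called
    resistant iff p > threshold.  Ties in J resolve to the lower threshold.
    """
    fpr, tpr, thresholds = _roc_points(y, p)
    J = tpr - fpr
    # skip the (0,0) sentinel point; among maxima take the lowest threshold
    best, best_j = None, -np.inf
    for t, j, se, sp in zip(thresholds[1:], J[1:], tpr[1:], 1 - fpr[1:]):
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and best is not None and t < best[0]):
            best, best_j = (float(t), float(j), float(se), float(sp)), float(j)
    t, j, se, sp = best
    return ThresholdReport(threshold=t, J=j, sensitivity=se, specificity=sp)
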