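"""Per-sample additive feature attributions and their downstream analyses.

Each attribution value ΔP_ij is the change in predicted probability of the
resistant class for sample i attributed to feature j.  Two computation
modes are provided:

* **exact** — interventional Shapley values computed by full subset
  enumeration against a background set: the characteristic function of a
  coalition S is the mean model output over composites taking the features
  in S from the explained sample and the rest from background samples.
  Feasible for small trees/feature counts; satisfies local accuracy
  (sum_j ΔP_ij = p_i − prior with prior the mean background prediction).
* **approximate** — the gradient-boosting library's path-dependent
  per-feature contributions (computed in margin/log-odds space) linearly
  rescaled into probability space so each sample's attributions sum to
  p_i − prior.  The rescaling preserves relative feature credit within a
  sample but inherits the path-dependent traversal's bias; it is the mode
  used at full pipeline scale.

The rest of the module implements cross-split aggregation with
inverse-loss weights, the 95% cumulative-sum significance rule, per-sample
dataset contributions with gap-statistic k-means clustering, and the
interpretation statistics (Spearman ΔP-vs-value correlation, Yates-corrected
χ² enrichment, Fisher overlap/representation factor).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AnnotationSets, DataError

__all__ = [
    "DecisionTree",
    "TreeEnsembleModel",
    "AttributionMatrix",
    "ContributionProfile",
    "shap_values",
    "aggregate_across_splits",
    "significant_features",
    "dataset_contributions",
    "cluster_contributions",
    "cluster_from_meta_weight",
    "spearman_attr_value",
    "enrichment_test",
    "overlap_representation",
]

NORMALIZATION_EPS = 1e-6   # |p - prior| below this -> sample flagged
EXACT_MAX_FEATURES = 14
EXACT_MAX_LEAVES = 512


# ---------------------------------------------------------------------------
# Minimal tree-ensemble representation
# ---------------------------------------------------------------------------


@dataclass
class DecisionTree:
    """Array-encoded binary decision tree.

    ``feature[n] == -1`` marks a leaf with output ``value[n]``.  Internal
    nodes route x[feature] < threshold to ``left`` else ``right``; missing
    values follow ``missing_left``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    missing_left: np.ndarray

    @property
    def n_leaves(self) -> int:
        return int((self.feature == -1).sum())

    def predict_one(self, x) -> float:
        # comparisons run in the threshold dtype (float32 for trees parsed
        # from xgboost, matching its split semantics exactly)
        dt = self.threshold.dtype
        n = 0
        while self.feature[n] != -1:
            f = self.feature[n]
            v = x[f]
            if math.isnan(v):
                n = self.left[n] if self.missing_left[n] else self.right[n]
            elif dt.type(v) < self.threshold[n]:
                n = self.left[n]
            else:
                n = self.right[n]
        return float(self.value[n])


@dataclass
class TreeEnsembleModel:
    """A list of trees plus an aggregation rule.

    aggregation ``"mean"``: trees carry probability leaves, output is the
    plain average (a probability forest).  aggregation ``"logistic"``: trees
    carry margin leaves, output is sigmoid(sum + base_margin) — the
    gradient-boosting convention.
    """

    trees: list
    feature_names: list
    aggregation: str = "mean"
    base_margin: float = 0.0

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def total_leaves(self) -> int:
        return sum(t.n_leaves for t in self.trees)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        raw = np.array(
            [[t.predict_one(row) for t in self.trees] for row in X]
        ).sum(axis=1)
        if self.aggregation == "mean":
            return raw / len(self.trees)
        return 1.0 / (1.0 + np.exp(-(raw + self.base_margin)))

    @classmethod
    def from_xgboost(cls, booster, feature_names) -> "TreeEnsembleModel":
        """Parse an XGBoost binary:logistic booster into array trees."""
        cfg = json.loads(booster.save_config())
        base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
        base_margin = math.log(base_score / (1.0 - base_score))
        name_to_idx = {n: i for i, n in enumerate(feature_names)}
        trees = []
        for dump in booster.get_dump(dump_format="json"):
            nodes = {}

            def walk(obj):
                nodes[obj["nodeid"]] = obj
                for ch in obj.get("children", []):
                    walk(ch)

            walk(json.loads(dump))
            ids = sorted(nodes)
            remap = {nid: i for i, nid in enumerate(ids)}
            n = len(ids)
            feature = np.full(n, -1, dtype=int)
            threshold = np.zeros(n, dtype=np.float32)
            left = np.zeros(n, dtype=int)
            right = np.zeros(n, dtype=int)
            value = np.zeros(n)
            missing_left = np.zeros(n, dtype=bool)
            for nid, obj in nodes.items():
                i = remap[nid]
                if "leaf" in obj:
                    value[i] = obj["leaf"]
                else:
                    split = obj["split"]
                    feature[i] = name_to_idx.get(split, int(split.lstrip("f")) if split.lstrip("f").isdigit() else name_to_idx[split])
                    threshold[i] = obj["split_condition"]
                    left[i] = remap[obj["yes"]]
                    right[i] = remap[obj["no"]]
                    missing_left[i] = obj["missing"] == obj["yes"]
            trees.append(
                DecisionTree(feature, threshold, left, right, value, missing_left)
            )
        return cls(trees, list(feature_names), aggregation="logistic",
                   base_margin=base_margin)


# ---------------------------------------------------------------------------
# Attribution container
# ---------------------------------------------------------------------------


@dataclass
class AttributionMatrix:
    """ΔP values per sample (rows) and feature (columns)."""

    values: pd.DataFrame
    prior: float
    dataset_of: dict = field(default_factory=dict)
    mode: str = "exact"
    flagged: list = field(default_factory=list)
    split_weights: list | None = None

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    def mean_abs(self) -> pd.Series:
        """Global importance: mean |ΔP| per feature across samples."""
        return self.values.abs().mean(axis=0)

    def to_tsv(self, path) -> None:
        long = self.values.stack().rename("delta_p").reset_index()
        long.columns = ["sample_id", "feature_id", "delta_p"]
        long["dataset"] = long["feature_id"].map(
            lambda f: self.dataset_of.get(f, "")
        )
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, prior=float("nan"), mode="exact") -> "AttributionMatrix":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot(index="sample_id", columns="feature_id",
                          values="delta_p")
        dataset_of = dict(
            long.drop_duplicates("feature_id")
            .set_index("feature_id")["dataset"]
            .dropna()
        )
        return cls(values=wide, prior=prior, dataset_of=dataset_of, mode=mode)


# ---------------------------------------------------------------------------
# Shapley computation
# ---------------------------------------------------------------------------


def _shapley_weights(m: int) -> np.ndarray:
    """w[s] = s! (m-1-s)! / m! for coalition size s."""
    return np.array(
        [math.factorial(s) * math.factorial(m - 1 - s) / math.factorial(m)
         for s in range(m)]
    )


def exact_shapley(model: TreeEnsembleModel, X, background) -> np.ndarray:
    """Interventional Shapley values by full subset enumeration.

    For every coalition S the characteristic value is the mean prediction
    over composites x_S ∪ z_{S̄} across background rows z.  Complexity
    O(2^M · |background| · trees); intended for tiny ensembles.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(background, dtype=float)
    m = X.shape[1]
    if m > EXACT_MAX_FEATURES:
        raise DataError(f"exact mode limited to {EXACT_MAX_FEATURES} features, got {m}")
    weights = _shapley_weights(m)
    phi = np.zeros((X.shape[0], m))
    n_masks = 1 << m
    for i, x in enumerate(X):
        v = np.empty(n_masks)
        for mask in range(n_masks):
            comp = Z.copy()
            for j in range(m):
                if mask >> j & 1:
                    comp[:, j] = x[j]
            v[mask] = model.predict_proba(comp).mean()
        for j in range(m):
            bit = 1 << j
            acc = 0.0
            for mask in range(n_masks):
                if mask & bit:
                    continue
                s = bin(mask).count("1")
                acc += weights[s] * (v[mask | bit] - v[mask])
            phi[i, j] = acc
    return phi


def shap_values(
    learner,
    samples: pd.DataFrame,
    background: pd.DataFrame | None = None,
    mode: str = "auto",
    prior: float | None = None,
    dataset_of: dict | None = None,
) -> AttributionMatrix:
    """Attribute each prediction to features, in probability space.

    ``learner`` is a :class:`TreeEnsembleModel` or an object exposing
    ``booster_`` / ``feature_names`` (the trained base learners).  In exact
    mode ``background`` is required and ``prior`` is the mean background
    prediction; in approximate mode ``prior`` must be supplied (the
    resistant-class frequency of the training cohort).
    """
    model = learner if isinstance(learner, TreeEnsembleModel) else None
    feature_names = (
        model.feature_names if model is not None else list(learner.feature_names)
    )
    if list(samples.columns) != list(feature_names):
        raise DataError(
            "feature mismatch between learner and samples "
            f"({len(feature_names)} vs {len(samples.columns)} columns)"
        )

    if mode == "auto":
        if (
            model is not None
            and model.n_features <= EXACT_MAX_FEATURES
            and model.total_leaves <= EXACT_MAX_LEAVES
            and background is not None
        ):
            mode = "exact"
        else:
            mode = "approximate"

    if mode == "exact":
        if model is None:
            raise DataError("exact mode requires a TreeEnsembleModel")
        if background is None or len(background) == 0:
            raise DataError("exact mode requires a non-empty background set")
        phi = exact_shapley(model, samples.to_numpy(float),
                            np.asarray(background, dtype=float))
        base = float(model.predict_proba(np.asarray(background, float)).mean())
        return AttributionMatrix(
            values=pd.DataFrame(phi, index=samples.index, columns=feature_names),
            prior=base,
            dataset_of=dataset_of or {},
            mode="exact",
        )

    # approximate: library path-dependent contributions, rescaled to
    # probability space so rows sum to p - prior
    import xgboost as xgb

    booster = learner.booster_ if hasattr(learner, "booster_") else learner
    if prior is None:
        raise DataError("approximate mode requires an explicit prior")
    dm = xgb.DMatrix(samples.to_numpy(float), feature_names=list(feature_names),
                     missing=np.nan)
    best_it = getattr(learner, "best_iteration", None)
    it_range = (0, best_it + 1) if best_it is not None else None
    contrib = booster.predict(dm, pred_contribs=True, iteration_range=it_range)
    margin_phi = contrib[:, :-1]
    p = booster.predict(dm, iteration_range=it_range)
    rowsum = margin_phi.sum(axis=1)
    target = p - prior
    scale = np.where(np.abs(rowsum) > 1e-12, target / np.where(rowsum == 0, 1, rowsum), 0.0)
    phi = margin_phi * scale[:, None]
    return AttributionMatrix(
        values=pd.DataFrame(phi, index=samples.index, columns=feature_names),
        prior=float(prior),
        dataset_of=dataset_of or {},
        mode="approximate",
    )


# ---------------------------------------------------------------------------
# Aggregation across outer splits
# ---------------------------------------------------------------------------


def aggregate_across_splits(per_split, per_split_test_loss) -> AttributionMatrix:
    """Combine test-set attributions from several outer splits.

    Split weights are proportional to 1/(weighted log loss on the split's
    test set).  Within each split every sample's ΔP row is first divided by
    its prior-to-posterior gap (the row sum, equal to p_i − prior under
    local accuracy); rows with |gap| ≤ 1e−6 are left unnormalized and the
    sample is flagged.  Each sample is then averaged over the splits in
    which it was a test sample, with the split weights renormalized over
    those splits.
    """
    losses = np.asarray(per_split_test_loss, dtype=float)
    if len(per_split) != len(losses):
        raise DataError("one test loss per attribution matrix required")
    if np.any(losses <= 0):
        raise DataError("test losses must be positive for inverse weighting")
    w = (1.0 / losses) / (1.0 / losses).sum()

    features = list(per_split[0].values.columns)
    for m in per_split[1:]:
        if list(m.values.columns) != features:
            raise DataError("attribution matrices must share a feature space")

    flagged = set()
    normalized = []
    for m in per_split:
        vals = m.values.copy()
        gap = vals.sum(axis=1)
        ok = gap.abs() > NORMALIZATION_EPS
        flagged.update(vals.index[~ok])
        vals.loc[ok] = vals.loc[ok].div(gap[ok], axis=0)
        normalized.append(vals)

    all_ids = sorted(set().union(*[m.values.index for m in per_split]))
    num = pd.DataFrame(0.0, index=all_ids, columns=features)
    den = pd.Series(0.0, index=all_ids)
    for wk, vals in zip(w, normalized):
        num.loc[vals.index] += wk * vals.values
        den.loc[vals.index] += wk
    out = num.div(den, axis=0)

    return AttributionMatrix(
        values=out,
        prior=float(np.average([m.prior for m in per_split], weights=w)),
        dataset_of=dict(per_split[0].dataset_of),
        mode=per_split[0].mode,
        flagged=sorted(flagged),
        split_weights=w.tolist(),
    )


# ---------------------------------------------------------------------------
# Significance rule and dataset contributions
# ---------------------------------------------------------------------------


def significant_features(mean_abs, coverage: float = 0.95) -> list:
    """Shortest prefix of features, sorted by descending mean |ΔP|, whose
    cumulative sum reaches ``coverage`` of the total.  Stable order for
    ties; all-zero input yields an empty list."""
    s = pd.Series(mean_abs, dtype=float)
    if (s < 0).any():
        raise DataError("mean |ΔP| values must be nonnegative")
    total = s.sum()
    if total == 0:
        return []
    ordered = s.sort_values(ascending=False, kind="stable")
    cum = ordered.cumsum()
    cutoff = int(np.searchsorted(cum.values, coverage * total - 1e-12)) + 1
    return list(ordered.index[:cutoff])


@dataclass
class ContributionProfile:
    fractions: pd.DataFrame          # samples × datasets, rows sum to 1
    flagged: list                    # samples with all-zero attributions
    cluster_labels: pd.Series | None = None
    chosen_k: int | None = None


def dataset_contributions(attr: AttributionMatrix) -> ContributionProfile:
    """Per-sample fraction of total |ΔP| contributed by each dataset."""
    missing_tag = [f for f in attr.feature_ids if f not in attr.dataset_of]
    if missing_tag:
        raise DataError(
            f"features without a dataset tag: {missing_tag[:3]}"
            + ("..." if len(missing_tag) > 3 else "")
        )
    absval = attr.values.abs()
    groups = absval.T.groupby(
        pd.Series({f: attr.dataset_of[f] for f in attr.feature_ids})
    ).sum().T
    totals = groups.sum(axis=1)
    flagged = list(groups.index[totals == 0])
    ok = totals > 0
    fractions = groups.loc[ok].div(totals[ok], axis=0)
    return ContributionProfile(fractions=fractions, flagged=flagged)


# ---------------------------------------------------------------------------
# Gap-statistic k-means clustering of contributions
# ---------------------------------------------------------------------------

CLUSTER_NAMES = {1: ["Low"], 2: ["Low", "High"], 3: ["Low", "Medium", "High"]}


def _inertia(X, k, seed, n_restarts=10):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return float(km.inertia_), labels, km.cluster_centers_


def gap_statistic(X, k_max: int, seed: int = 0, n_refs: int = 50):
    """Gap(k) = E*[log W_k] − log W_k with a uniform reference over the
    observed per-dimension range (B = ``n_refs`` draws)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < X.shape[1]:
        X = X.T if X.shape[1] > 1 and X.shape[0] == 1 else X
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    gaps = np.zeros(k_max)
    details = []
    for k in range(1, k_max + 1):
        w_k, labels, centers = _inertia(X, k, seed)
        ref_logs = []
        for b in range(n_refs):
            ref = rng.uniform(lo, hi, size=X.shape)
            w_ref, _, _ = _inertia(ref, k, seed, n_restarts=3)
            ref_logs.append(np.log(max(w_ref, 1e-300)))
        gaps[k - 1] = float(np.mean(ref_logs) - np.log(max(w_k, 1e-300)))
        details.append((labels, centers))
    return gaps, details


def cluster_contributions(fractions, k_max: int = 5, seed: int = 0,
                          n_refs: int = 50):
    """Cluster one dataset's contribution fractions; pick k by the gap
    statistic; name clusters by ascending mean (Low < Medium < High)."""
    x = np.asarray(fractions, dtype=float).reshape(-1, 1)
    if x.shape[0] < 2 * k_max:
        raise DataError(f"need at least {2 * k_max} samples for k_max={k_max}")
    if np.allclose(x, x[0]):
        names = pd.Series(["Low"] * len(x))
        return names, 1, np.zeros(k_max)
    gaps, details = gap_statistic(x, k_max, seed=seed, n_refs=n_refs)
    k = int(np.argmax(gaps)) + 1
    labels, centers = details[k - 1]
    order = np.argsort(centers[:, 0])
    rank_of = {int(c): r for r, c in enumerate(order)}
    names_for_k = CLUSTER_NAMES.get(k, [f"L{r}" for r in range(k)])
    named = pd.Series([names_for_k[rank_of[int(l)]] for l in labels])
    return named, k, gaps


def cluster_from_meta_weight(weights, cluster_labels, low_label: str = "Low"):
    """Predict the binary Low vs Medium/High grouping from the clinical
    meta-learner weight.  Sweeps thresholds over the unique weights with
    the rule "Low iff weight ≤ t", returning the accuracy-maximizing
    threshold (ties resolve to the lower threshold) and its accuracy."""
    w = np.asarray(weights, dtype=float)
    is_low = np.asarray([l == low_label for l in cluster_labels])
    if is_low.all() or (~is_low).all():
        raise DataError("grouping must contain both Low and non-Low samples")
    best_t, best_acc = None, -1.0
    for t in np.unique(w):
        acc = float(((w <= t) == is_low).mean())
        if acc > best_acc + 1e-12:
            best_t, best_acc = float(t), acc
    return best_t, best_acc


# ---------------------------------------------------------------------------
# Interpretation statistics
# ---------------------------------------------------------------------------


def spearman_attr_value(attr_column, feature_values):
    """Spearman rank correlation (midrank ties) between a feature's ΔP
    column and its values across samples; pairs with a missing member are
    dropped.  Returns (rho, p); constant input yields (nan, nan)."""
    a = np.asarray(attr_column, dtype=float)
    v = np.asarray(feature_values, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(v))
    if ok.sum() < 3:
        raise DataError("need at least 3 non-missing pairs")
    a, v = a[ok], v[ok]
    if np.all(a == a[0]) or np.all(v == v[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(a, v)
    return float(rho), float(p)


def enrichment_test(significant, sets: AnnotationSets) -> pd.DataFrame:
    """Per-set over-representation of the significant features.

    2×2 table (in/out of set × in/out of significant) tested by χ² with
    Yates' continuity correction (clamped at zero), two-sided p from the
    χ²(1) distribution.
    """
    significant = set(significant)
    universe = set(sets.universe)
    if not universe:
        raise DataError("empty universe")
    stray = significant - universe
    if stray:
        raise DataError(f"significant features outside the universe: {sorted(stray)[:3]}")
    rows = []
    for name, members in sets.sets.items():
        members = set(members) & universe
        if not members:
            raise DataError(f"set {name!r} disjoint from the universe")
        a = len(members & significant)
        b = len(members - significant)
        c = len(significant - members)
        d = len(universe) - a - b - c
        n = a + b + c + d
        margins = (a + b) * (c + d) * (a + c) * (b + d)
        if margins == 0:
            chi2, p = 0.0, 1.0
        else:
            num = max(abs(a * d - b * c) - n / 2.0, 0.0)
            chi2 = n * num * num / margins
            p = float(stats.chi2.sf(chi2, df=1))
        expected = (a + b) * (a + c) / n
        rows.append({
            "set": name, "overlap": a, "set_size": len(members),
            "expected": expected, "chi2": chi2, "p": p,
        })
    return pd.DataFrame(rows).set_index("set")


def overlap_representation(set1, set2, universe):
    """Representation factor and two-sided Fisher exact p for the overlap
    of two feature sets given a universe.

    rf = observed overlap / (|set1|·|set2| / |universe|); rf < 1 means the
    sets overlap less than expected under independence.
    """
    set1, set2, universe = set(set1), set(set2), set(universe)
    if not set1 or not set2:
        raise DataError("both sets must be non-empty")
    if not set1 <= universe or not set2 <= universe:
        raise DataError("sets must be subsets of the universe")
    n = len(universe)
    a = len(set1 & set2)
    expected = len(set1) * len(set2) / n
    rf = a / expected if expected > 0 else float("nan")
    table = [
        [a, len(set1) - a],
        [len(set2) - a, n - len(set1) - len(set2) + a],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(rf), float(p)
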