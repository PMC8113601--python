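"""Synthetic cohorts and toy networks with the structure the method assumes.

The multi-omics generator emulates a radiotherapy cohort: a 716:199
sensitive:resistant class imbalance, one feature table per dataset kind
(clinical with categorical columns and missingness, log-normal expression,
sparse binary mutations, continuous metabolite production), and a latent
subgroup structure in which each subgroup's radiation response is encoded
only in its assigned dataset.  Informative features play a dual role: they
separate the classes inside their subgroup (a mean shift of ``effect``
standard deviations, or an elevated mutation rate) and they carry a
subgroup offset for out-of-subgroup samples, so the optimal dataset for a
sample is recoverable from the features themselves — the structure the
meta-learner is designed to exploit.

The toy metabolic cohorts plant group-specific uptake-bound multipliers on
disjoint production pathways, so the log2 production ratio between groups
equals log2(multiplier) exactly by LP homogeneity (up to the optional
per-model jitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .attribution import DecisionTree, TreeEnsembleModel
from .core_data import (
    DataError,
    LabelVector,
    MetabolicNetworkModel,
    OmicsDataset,
    Reaction,
    one_hot_encode,
)

__all__ = [
    "DatasetSpec",
    "CohortConfig",
    "generate_multiomics_cohort",
    "base_toy_network",
    "generate_toy_model_cohort",
    "generate_chain_network",
    "random_chain_network",
    "generate_tiny_tree_model",
]

RESISTANT_FRACTION = 199 / 915   # the emulated cohort's class imbalance


# ---------------------------------------------------------------------------
# Multi-omics cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetSpec:
    kind: str                      # clinical | expression | mutation | metabolite
    n_features: int
    n_informative: int = 0
    effect: float = 2.0            # mean shift in SD (continuous) or elevated
                                   # mutation rate (binary datasets)
    n_categorical: int = 0         # clinical only
    n_markers: int = 2             # label-independent subgroup-marker features
    marker_shift: float = 2.0      # subgroup mean shift of marker features
    confound_shift: float | None = None  # shift of informative features for ALL
                                   # out-of-subgroup samples (defaults to
                                   # ``effect``): outside its subgroup the
                                   # feature looks "resistant" regardless of
                                   # label, so its meaning is context-dependent


@dataclass
class CohortConfig:
    n_samples: int = 240
    resistant_fraction: float = RESISTANT_FRACTION
    datasets: dict = field(default_factory=dict)
    blocks: list = field(default_factory=list)   # dataset name per latent subgroup
    clinical_missing_rate: float = 0.1
    mutation_base_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.resistant_fraction < 1:
            raise DataError("resistant_fraction must lie in (0, 1)")
        for d in self.blocks:
            if d not in self.datasets:
                raise DataError(f"block dataset {d!r} not among datasets")
        for name, spec in self.datasets.items():
            if spec.n_informative > spec.n_features:
                raise DataError(
                    f"dataset {name!r}: n_informative exceeds n_features"
                )

    @classmethod
    def default(cls, n_samples: int = 240, effect: float = 2.0,
                seed: int = 0) -> "CohortConfig":
        """Four-dataset cohort mirroring the clinical/expression/mutation/
        metabolite structure, with expression and metabolite each carrying
        one subgroup's signal."""
        return cls(
            n_samples=n_samples,
            datasets={
                "clinical": DatasetSpec("clinical", 10, n_informative=2,
                                        effect=effect, n_categorical=3),
                "expression": DatasetSpec("expression", 60, n_informative=8,
                                          effect=effect),
                "mutation": DatasetSpec("mutation", 40, n_informative=6,
                                        effect=0.4),
                "metabolite": DatasetSpec("metabolite", 30, n_informative=6,
                                          effect=effect),
            },
            blocks=["expression", "metabolite"],
            seed=seed,
        )

    @classmethod
    def block_cohort(cls, n_samples: int = 240, effect: float = 2.0,
                     n_features: int = 120, n_informative: int = 8,
                     seed: int = 0) -> "CohortConfig":
        """Two continuous datasets, each informative only for one of two
        disjoint latent subgroups — the structure behind the
        ensemble-versus-combined architecture comparison."""
        return cls(
            n_samples=n_samples,
            datasets={
                "expression": DatasetSpec("expression", n_features,
                                          n_informative=n_informative,
                                          effect=effect),
                "metabolite": DatasetSpec("metabolite", n_features,
                                          n_informative=n_informative,
                                          effect=effect),
            },
            blocks=["expression", "metabolite"],
            seed=seed,
        )


def _exact_fraction_labels(n: int, fraction: float, rng) -> np.ndarray:
    n_pos = int(round(n * fraction))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    return y


def generate_multiomics_cohort(config: CohortConfig):
    """Generate (bundle, labels, manifest) for the configured cohort.

    Returns the per-dataset :class:`OmicsDataset` bundle (clinical table
    already one-hot encoded), the label vector with w_R, and a manifest
    recording every planted informative feature, the subgroup assignment
    and effect sizes.  Byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    y = _exact_fraction_labels(n, config.resistant_fraction, rng)

    n_groups = max(len(config.blocks), 1)
    subgroup = rng.permutation(np.arange(n) % n_groups)
    informative_of_group = {g: config.blocks[g] for g in range(len(config.blocks))}

    bundle = {}
    manifest = {
        "seed": config.seed,
        "n_samples": n,
        "resistant_fraction": config.resistant_fraction,
        "subgroup_of": dict(zip(sample_ids, subgroup.tolist())),
        "informative_dataset_of_subgroup": {
            str(g): d for g, d in informative_of_group.items()
        },
        "informative_features": {},
        "effects": {},
        "categorical_columns": {},
    }

    for name, spec in config.datasets.items():
        own_groups = [g for g, d in informative_of_group.items() if d == name]
        in_subgroup = np.isin(subgroup, own_groups) if own_groups else np.ones(n, bool)
        if not config.blocks:
            in_subgroup = np.ones(n, dtype=bool)
        resistant_here = (y == 1) & in_subgroup

        if spec.kind == "mutation":
            base = config.mutation_base_rate
            M = (rng.random((n, spec.n_features)) < base).astype(float)
            feats = [f"{name}_g{j}" for j in range(spec.n_features)]
            info = feats[: spec.n_informative]
            for j in range(spec.n_informative):
                hit = rng.random(n) < spec.effect
                M[resistant_here & hit, j] = 1.0
            df = pd.DataFrame(M, index=sample_ids, columns=feats)
            manifest["effects"][name] = {"elevated_rate": spec.effect,
                                         "base_rate": base}
        else:
            Z = rng.normal(size=(n, spec.n_features))
            info_n = spec.n_informative
            if info_n:
                # label signal only inside the assigned subgroup
                Z[:, :info_n] += np.where(resistant_here, spec.effect, 0.0)[:, None]
                if own_groups and config.blocks:
                    # outside the subgroup the feature carries the same
                    # elevated values irrespective of response: its label
                    # meaning is conditional on context, which is what makes
                    # a per-dataset router valuable
                    conf = (spec.confound_shift
                            if spec.confound_shift is not None else spec.effect)
                    Z[:, :info_n] += np.where(in_subgroup, 0.0, conf)[:, None]
            n_mark = spec.n_markers if config.blocks else 0
            for j in range(n_mark):
                # subgroup markers: label-independent features encoding the
                # latent subgroup (marker j flags subgroup j mod n_groups) —
                # the information a router needs to pick the right dataset
                flag = subgroup == (j % n_groups)
                Z[:, info_n + j] += np.where(flag, spec.marker_shift, 0.0)
            feats = [f"{name}_f{j}" for j in range(spec.n_features)]
            info = feats[:info_n]
            if spec.kind == "expression":
                values = np.exp(Z)        # log-normal expression levels
            elif spec.kind == "metabolite":
                values = 5.0 + Z          # production rates around a plateau
            else:
                values = Z
            df = pd.DataFrame(values, index=sample_ids, columns=feats)
            manifest["effects"][name] = {"shift_sd": spec.effect,
                                         "marker_shift": spec.marker_shift}
            manifest.setdefault("marker_features", {})[name] = feats[
                info_n: info_n + n_mark
            ]

        categorical = []
        if spec.kind == "clinical" and spec.n_categorical:
            levels = ["ductal", "lobular", "mucinous", "other"]
            for c in range(spec.n_categorical):
                col = f"{name}_cat{c}"
                df[col] = rng.choice(levels[: 2 + c % 3], size=n)
                categorical.append(col)
        if spec.kind == "clinical" and config.clinical_missing_rate > 0:
            mask = rng.random(df.shape) < config.clinical_missing_rate
            df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))

        ds = OmicsDataset(name=name, kind=spec.kind, values=df,
                          provenance=f"synthetic seed={config.seed}")
        if categorical:
            ds = one_hot_encode(ds, categorical)
        bundle[name] = ds
        manifest["informative_features"][name] = info
        manifest["categorical_columns"][name] = categorical

    labels = LabelVector.from_labels(sample_ids, y)
    return bundle, labels, manifest


# ---------------------------------------------------------------------------
# Toy metabolic networks
# ---------------------------------------------------------------------------

# metabolite -> the uptake exchange that limits its production in the base
# toy network (disjoint pathways, so multipliers act independently)
LIMITING_EXCHANGE = {"lac": "EX_glc", "cit": "EX_gln"}


def base_toy_network(model_id: str = "toy") -> MetabolicNetworkModel:
    """Two-compartment toy network: glucose and glutamine uptake feed two
    disjoint pathways producing lactate (cytosol, yield 2) and citrate
    (mitochondria, yield 1).  Lactate also occurs in the mitochondria via a
    transporter, exercising multi-compartment sinks.  ``orphan_c`` has no
    producing reaction and ``glc`` is a media metabolite — the two planted
    ineligible screen candidates."""
    species = [
        ("glc_e", "e"), ("gln_e", "e"),
        ("glc_c", "c"), ("gln_c", "c"),
        ("lac_c", "c"), ("lac_m", "m"),
        ("cit_m", "m"),
        ("orphan_c", "c"),
    ]
    reactions = [
        Reaction("EX_glc", {"glc_e": -1.0}, -10.0, 1000.0, is_exchange=True),
        Reaction("EX_gln", {"gln_e": -1.0}, -10.0, 1000.0, is_exchange=True),
        Reaction("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, 1000.0),
        Reaction("T_gln", {"gln_e": -1.0, "gln_c": 1.0}, 0.0, 1000.0),
        Reaction("GLYC", {"glc_c": -1.0, "lac_c": 2.0}, 0.0, 1000.0),
        Reaction("CITS", {"gln_c": -1.0, "cit_m": 1.0}, 0.0, 1000.0),
        Reaction("T_lac", {"lac_c": -1.0, "lac_m": 1.0}, 0.0, 1000.0),
    ]
    return MetabolicNetworkModel(
        id=model_id, species=species, reactions=reactions,
        external_compartment="e",
    )


def generate_toy_model_cohort(n_per_group: int, planted: dict,
                              seed: int = 0, jitter: float = 0.0):
    """Two model cohorts with planted production differences.

    ``planted`` maps metabolite -> {group: bound multiplier}; the
    multiplier scales the uptake bound of the pathway feeding that
    metabolite in every model of the group, so the planted log2 production
    ratio is log2(m_resistant / m_sensitive) exactly (LP homogeneity).
    Optional multiplicative log-normal jitter (sigma ``jitter``) perturbs
    every bound of every model.  Returns ``{group: [models]}``.
    """
    for met, mult in planted.items():
        if met not in LIMITING_EXCHANGE:
            raise DataError(f"no planted pathway for metabolite {met!r}")
        if any(m <= 0 for m in mult.values()):
            raise DataError("bound multipliers must be positive")
    rng = np.random.default_rng(seed)
    cohorts = {}
    for group in ("sensitive", "resistant"):
        models = []
        for i in range(n_per_group):
            m = base_toy_network(model_id=f"{group}_{i:03d}")
            scale_of = {}
            for met, mult in planted.items():
                scale_of[LIMITING_EXCHANGE[met]] = mult.get(group, 1.0)
            new_reactions = []
            for r in m.reactions:
                s = scale_of.get(r.id, 1.0)
                if jitter > 0:
                    s *= float(np.exp(rng.normal(0.0, jitter)))
                lb = r.lb * s if np.isfinite(r.lb) else r.lb
                ub = r.ub * s if np.isfinite(r.ub) else r.ub
                new_reactions.append(replace(r, lb=lb, ub=ub))
            models.append(replace(m, reactions=new_reactions))
        cohorts[group] = models
    return cohorts


def generate_chain_network(chains, model_id: str = "chain"):
    """Build an acyclic 'bundle of chains' network.

    ``chains`` is a list of (uptake_bound, [(a, b, ub), ...]): each chain
    imports its own nutrient (uptake bound) and converts it through
    reactions ``a X_j -> b X_{j+1}`` (flux bound ub) into the shared target
    species ``target_c``.  Chains share no intermediates, so the LP
    optimum decomposes per chain — which is what makes an independent
    path-propagation oracle exact on these instances.
    """
    species = [("target_c", "c")]
    reactions = []
    for ci, (uptake, steps) in enumerate(chains):
        nutrient = f"n{ci}_e"
        species.append((nutrient, "e"))
        reactions.append(
            Reaction(f"EX_n{ci}", {nutrient: -1.0}, -float(uptake), 0.0,
                     is_exchange=True)
        )
        prev = nutrient
        for si, (a, b, ub) in enumerate(steps):
            out = "target_c" if si == len(steps) - 1 else f"x{ci}_{si}_c"
            if out != "target_c":
                species.append((out, "c"))
            reactions.append(
                Reaction(f"R{ci}_{si}", {prev: -float(a), out: float(b)},
                         0.0, float(ub))
            )
            prev = out
    return MetabolicNetworkModel(
        id=model_id, species=species, reactions=reactions,
        external_compartment="e",
    )


def random_chain_network(seed: int, max_chains: int = 3, max_steps: int = 3):
    """A random chain-bundle instance with at most 8 reactions.
    Returns (model, chains) so callers can evaluate the closed-form
    capacity independently of the LP."""
    rng = np.random.default_rng(seed)
    chains = []
    budget = 8
    n_chains = int(rng.integers(1, max_chains + 1))
    for _ in range(n_chains):
        steps_left = budget - sum(1 + len(s) for _, s in chains)
        if steps_left < 2:
            break
        n_steps = int(rng.integers(1, min(max_steps, steps_left - 1) + 1))
        uptake = float(np.round(rng.uniform(1.0, 10.0), 3))
        steps = [
            (int(rng.integers(1, 3)), int(rng.integers(1, 3)),
             float(np.round(rng.uniform(1.0, 10.0), 3)))
            for _ in range(n_steps)
        ]
        chains.append((uptake, steps))
    return generate_chain_network(chains, model_id=f"chain_{seed}"), chains


# ---------------------------------------------------------------------------
# Tiny tree ensembles (attribution oracle fixtures)
# ---------------------------------------------------------------------------


def _random_tree(rng, n_features: int, depth: int) -> DecisionTree:
    feature, threshold, left, right, value, missing_left = [], [], [], [], [], []

    def grow(level: int) -> int:
        idx = len(feature)
        feature.append(-1); threshold.append(0.0); left.append(0)
        right.append(0); value.append(0.0); missing_left.append(True)
        if level >= depth or rng.random() < 0.25:
            value[idx] = float(rng.uniform(0.05, 0.95))
            return idx
        feature[idx] = int(rng.integers(n_features))
        threshold[idx] = float(rng.uniform(-1.0, 1.0))
        missing_left[idx] = bool(rng.random() < 0.5)
        left[idx] = grow(level + 1)
        right[idx] = grow(level + 1)
        return idx

    grow(0)
    return DecisionTree(
        np.array(feature), np.array(threshold), np.array(left),
        np.array(right), np.array(value), np.array(missing_left),
    )


def generate_tiny_tree_model(n_features: int, n_trees: int = 3,
                             depth: int = 3, seed: int = 0) -> TreeEnsembleModel:
    """Random probability-leaf forest small enough for exhaustive Shapley
    enumeration (depth ≤ 3)."""
    if depth > 3:
        raise DataError("tiny tree models are limited to depth <= 3")
    rng = np.random.default_rng(seed)
    trees = [_random_tree(rng, n_features, depth) for _ in range(n_trees)]
    return TreeEnsembleModel(
        trees=trees, feature_names=[f"x{j}" for j in range(n_features)],
        aggregation="mean",
    )
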