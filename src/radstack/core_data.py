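"""Core data model and IO for the radiation-response pipeline.

Holds the per-dataset feature tables (clinical, expression, mutation,
metabolite), the binary response labels derived from RECIST records, the
compartmentalized stoichiometric network used by the FBA screen, and the
annotation sets used for enrichment.  Missing values are represented by a
single sentinel, ``numpy.nan``, throughout: the gradient-boosted learners
downstream consume missingness natively, so no imputation happens here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DATASET_KINDS",
    "OmicsDataset",
    "LabelVector",
    "ResponseRecord",
    "Reaction",
    "MetabolicNetworkModel",
    "AnnotationSets",
    "assign_labels",
    "one_hot_encode",
    "filter_low_information",
    "read_feature_table",
    "write_feature_table",
    "read_column_types",
    "read_json_model",
    "write_json_model",
    "read_sbml_model",
    "write_sbml_model",
    "read_gmt",
    "write_gmt",
    "read_media_list",
    "write_media_list",
]

DATASET_KINDS = ("clinical", "expression", "mutation", "metabolite")

RECIST_SENSITIVE = frozenset({"complete", "partial"})
RECIST_RESISTANT = frozenset({"stable", "progressive"})


class DataError(ValueError):
    """Raised when an input violates a structural contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OmicsDataset:
    """One named feature table: samples in rows, features in columns.

    Parameters
    ----------
    name : str
        Dataset identifier (e.g. ``"clinical"``).
    kind : str
        One of :data:`DATASET_KINDS`.
    values : pandas.DataFrame
        Real-valued matrix indexed by sample id, columns are feature ids.
        Missing entries are ``numpy.nan``.
    provenance : str
        Free-text source tag.
    """

    name: str
    kind: str
    values: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind not in DATASET_KINDS:
            raise DataError(
                f"dataset {self.name!r}: kind {self.kind!r} not in {DATASET_KINDS}"
            )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataError(f"dataset {self.name!r}: duplicate sample id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DataError(f"dataset {self.name!r}: duplicate feature id {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def matrix(self) -> np.ndarray:
        """Float matrix with nan for missing values."""
        return self.values.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "OmicsDataset":
        return replace(self, values=self.values.loc[list(sample_ids)])


@dataclass
class LabelVector:
    """Binary response labels: 0 = sensitive, 1 = resistant.

    ``w_R`` is the class weight applied to resistant samples in the
    weighted log loss, equal to (#sensitive)/(#resistant).
    """

    sample_ids: list[str]
    y: np.ndarray
    w_R: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.sample_ids) != len(self.y):
            raise DataError("sample_ids and y length mismatch")
        if not np.isin(self.y, (0, 1)).all():
            raise DataError("labels must be 0 (sensitive) or 1 (resistant)")
        if self.w_R <= 0:
            raise DataError("w_R must be positive")

    @classmethod
    def from_labels(cls, sample_ids, y) -> "LabelVector":
        y = np.asarray(y, dtype=int)
        n_res = int((y == 1).sum())
        n_sen = int((y == 0).sum())
        if n_res == 0 or n_sen == 0:
            raise DataError("both classes must be present to compute w_R")
        return cls(list(sample_ids), y, n_sen / n_res)

    def subset(self, sample_ids) -> "LabelVector":
        """Labels restricted to ``sample_ids``; w_R is kept from the parent cohort."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return LabelVector(list(sample_ids), self.y[idx], self.w_R)

    def to_series(self) -> pd.Series:
        return pd.Series(self.y, index=self.sample_ids, name="y")


@dataclass(frozen=True)
class ResponseRecord:
    """One course of radiation therapy with its RECIST category."""

    sample_id: str
    course_index: int
    recist_category: str

    def __post_init__(self) -> None:
        if self.course_index < 1:
            raise DataError(
                f"record {self.sample_id!r}: course_index must be >= 1"
            )


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoich`` maps species id -> coefficient (negative = consumed).
    Exchange reactions move a single external species across the system
    boundary; by convention their stoichiometry is ``{species: -1}`` so a
    negative flux is uptake and a positive flux is secretion.
    """

    id: str
    stoich: dict
    lb: float
    ub: float
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise DataError(f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}")


@dataclass
class MetabolicNetworkModel:
    """Compartmentalized stoichiometric model with flux bounds.

    ``species`` is a list of (species id, compartment id).  Species ids
    follow the usual ``met_c`` / ``met_e`` suffix style but the compartment
    is stored explicitly; nothing is inferred from the id string.
    """

    id: str
    species: list
    reactions: list
    external_compartment: str = "e"
    objective: str | None = None

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.species]
        if len(set(ids)) != len(ids):
            raise DataError(f"model {self.id!r}: duplicate species ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise DataError(f"model {self.id!r}: duplicate reaction ids")
        declared = set(ids)
        for r in self.reactions:
            for s in r.stoich:
                if s not in declared:
                    raise DataError(
                        f"model {self.id!r}: reaction {r.id!r} references "
                        f"undeclared species {s!r}"
                    )

    @property
    def compartment_of(self) -> dict:
        return dict(self.species)

    def species_in_compartments(self, metabolite: str) -> dict:
        """Map compartment -> species id for every species whose base name
        (id with the trailing ``_<compartment>`` stripped, if present)
        or full id equals ``metabolite``."""
        out = {}
        for sid, comp in self.species:
            base = sid[: -(len(comp) + 1)] if sid.endswith("_" + comp) else sid
            if metabolite in (sid, base):
                out[comp] = sid
        return out

    def exchange_reactions(self) -> list:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicNetworkModel":
        return MetabolicNetworkModel(
            id=self.id,
            species=list(self.species),
            reactions=[replace(r, stoich=dict(r.stoich)) for r in self.reactions],
            external_compartment=self.external_compartment,
            objective=self.objective,
        )


@dataclass
class AnnotationSets:
    """Named feature-id sets over a declared universe (GMT-style)."""

    universe: set
    sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) < 1:
                raise DataError(f"annotation set {name!r} is empty")


# ---------------------------------------------------------------------------
# Label mapping
# ---------------------------------------------------------------------------


def assign_labels(records) -> LabelVector:
    """Map RECIST response records to binary labels.

    Each sample is classified by the record with the minimal course index
    (the first course of radiation therapy): complete/partial response ->
    0 (sensitive), stable/progressive disease -> 1 (resistant).  The
    resistant-class weight w_R is computed from the resulting labels.
    """
    by_sample: dict[str, ResponseRecord] = {}
    for rec in records:
        cat = rec.recist_category
        if cat not in RECIST_SENSITIVE and cat not in RECIST_RESISTANT:
            raise DataError(
                f"record {rec.sample_id!r} course {rec.course_index}: "
                f"unknown RECIST category {cat!r}"
            )
        cur = by_sample.get(rec.sample_id)
        if cur is None or rec.course_index < cur.course_index:
            by_sample[rec.sample_id] = rec
    if not by_sample:
        raise DataError("no response records supplied")
    sample_ids = sorted(by_sample)
    y = np.array(
        [0 if by_sample[s].recist_category in RECIST_SENSITIVE else 1
         for s in sample_ids],
        dtype=int,
    )
    return LabelVector.from_labels(sample_ids, y)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def one_hot_encode(dataset: OmicsDataset, categorical) -> OmicsDataset:
    """Expand each declared categorical column into one indicator per level.

    Indicators are named ``column=level``.  A missing source value yields
    missing (nan) in *all* derived indicators — not zero — so downstream
    tree learners can branch on absence.  Non-categorical columns pass
    through unchanged; an empty categorical set is a no-op.
    """
    categorical = [c for c in categorical]
    unknown = set(categorical) - set(dataset.values.columns)
    if unknown:
        raise DataError(
            f"dataset {dataset.name!r}: categorical columns not present: "
            f"{sorted(unknown)}"
        )
    if not categorical:
        return dataset

    pieces = []
    for col in dataset.values.columns:
        if col not in categorical:
            pieces.append(dataset.values[[col]].astype(float))
            continue
        src = dataset.values[col]
        levels = sorted({str(v) for v in src[src.notna()]})
        block = pd.DataFrame(index=dataset.values.index, dtype=float)
        for lev in levels:
            ind = (src.astype("string") == lev).astype(float)
            ind[src.isna()] = np.nan
            block[f"{col}={lev}"] = ind
        pieces.append(block)
    out = pd.concat(pieces, axis=1)
    return replace(dataset, values=out)


def filter_low_information(dataset: OmicsDataset):
    """Keep only features with at least two unique non-missing values.

    Returns ``(filtered_dataset, dropped_feature_ids)``; column order is
    preserved.  Idempotent.  Raises if every feature would be dropped.
    """
    keep, dropped = [], []
    for col in dataset.values.columns:
        vals = dataset.values[col]
        if vals[vals.notna()].nunique() >= 2:
            keep.append(col)
        else:
            dropped.append(col)
    if not keep:
        raise DataError(
            f"dataset {dataset.name!r}: all {len(dropped)} features have "
            "fewer than two unique non-missing values"
        )
    return replace(dataset, values=dataset.values[keep]), dropped


# ---------------------------------------------------------------------------
# Feature-table IO (TSV/CSV; first column = sample id, header = feature ids)
# ---------------------------------------------------------------------------


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_feature_table(path, kind, name=None, provenance=None) -> OmicsDataset:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"{path}: duplicate sample id {dup!r}")
    return OmicsDataset(
        name=name or str(path),
        kind=kind,
        values=df,
        provenance=provenance or str(path),
    )


def write_feature_table(dataset: OmicsDataset, path) -> None:
    dataset.values.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_column_types(path) -> list:
    """Read the column-type sidecar (JSON) listing categorical columns.

    Accepts either ``{"categorical": [...]}`` or a flat
    ``{"column": "categorical"|"numeric"}`` map.
    """
    with open(path) as fh:
        obj = json.load(fh)
    if isinstance(obj, dict) and "categorical" in obj:
        return list(obj["categorical"])
    if isinstance(obj, dict):
        return [c for c, t in obj.items() if t == "categorical"]
    raise DataError(f"{path}: unrecognized column-type sidecar structure")


# ---------------------------------------------------------------------------
# Metabolic model IO — JSON dialect
# ---------------------------------------------------------------------------


def read_json_model(path) -> MetabolicNetworkModel:
    """Read a model in the package's JSON dialect.

    Schema::

        {"id": ..., "external_compartment": ...,
         "species": [{"id": ..., "compartment": ...}, ...],
         "reactions": [{"id": ..., "stoich": {species: coeff, ...},
                        "lb": ..., "ub": ..., "exchange": bool}, ...],
         "objective": optional reaction id}
    """
    with open(path) as fh:
        obj = json.load(fh)
    try:
        species = [(s["id"], s["compartment"]) for s in obj["species"]]
        reactions = [
            Reaction(
                id=r["id"],
                stoich={k: float(v) for k, v in r["stoich"].items()},
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                is_exchange=bool(r.get("exchange", False)),
            )
            for r in obj["reactions"]
        ]
    except KeyError as exc:
        raise DataError(f"{path}: missing required model key {exc}") from exc
    return MetabolicNetworkModel(
        id=obj.get("id", str(path)),
        species=species,
        reactions=reactions,
        external_compartment=obj.get("external_compartment", "e"),
        objective=obj.get("objective"),
    )


def write_json_model(model: MetabolicNetworkModel, path) -> None:
    obj = {
        "id": model.id,
        "external_compartment": model.external_compartment,
        "species": [{"id": s, "compartment": c} for s, c in model.species],
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoich,
                "lb": r.lb,
                "ub": r.ub,
                "exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
    }
    if model.objective is not None:
        obj["objective"] = model.objective
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Metabolic model IO — SBML Level 3 with the fbc package
# ---------------------------------------------------------------------------


def read_sbml_model(path) -> MetabolicNetworkModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise DataError(f"{path}: SBML parse error: {err.getMessage().strip()}")
    sbml = doc.getModel()
    if sbml is None:
        raise DataError(f"{path}: no model element")

    compartments = {c.getId() for c in sbml.getListOfCompartments()}
    species = []
    for sp in sbml.getListOfSpecies():
        if sp.getCompartment() not in compartments:
            raise DataError(
                f"{path}: species {sp.getId()!r} in unknown compartment "
                f"{sp.getCompartment()!r}"
            )
        species.append((sp.getId(), sp.getCompartment()))

    def _param(pid):
        p = sbml.getParameter(pid)
        if p is None:
            raise DataError(f"{path}: flux-bound parameter {pid!r} not found")
        return p.getValue()

    reactions = []
    for rx in sbml.getListOfReactions():
        stoich: dict[str, float] = {}
        for i in range(rx.getNumReactants()):
            ref = rx.getReactant(i)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for i in range(rx.getNumProducts()):
            ref = rx.getProduct(i)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        fbc = rx.getPlugin("fbc")
        if fbc is not None and fbc.isSetLowerFluxBound():
            lb = _param(fbc.getLowerFluxBound())
            ub = _param(fbc.getUpperFluxBound())
        else:
            lb = -1000.0 if rx.getReversible() else 0.0
            ub = 1000.0
        reactions.append(
            Reaction(
                id=rx.getId(),
                stoich=stoich,
                lb=lb,
                ub=ub,
                is_exchange=rx.getId().startswith("EX_") or len(stoich) == 1,
            )
        )

    objective = None
    mfbc = sbml.getPlugin("fbc")
    if mfbc is not None and mfbc.getNumObjectives() > 0:
        active = mfbc.getActiveObjective()
        if active is not None and active.getNumFluxObjectives() > 0:
            objective = active.getFluxObjective(0).getReaction()

    external = "e" if "e" in compartments else (
        sorted(compartments)[0] if compartments else "e"
    )
    return MetabolicNetworkModel(
        id=sbml.getId() or str(path),
        species=species,
        reactions=reactions,
        external_compartment=external,
        objective=objective,
    )


def write_sbml_model(model: MetabolicNetworkModel, path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml = doc.createModel()
    sbml.setId(model.id)
    mfbc = sbml.getPlugin("fbc")
    mfbc.setStrict(True)

    comps = sorted({c for _, c in model.species} | {model.external_compartment})
    for c in comps:
        comp = sbml.createCompartment()
        comp.setId(c)
        comp.setConstant(True)

    for sid, c in model.species:
        sp = sbml.createSpecies()
        sp.setId(sid)
        sp.setCompartment(c)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)

    bounds: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bounds:
            pid = f"fb_{len(bounds)}"
            par = sbml.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bounds[value] = pid
        return bounds[value]

    for r in model.reactions:
        rx = sbml.createReaction()
        rx.setId(r.id)
        rx.setReversible(r.lb < 0)
        rx.setFast(False)
        for sid, coeff in r.stoich.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(float(r.lb)))
        rfbc.setUpperFluxBound(_bound_param(float(r.ub)))

    if model.objective is not None:
        obj = mfbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective)
        fo.setCoefficient(1.0)
        mfbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise DataError(f"failed to write SBML to {path}")


# ---------------------------------------------------------------------------
# GMT annotation sets & media lists
# ---------------------------------------------------------------------------


def read_gmt(path, universe=None) -> AnnotationSets:
    """Read GMT: one set per line, ``name <TAB> description <TAB> members...``.

    If ``universe`` is None it defaults to the union of all members.
    """
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, members = parts[0], set(parts[2:]) - {""}
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise DataError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return AnnotationSets(universe=set(universe), sets=sets)


def write_gmt(annotations: AnnotationSets, path) -> None:
    with open(path, "w") as fh:
        for name, members in annotations.sets.items():
            fh.write("\t".join([name, ""] + sorted(members)) + "\n")


def read_media_list(path) -> list:
    """One metabolite id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_media_list(media, path) -> None:
    with open(path, "w") as fh:
        for m in media:
            fh.write(str(m) + "\n")
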