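"""Genome-scale metabolite-production screen by flux balance analysis.

For each candidate metabolite an artificial sink reaction ``1 met -> ∅`` is
added in every cellular compartment where the species occurs; maximizing
the summed sink flux under steady state (S v = 0) and the flux bounds gives
the network's maximal production capacity for that metabolite.  Candidates
already supplied by the extracellular media, and candidates that cannot be
produced by every model in the cohort, are excluded before the screen.
Cohort contrasts are reported as log2 ratios of mean production between
groups with two-sided t-tests.

LPs are solved with scipy's HiGHS interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

from .core_data import DataError, MetabolicNetworkModel, Reaction

__all__ = [
    "SinkObjective",
    "FluxResult",
    "ProductionMatrix",
    "apply_media",
    "add_sink",
    "max_production",
    "production_screen",
    "cohort_contrast",
]

PRODUCIBLE_TOL = 1e-9    # flux above this counts as producible
PSEUDO_FLUX = 1e-6       # added to both group means before the log2 ratio
DEFAULT_UPTAKE = 1000.0


def _base_name(species_id: str, compartment: str) -> str:
    suffix = "_" + compartment
    return species_id[: -len(suffix)] if species_id.endswith(suffix) else species_id


# ---------------------------------------------------------------------------
# Media constraints
# ---------------------------------------------------------------------------


def apply_media(model: MetabolicNetworkModel, media,
                uptake_bound: float = DEFAULT_UPTAKE):
    """Open uptake only for exchange reactions of media metabolites.

    For every exchange reaction whose species matches a media metabolite
    (by full species id or by base name without the compartment suffix),
    uptake is opened: an already-negative lower bound is kept — it encodes
    the model's own uptake capacity — and a closed one is set to
    ``-uptake_bound``.  All other exchanges get their uptake closed (lower
    bound 0).  Secretion (upper) bounds are untouched.  Media entries with
    no matching exchange are skipped and reported.  Idempotent.

    Returns ``(constrained_model, skipped_media_ids)``.
    """
    media = [str(m) for m in media]
    exchanges = model.exchange_reactions()
    if not exchanges:
        raise DataError(f"model {model.id!r} has no identified exchange reactions")
    comp_of = model.compartment_of
    matched = set()
    new_reactions = []
    for r in model.reactions:
        if not r.is_exchange:
            new_reactions.append(r)
            continue
        names = set()
        for sid in r.stoich:
            names.add(sid)
            names.add(_base_name(sid, comp_of[sid]))
        hit = names & set(media)
        if hit:
            matched.update(hit)
            new_lb = r.lb if r.lb < 0 else -abs(uptake_bound)
            new_reactions.append(replace(r, lb=new_lb))
        else:
            new_reactions.append(replace(r, lb=max(r.lb, 0.0)))
    skipped = [m for m in media if m not in matched]
    out = replace(model, reactions=new_reactions)
    return out, skipped


# ---------------------------------------------------------------------------
# Artificial sinks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SinkObjective:
    metabolite: str
    compartments: tuple
    sink_reaction_ids: tuple


def add_sink(model: MetabolicNetworkModel, metabolite: str):
    """Add one irreversible sink per non-external compartment holding the
    metabolite; the screen objective is the sum of the sink fluxes.  The
    source model is left untouched."""
    occupied = {
        comp: sid
        for comp, sid in model.species_in_compartments(metabolite).items()
        if comp != model.external_compartment
    }
    if not occupied:
        raise DataError(
            f"metabolite {metabolite!r} not found in any non-external "
            f"compartment of model {model.id!r}"
        )
    new = model.copy()
    sink_ids = []
    for comp in sorted(occupied):
        sid = occupied[comp]
        rid = f"SINK_{sid}"
        if any(r.id == rid for r in new.reactions):
            raise DataError(f"sink reaction id {rid!r} already present")
        new.reactions.append(
            Reaction(id=rid, stoich={sid: -1.0}, lb=0.0, ub=np.inf,
                     is_exchange=False)
        )
        sink_ids.append(rid)
    new.species = list(new.species)
    obj = SinkObjective(metabolite, tuple(sorted(occupied)), tuple(sink_ids))
    return new, obj


# ---------------------------------------------------------------------------
# LP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluxResult:
    status: str            # "optimal" | "infeasible" | "unbounded"
    flux: float

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _solve_max(model: MetabolicNetworkModel, objective_reactions) -> FluxResult:
    species_idx = {sid: i for i, (sid, _) in enumerate(model.species)}
    n_s, n_r = len(model.species), len(model.reactions)
    S = np.zeros((n_s, n_r))
    bounds = []
    c = np.zeros(n_r)
    obj = set(objective_reactions)
    for j, r in enumerate(model.reactions):
        for sid, coeff in r.stoich.items():
            S[species_idx[sid], j] = coeff
        bounds.append((None if np.isneginf(r.lb) else r.lb,
                       None if np.isposinf(r.ub) else r.ub))
        if r.id in obj:
            c[j] = -1.0  # linprog minimizes
    res = linprog(c, A_eq=S, b_eq=np.zeros(n_s), bounds=bounds, method="highs")
    if res.status == 0:
        return FluxResult("optimal", max(float(-res.fun), 0.0))
    if res.status == 2:
        return FluxResult("infeasible", float("nan"))
    if res.status == 3:
        return FluxResult("unbounded", float("inf"))
    raise DataError(
        f"LP solver failure on model {model.id!r}: {res.message}"
    )


def max_production(model: MetabolicNetworkModel, metabolite: str) -> FluxResult:
    """Maximal summed sink flux for the metabolite across its compartments."""
    sunk, obj = add_sink(model, metabolite)
    try:
        return _solve_max(sunk, obj.sink_reaction_ids)
    except DataError as exc:
        raise DataError(f"{exc} (metabolite {metabolite!r})") from exc


# ---------------------------------------------------------------------------
# Cohort screen
# ---------------------------------------------------------------------------


@dataclass
class ProductionMatrix:
    """Maximal production fluxes, models × metabolites, plus group labels
    and the eligibility report of excluded candidates."""

    values: pd.DataFrame
    groups: dict
    report: pd.DataFrame


def production_screen(models, candidates, media=None, groups=None,
                      tol: float = PRODUCIBLE_TOL) -> ProductionMatrix:
    """Evaluate maximal production of each eligible candidate in each model.

    Eligibility: a candidate is dropped if it appears in the supplied media
    list, or if any model in the cohort cannot produce it (flux ≤ ``tol``,
    infeasible, or the species is absent).  Exclusions are recorded with
    their reason in the report.
    """
    media = set(str(m) for m in (media or []))
    groups = dict(groups or {})
    report_rows = []
    eligible = []
    for met in candidates:
        if str(met) in media:
            report_rows.append({"metabolite": met, "excluded": True,
                                "reason": "present in extracellular media"})
            continue
        eligible.append(met)

    fluxes: dict[str, dict[str, float]] = {m.id: {} for m in models}
    surviving = []
    for met in eligible:
        ok = True
        reason = ""
        col = {}
        for model in models:
            try:
                res = max_production(model, met)
            except DataError:
                ok, reason = False, f"absent from model {model.id}"
                break
            if not res.ok or res.flux <= tol:
                ok = False
                reason = (
                    f"{res.status} in model {model.id}"
                    if not res.ok else
                    f"not producible by model {model.id} (flux {res.flux:.3g})"
                )
                break
            col[model.id] = res.flux
        if ok:
            surviving.append(met)
            for mid, f in col.items():
                fluxes[mid][met] = f
            report_rows.append({"metabolite": met, "excluded": False,
                                "reason": ""})
        else:
            report_rows.append({"metabolite": met, "excluded": True,
                                "reason": reason})
    report = pd.DataFrame(report_rows)
    if not surviving:
        raise DataError(
            "no candidate metabolite survived eligibility filtering:\n"
            + report.to_string(index=False)
        )
    values = pd.DataFrame(
        [[fluxes[m.id][met] for met in surviving] for m in models],
        index=[m.id for m in models],
        columns=surviving,
    )
    return ProductionMatrix(values=values, groups=groups, report=report)


def cohort_contrast(production: ProductionMatrix, groups=None,
                    group_pair=("resistant", "sensitive")) -> pd.DataFrame:
    """Per-metabolite log2 ratio of mean production between two groups,
    with a two-sided two-sample t-test on the per-model values.

    A pseudo-flux of 1e−6 is added to both means before the ratio; it only
    guards numerics because unproducible metabolites were already screened
    out.  Identical zero-variance groups report ratio 0, p = 1.
    """
    groups = dict(groups or production.groups)
    num_label, den_label = group_pair
    num_ids = [m for m, g in groups.items() if g == num_label]
    den_ids = [m for m, g in groups.items() if g == den_label]
    if not num_ids or not den_ids:
        raise DataError(f"both groups {group_pair} must be non-empty")
    rows = []
    for met in production.values.columns:
        a = production.values.loc[num_ids, met].to_numpy(float)
        b = production.values.loc[den_ids, met].to_numpy(float)
        ratio = float(np.log2((a.mean() + PSEUDO_FLUX) / (b.mean() + PSEUDO_FLUX)))
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            ratio, p = 0.0, 1.0
        else:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                t = stats.ttest_ind(a, b)
            p = float(t.pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({
            "metabolite": met,
            f"mean_{num_label}": a.mean(),
            f"mean_{den_label}": b.mean(),
            "log2_ratio": ratio,
            "p": p,
        })
    return pd.DataFrame(rows).set_index("metabolite")
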