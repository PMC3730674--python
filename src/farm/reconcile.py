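"""Evidence-weighted reconciliation of growth/no-growth phenotypes.

When the model disagrees with an observed knockout phenotype, the
reconciler proposes the cheapest network edit that flips the in-silico
growth call:

* observed **viable**, predicted no-growth → suggest reactions to *add*
  from a candidate database (LP relaxation of the add-set MILP, with
  rounding and re-simulation);
* observed **inviable**, predicted growth → suggest reactions to
  *remove* from the model (an indicator MILP solved by iterative
  covering cuts, each cut re-checked by re-simulation).

"Cheapest" is measured by per-reaction weights with a maximum
a-posteriori flavor: ``w_r = −log(p_biochem · p_thermo ·
pathway_support)``, so independent evidence is additive and a fully
supported reaction costs nothing.  Manually curated reactions are never
candidates for removal.  Suggestions are ranked, never auto-applied:
acceptance is a manual-review decision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import dilution as dil
from .media import Media
from .model import (
    EvidenceRecord,
    MetabolicModel,
    ReactionRecord,
    V_MAX_DEFAULT,
    apply_knockout,
    split_reversible,
)
from .solve import limed_fba, solve_lp

logger = logging.getLogger(__name__)

#: Biomass-flux threshold separating viable from inviable calls.
VIABILITY_THRESHOLD = 0.02
#: Indicator-rounding threshold for the LP relaxation.
ROUND_THRESHOLD = 0.5
#: Flux treated as zero when extracting growth-supporting reaction sets.
FLUX_TOL = 1e-6
#: Deterministic lexicographic tie-break among equal-weight solutions.
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class Phenotype:
    """An observed knockout growth phenotype on a given medium."""

    genes: frozenset
    media: Optional[Media]
    observed: str  # "viable" | "inviable"
    name: str = ""


@dataclass
class Reconciliation:
    phenotype: Phenotype
    action: str  # "add" | "remove"
    suggestions: list = field(default_factory=list)  # [(reaction id, weight)]
    post_change_biomass: float = 0.0
    resolved: bool = False
    accepted: bool = False  # manual-review hook


def reaction_weight(ev: EvidenceRecord) -> float:
    """MAP-style weight ``−log(p_biochem · p_thermo · pathway_support)``."""
    for label, p in (("p_biochem", ev.p_biochem),
                     ("p_thermo", ev.p_thermo),
                     ("pathway_support", ev.pathway_support)):
        if not (0 < p <= 1):
            raise ValueError(f"{label} must lie in (0, 1], got {p}")
    return -math.log(ev.p_biochem * ev.p_thermo * ev.pathway_support)


def default_weights(reactions: Iterable[ReactionRecord]) -> dict:
    """Weights from attached evidence.

    A reaction without an evidence record gets the uninformative default
    ``pathway_support = 0.5`` (weight ln 2); a curated reaction weighs 0.
    """
    out = {}
    for rxn in reactions:
        ev = rxn.evidence or EvidenceRecord(pathway_support=0.5)
        out[rxn.id] = 0.0 if ev.curated else reaction_weight(ev)
    return out


def _tie_broken(weights: Mapping[str, float], ids: Sequence[str]) -> np.ndarray:
    order = {rid: k for k, rid in enumerate(sorted(ids))}
    return np.array([weights[r] + _TIE_EPS * order[r] for r in ids])


def _viable(model: MetabolicModel, media, threshold, v_max) -> float:
    sol = limed_fba(model, media, v_max=v_max)
    return sol.objective_value


# ---------------------------------------------------------------------------
# restore growth (additions, LP relaxation)
# ---------------------------------------------------------------------------

def restore_growth(model: MetabolicModel,
                   database: Sequence[ReactionRecord],
                   phenotype: Phenotype,
                   weights: Optional[Mapping[str, float]] = None,
                   threshold: float = VIABILITY_THRESHOLD,
                   v_max: float = V_MAX_DEFAULT,
                   round_threshold: float = ROUND_THRESHOLD,
                   max_iter: int = 20) -> Reconciliation:
    """Suggest a minimum-weight addition set that restores growth.

    Solves the LP relaxation ``min Σ w_r y_r`` over candidate indicators
    ``y_r ∈ [0,1]`` with candidate fluxes gated by ``v ≤ v_max·y`` and
    biomass held at the growth threshold under the dilution-aware
    constraints.  Because the gating scales indicators with flux, the
    relaxed optimum puts weight only on the cheapest adequate route;
    candidates are rounded in relative to the largest indicator
    (``y_r ≥ round_threshold · max y``), verified by re-simulation, and
    on failure the set is pinned and re-solved (lowering the relative
    cut when pinning makes no progress).
    """
    if phenotype.observed != "viable":
        raise ValueError("restore_growth applies to observed-viable phenotypes")
    base = apply_knockout(model, phenotype.genes)
    rec = Reconciliation(phenotype=phenotype, action="add")
    if _viable(base, phenotype.media, threshold, v_max) > threshold:
        raise ValueError("model already predicts growth for this phenotype")
    if weights is None:
        weights = default_weights(database)

    # merge candidates (respecting the phenotype's knockout on their GPRs)
    merged = base.copy()
    for cand in database:
        for met_id in cand.stoichiometry:
            if not merged.has_metabolite(met_id):
                raise KeyError(
                    f"candidate {cand.id!r} uses unknown metabolite {met_id!r}")
        merged.add_reaction(cand)
        merged.genes |= cand.gpr.genes()
    merged = apply_knockout(merged, phenotype.genes)

    from .media import apply_media
    irr = split_reversible(apply_media(merged, phenotype.media, v_max=v_max))
    spec = dil.compute_epsilon(irr, v_max=v_max)
    S_limed = dil.limed_matrix(irr, spec)
    n = len(irr.reactions)
    cand_ids = [r.id for r in database]
    k = len(cand_ids)
    cand_pos = {rid: i for i, rid in enumerate(cand_ids)}

    rows, cols, vals = [], [], []
    nrow = 0
    for j, rxn in enumerate(irr.reactions):
        parent = rxn.parent or rxn.id
        if parent in cand_pos:
            rows += [nrow, nrow]
            cols += [j, n + cand_pos[parent]]
            vals += [1.0, -v_max]
            nrow += 1
    A_ub = sparse.csr_matrix((vals, (rows, cols)), shape=(nrow, n + k))
    A_eq = sparse.hstack([S_limed, sparse.csr_matrix((S_limed.shape[0], k))])
    c = np.concatenate([np.zeros(n), _tie_broken(weights, cand_ids)])
    target = threshold * (1 + 1e-3)  # strictly above the viability cut

    forced: set = set()
    rel_cut = round_threshold
    for _ in range(max_iter):
        bounds = []
        for rxn in irr.reactions:
            lb = target if rxn.id == irr.objective else rxn.lower_bound
            bounds.append((lb, rxn.upper_bound))
        for rid in cand_ids:
            bounds.append((1.0, 1.0) if rid in forced else (0.0, 1.0))
        res, _ = solve_lp(c, A_ub=A_ub, b_ub=np.zeros(nrow),
                          A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
                          bounds=bounds)
        if res.status != 0:
            rec.resolved = False
            logger.info("no feasible addition set for %s", phenotype.name)
            return rec
        y = res.x[n:]
        y_max = max(float(np.max(y)), FLUX_TOL / v_max)
        chosen = forced | {rid for rid, yi in zip(cand_ids, y)
                           if yi >= rel_cut * y_max}
        trial = base.copy()
        for cand in database:
            if cand.id in chosen:
                trial.add_reaction(cand)
                trial.genes |= cand.gpr.genes()
        trial = apply_knockout(trial, phenotype.genes)
        biomass = _viable(trial, phenotype.media, threshold, v_max)
        if biomass > threshold:
            rec.suggestions = sorted(((rid, weights[rid]) for rid in chosen),
                                     key=lambda t: (t[1], t[0]))
            rec.post_change_biomass = biomass
            rec.resolved = True
            return rec
        if chosen == forced:
            # pinning made no progress: admit weaker flux-carriers
            rel_cut /= 10.0
            if rel_cut < FLUX_TOL:
                break
        forced = chosen
    rec.resolved = False
    return rec


# ---------------------------------------------------------------------------
# suppress growth (removals, MILP with covering cuts)
# ---------------------------------------------------------------------------

def suppress_growth(model: MetabolicModel,
                    phenotype: Phenotype,
                    weights: Optional[Mapping[str, float]] = None,
                    threshold: float = VIABILITY_THRESHOLD,
                    v_max: float = V_MAX_DEFAULT,
                    max_iter: int = 50) -> Reconciliation:
    """Suggest a minimum-weight removal set that abolishes growth.

    Curated reactions, the biomass reaction and exchange reactions are
    immutable.  The master problem is a binary covering MILP: each
    re-simulation of the edited model that still grows contributes a cut
    requiring at least one reaction of its flux support to be removed.
    The loop terminates with a verified cut set (max biomass below the
    threshold) or reports the phenotype unresolvable when growth flows
    entirely through immutable reactions.
    """
    if phenotype.observed != "inviable":
        raise ValueError("suppress_growth applies to observed-inviable phenotypes")
    base = apply_knockout(model, phenotype.genes)
    rec = Reconciliation(phenotype=phenotype, action="remove")
    if _viable(base, phenotype.media, threshold, v_max) <= threshold:
        raise ValueError("model already predicts no growth for this phenotype")

    removable = [r.id for r in base.reactions
                 if r.id != base.objective
                 and not r.is_exchange
                 and not (r.evidence is not None and r.evidence.curated)]
    if weights is None:
        weights = default_weights([base.reaction(r) for r in removable])
    w = _tie_broken(weights, removable)
    pos = {rid: i for i, rid in enumerate(removable)}

    cuts: list = []
    removal: set = set()
    for _ in range(max_iter):
        trial = base.copy()
        for rid in removal:
            rxn = trial.reaction(rid)
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        sol = limed_fba(trial, phenotype.media, v_max=v_max)
        if sol.objective_value <= threshold:
            rec.suggestions = sorted(((rid, weights[rid]) for rid in removal),
                                     key=lambda t: (t[1], t[0]))
            rec.post_change_biomass = sol.objective_value
            rec.resolved = True
            return rec
        support = [rid for rid in removable
                   if rid not in removal
                   and abs(sol.fluxes.get(rid, 0.0)) > FLUX_TOL]
        if not support:
            logger.info("growth for %s flows only through immutable reactions",
                        phenotype.name)
            rec.resolved = False
            return rec
        cuts.append(support)
        removal = _solve_covering(cuts, w, removable, pos)
        if removal is None:
            rec.resolved = False
            return rec
    rec.resolved = False
    return rec


def _solve_covering(cuts, w, removable, pos):
    k = len(removable)
    rows, cols = [], []
    for i, cut in enumerate(cuts):
        for rid in cut:
            rows.append(i)
            cols.append(pos[rid])
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(len(cuts), k))
    res = milp(w,
               constraints=[LinearConstraint(A, lb=1, ub=np.inf)],
               integrality=np.ones(k),
               bounds=Bounds(0, 1))
    if not res.success:
        return None
    return {rid for rid, yi in zip(removable, res.x) if yi > 0.5}


# ---------------------------------------------------------------------------
# applying a suggestion (for verification / review tooling)
# ---------------------------------------------------------------------------

def apply_reconciliation(model: MetabolicModel, rec: Reconciliation,
                         database: Sequence[ReactionRecord] = ()) -> MetabolicModel:
    """Return a copy of ``model`` with the suggested edit applied."""
    out = model.copy()
    chosen = {rid for rid, _ in rec.suggestions}
    if rec.action == "add":
        by_id = {r.id: r for r in database}
        for rid in sorted(chosen):
            out.add_reaction(by_id[rid])
            out.genes |= by_id[rid].gpr.genes()
    else:
        for rxn in out.reactions:
            if rxn.id in chosen:
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
    return out
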