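"""One-LP functional pruning of blocked reactions.

A blocked reaction can carry no flux under any nutrient condition.  The
textbook detector — flux variability analysis — costs one LP per
reaction.  The goal-programming alternative solved here finds the whole
unblocked set in a single compact LP: send flux through as many
reactions as possible given unlimited nutrients,

    max Σ_i t_i   s.t.   S_limed v = 0,  0 ≤ v ≤ v_max,
                          0 ≤ t_i ≤ 1,   t_i ≤ v_i / δ.

Once a reaction has reached flux δ its ``t_i`` saturates at 1 and the
optimizer is free to pursue the remaining goals, so at the optimum every
``t_i`` is (numerically) binary: 1 for reactions that can carry flux,
0 for blocked ones.  δ is the operational definition of "can carry
flux".  In a dilution-constrained model the smallest legitimate fluxes
are disposals through metabolite dilution, on the order of
``d_max / k`` (~1e-2 flux units); the default δ = 1e-4 sits two orders
of magnitude below that scale and three above solver feasibility
tolerances, so the goal LP and per-reaction flux maximization agree on
what is blocked.  Using the dilution-aware matrix ``S_limed``
penalizes input-free two-cycles such as a disconnected A↔B pair, whose
split children would otherwise look unblocked.  Simple-transport
self-cycles are exempt from dilution and therefore survive the LP; the
FVA cross-check (``fva_check=True``) catches them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse

from . import dilution as dil
from .media import open_all_exchanges
from .model import IrreversibleModel, MetabolicModel, V_MAX_DEFAULT, split_reversible
from .solve import solve_lp

logger = logging.getLogger(__name__)

#: t_i within this of 1 counts as unblocked.
T_TOL = 1e-6
#: Flux level at which a reaction counts as carrying flux (t saturates).
DELTA_DEFAULT = 1e-4


@dataclass
class PruneResult:
    unblocked: set
    blocked: set
    pruned_model: Optional[MetabolicModel] = None
    witness: dict = field(default_factory=dict)
    lp_solves: int = 0


def find_unblocked(model: IrreversibleModel,
                   spec: Optional[dil.DilutionSpec] = None,
                   v_max: float = V_MAX_DEFAULT,
                   delta: float = DELTA_DEFAULT,
                   tol: float = T_TOL) -> PruneResult:
    """Partition reactions into unblocked/blocked with one LP.

    ``model`` must be irreversible with nutrient exchanges already
    opened (only ``v_max`` caps them).  ``delta`` rescales the flux
    level at which a reaction counts as carrying flux (``t_i ≤ v_i/δ``).
    """
    if spec is None:
        spec = dil.compute_epsilon(model, v_max=v_max)
    n = len(model.reactions)
    S_limed = dil.limed_matrix(model, spec)
    m = S_limed.shape[0]
    # variables x = [v (n), t (n)]
    A_eq = sparse.hstack([S_limed, sparse.csr_matrix((m, n))]).tocsr()
    # t_i - v_i/delta <= 0
    A_ub = sparse.hstack([-sparse.eye(n) / delta, sparse.eye(n)]).tocsr()
    c = np.concatenate([np.zeros(n), -np.ones(n)])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    bounds += [(0.0, 1.0)] * n
    res, _ = solve_lp(c, A_ub=A_ub, b_ub=np.zeros(n),
                      A_eq=A_eq, b_eq=np.zeros(m), bounds=bounds)
    if res.status != 0:
        raise RuntimeError(f"goal program did not solve: {res.message}")
    v, t = res.x[:n], res.x[n:]
    unblocked = {r.id for r, ti in zip(model.reactions, t) if ti >= 1 - tol}
    blocked = {r.id for r in model.reactions} - unblocked
    witness = {r.id: float(vi) for r, vi in zip(model.reactions, v)}
    return PruneResult(unblocked=unblocked, blocked=blocked,
                       witness=witness, lp_solves=1)


def prune(model: MetabolicModel,
          spec: Optional[dil.DilutionSpec] = None,
          nutrients: str = "all",
          v_max: float = V_MAX_DEFAULT,
          fva_check: bool = False,
          remove_orphans: bool = True) -> PruneResult:
    """Remove blocked reactions from ``model``.

    With ``nutrients="all"`` every exchange is opened before the search
    (all extracellular metabolites treated as nutrients); with
    ``nutrients="media"`` the model's current exchange bounds stand.  A
    reversible reaction is removed only when both split directions are
    blocked; a single blocked direction tightens the corresponding
    bound to zero.  Metabolites orphaned by removal are dropped.
    ``fva_check=True`` re-derives the blocked set with the per-reaction
    FVA oracle and takes the union, catching exempt-transport
    self-cycles the single LP cannot penalize.
    """
    base = open_all_exchanges(model, v_max=v_max) if nutrients == "all" else model
    irr = split_reversible(base)
    if spec is None:
        spec = dil.compute_epsilon(irr, v_max=v_max)
    result = find_unblocked(irr, spec, v_max=v_max)
    blocked_children = set(result.blocked)
    if fva_check:
        # exempt-transport self-cycles carry flux in the limed irreversible
        # region, so they must be caught on the reversible plain matrix
        from .solve import fva_blocked_reversible
        oracle_parents = fva_blocked_reversible(base)
        extra = set()
        for pid in oracle_parents:
            for cid in irr.children_of(pid):
                if cid not in blocked_children:
                    extra.add(cid)
                blocked_children.add(cid)
        if extra:
            logger.info("FVA check blocked %d additional reaction(s): %s",
                        len(extra), sorted(extra))
        result.lp_solves += 2 * len(base.reactions)

    pruned = model.copy()
    removed = []
    kept = []
    for rxn in pruned.reactions:
        children = irr.children_of(rxn.id)
        child_blocked = [cid in blocked_children for cid in children]
        if all(child_blocked):
            if rxn.id == pruned.objective:
                raise ValueError(
                    "the biomass reaction itself is blocked: the model cannot "
                    "grow on any nutrient condition")
            removed.append(rxn.id)
            continue
        for cid, is_blocked in zip(children, child_blocked):
            if not is_blocked:
                continue
            if irr.reaction(cid).direction == "rev":
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
            else:
                rxn.upper_bound = min(rxn.upper_bound, 0.0)
        kept.append(rxn)
    pruned.reactions = kept
    pruned._reindex()

    if remove_orphans:
        used = {m for r in pruned.reactions for m in r.stoichiometry}
        orphans = [m.id for m in pruned.metabolites if m.id not in used]
        pruned.metabolites = [m for m in pruned.metabolites if m.id in used]
        pruned._reindex()
        if orphans:
            logger.info("removed %d orphaned metabolite(s)", len(orphans))
    logger.info("pruned %d blocked reaction(s), kept %d",
                len(removed), len(kept))

    # report at parent level
    parent_blocked = set(removed)
    parent_unblocked = {r.id for r in kept}
    return PruneResult(unblocked=parent_unblocked, blocked=parent_blocked,
                       pruned_model=pruned, witness=result.witness,
                       lp_solves=result.lp_solves)
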