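"""LP plumbing shared by the flux solvers.

Both classic FBA and the dilution-aware variant are linear programs of
the form ``max c^T v  s.t.  A v = 0, 0 ≤ v ≤ ub`` on the irreversible
model; they differ only in ``A`` (``S`` versus ``S_limed``).  Tiny ε
entries can upset a single LP algorithm numerically, so every solve
walks a fallback chain (dual simplex → interior point → default HiGHS)
before reporting failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from . import dilution as dil
from .media import Media, apply_media
from .model import IrreversibleModel, MetabolicModel, V_MAX_DEFAULT, split_reversible

logger = logging.getLogger(__name__)

#: LP algorithms tried in order on numerical failure.
SOLVER_CHAIN = ("highs-ds", "highs-ipm", "highs")


class SolverError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    """Outcome of one flux optimization."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float
    fluxes: dict = field(default_factory=dict)  # parent-reaction net fluxes
    irreversible_fluxes: dict = field(default_factory=dict)
    dilution: dict = field(default_factory=dict)  # realized b per metabolite
    method: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def max_dilution(self) -> float:
        return max(self.dilution.values(), default=0.0)


def solve_lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    """Minimize ``c^T x`` with the documented solver fallback chain."""
    last = None
    for method in SOLVER_CHAIN:
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method=method)
        if res.status in (0, 2, 3):  # solved / infeasible / unbounded
            if last is not None:
                logger.info("LP recovered with %s after numerical trouble", method)
            return res, method
        last = res
    raise SolverError(f"LP failed on all methods: {last.message if last else '?'}")


def _optimize(irr: IrreversibleModel, A_eq: sparse.csr_matrix,
              extra_dilution: Optional[dil.DilutionSpec]) -> FluxSolution:
    n = len(irr.reactions)
    if irr.objective is None:
        raise ValueError("model has no objective reaction")
    c = np.zeros(n)
    # maximize the forward biomass flux
    c[irr.reaction_ids.index(irr.objective)] = -1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in irr.reactions]
    res, method = solve_lp(c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
                           bounds=bounds)
    if res.status == 2:
        return FluxSolution(status="infeasible", objective_value=0.0,
                            method=method)
    if res.status == 3:
        raise SolverError("LP unbounded: the model lacks v_max flux caps")
    v = {r.id: float(x) for r, x in zip(irr.reactions, res.x)}
    sol = FluxSolution(
        status="optimal",
        objective_value=float(-res.fun),
        fluxes=irr.merge_fluxes(v),
        irreversible_fluxes=v,
        method=method,
    )
    if extra_dilution is not None:
        sol.dilution = dil.realized_dilution(irr, extra_dilution, v)
    return sol


def _prepare(model: MetabolicModel, media: Optional[Media],
             v_max: float) -> IrreversibleModel:
    bounded = apply_media(model, media, v_max=v_max)
    return split_reversible(bounded)


def fba(model: MetabolicModel, media: Optional[Media] = None,
        v_max: float = V_MAX_DEFAULT) -> FluxSolution:
    """Classic flux balance analysis: ``max c^T v`` over ``S v = 0``."""
    irr = _prepare(model, media, v_max)
    return _optimize(irr, irr.stoichiometric_matrix(), None)


def limed_fba(model: MetabolicModel, media: Optional[Media] = None,
              spec: Optional[dil.DilutionSpec] = None,
              d_max: float = dil.D_MAX_DEFAULT,
              v_max: float = V_MAX_DEFAULT) -> FluxSolution:
    """FBA with linear metabolite dilution: ``(S − ε S^binary) v = 0``.

    ``spec`` overrides the automatically derived dilution coefficients
    (transport exemptions detected from stoichiometry, biomass
    metabolites exempted, ε sized so dilution never exceeds ``d_max``).
    """
    irr = _prepare(model, media, v_max)
    if spec is None:
        spec = dil.compute_epsilon(irr, d_max=d_max, v_max=v_max)
    return _optimize(irr, dil.limed_matrix(irr, spec), spec)


def fva_blocked(irr: IrreversibleModel, A_eq: sparse.csr_matrix,
                tol: float = 1e-6) -> set:
    """Blocked reactions by per-reaction flux maximization (the oracle).

    On an irreversible model the flux minimum is 0 by construction, so
    one maximization per reaction decides blockedness: a reaction is
    blocked iff its maximal flux over the feasible region is ~0.
    """
    n = len(irr.reactions)
    bounds = [(r.lower_bound, r.upper_bound) for r in irr.reactions]
    b_eq = np.zeros(A_eq.shape[0])
    blocked = set()
    for j, rxn in enumerate(irr.reactions):
        if rxn.upper_bound <= tol:
            blocked.add(rxn.id)
            continue
        c = np.zeros(n)
        c[j] = -1.0
        res, _ = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds)
        if res.status != 0 or -res.fun <= tol:
            blocked.add(rxn.id)
    return blocked


def fva_blocked_reversible(model: MetabolicModel, tol: float = 1e-6) -> set:
    """Blocked reactions of the *reversible* plain-stoichiometry model.

    Classic FVA: maximize and minimize each flux over ``S v = 0,
    lb ≤ v ≤ ub``; blocked iff ``max |v| ≈ 0``.  Unlike any oracle on
    the split irreversible matrix, this catches reversible self-cycles
    (e.g. an exempt compartment shuttle) that can only carry flux by
    running both directions at once.
    """
    n = len(model.reactions)
    S = model.stoichiometric_matrix()
    b_eq = np.zeros(S.shape[0])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    blocked = set()
    for j, rxn in enumerate(model.reactions):
        extreme = 0.0
        for sign in (-1.0, 1.0):
            if sign < 0 and rxn.upper_bound <= tol:
                continue
            if sign > 0 and rxn.lower_bound >= -tol:
                continue
            c = np.zeros(n)
            c[j] = sign
            res, _ = solve_lp(c, A_eq=S, b_eq=b_eq, bounds=bounds)
            if res.status == 0:
                extreme = max(extreme, abs(res.x[j]))
        if extreme <= tol:
            blocked.add(rxn.id)
    return blocked
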