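"""Metabolite-dilution bookkeeping for dilution-aware FBA.

Growing cells dilute every metabolite pool: a compound that takes part
in active reactions must be net-synthesized at a small rate or its
concentration collapses.  Classic FBA ignores this and therefore lets
internal cycles run without any input flux.  The linear fix is to couple
a small dilution flux ``b = ε S^binary v`` to the activity of each
metabolite, where ``S^binary`` is the 0/1 sparsity pattern of the
stoichiometric matrix (on the irreversible model) and ``ε`` is a
diagonal matrix of per-metabolite coefficients.  The steady-state
constraint ``S v = b`` then becomes ``(S − ε S^binary) v = 0``.

Two exemptions keep the construction honest:

* **Simple transport reactions** — movements of a metabolite between
  compartments with no chemical change — are excluded from ``S^binary``
  (their columns are zeroed).  Otherwise a high-flux 1:1 shuttle loop
  could be used to manufacture dilution capacity for a by-product with
  no exporter.
* **Biomass metabolites** already dilute through the biomass equation
  itself, so they get ``ε_ii = 0`` to avoid double-counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse

from .model import IrreversibleModel, MetabolicModel, V_MAX_DEFAULT

#: Default cap on any single metabolite's dilution rate (flux units).
D_MAX_DEFAULT = 0.1


@dataclass
class DilutionSpec:
    """Per-metabolite dilution coefficients plus the exemption sets."""

    epsilon: Mapping[str, float] = field(default_factory=dict)
    d_max: float = D_MAX_DEFAULT
    v_max: float = V_MAX_DEFAULT
    exempt_transport: frozenset = frozenset()
    exempt_metabolites: frozenset = frozenset()


def detect_simple_transport(model: MetabolicModel) -> set:
    """Reactions that move metabolites between compartments unchanged.

    A reaction qualifies when its participants pair up perfectly: every
    consumed metabolite reappears as the chemically identical species in
    another compartment with coefficient magnitude 1, with no other
    participants (antiporters qualify; cofactor-driven pumps do not).
    """
    out = set()
    for rxn in model.reactions:
        stoich = rxn.stoichiometry
        if len(stoich) < 2 or len(stoich) % 2 != 0:
            continue
        if any(abs(c) != 1 for c in stoich.values()):
            continue
        consumed: dict = {}
        produced: dict = {}
        ok = True
        for met_id, coef in stoich.items():
            met = model.metabolite(met_id)
            side = consumed if coef < 0 else produced
            if met.species_key() in side:  # same species twice on one side
                ok = False
                break
            side[met.species_key()] = met.compartment
        if not ok or set(consumed) != set(produced):
            continue
        if all(consumed[k] != produced[k] for k in consumed):
            out.add(rxn.id)
    return out


def biomass_metabolites(model: MetabolicModel) -> set:
    """Metabolites whose dilution is already in the biomass equation."""
    if model.objective is None or not model.has_reaction(model.objective):
        return set()
    return set(model.reaction(model.objective).stoichiometry)


def build_binary_matrix(model: IrreversibleModel,
                        spec: DilutionSpec) -> sparse.csr_matrix:
    """0/1 pattern of S with exempt-transport columns zeroed.

    Entry (i, j) is 1 iff metabolite i participates in reaction j and j
    is not an exempt simple-transport reaction.  Row i of ``S^binary v``
    is then the summed absolute flux through metabolite i — twice its
    turnover — which is what the dilution term scales.
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, vals = [], [], []
    exempt = set(spec.exempt_transport)
    # children of an exempt reversible parent are exempt too
    for j, rxn in enumerate(model.reactions):
        if rxn.id in exempt or (rxn.parent or rxn.id) in exempt:
            continue
        for met_id in rxn.stoichiometry:
            rows.append(met_index[met_id])
            cols.append(j)
            vals.append(1.0)
    return sparse.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    )


def compute_epsilon(model: IrreversibleModel,
                    d_max: float = D_MAX_DEFAULT,
                    v_max: float = V_MAX_DEFAULT,
                    exempt_transport: Optional[Iterable[str]] = None,
                    exempt_metabolites: Optional[Iterable[str]] = None,
                    ) -> DilutionSpec:
    """Assign ε so no metabolite's dilution rate can exceed ``d_max``.

    With ``k_i`` the number of non-exempt reactions metabolite ``i``
    participates in, ``ε_ii = d_max / (k_i · v_max)`` makes the worst
    case ``b_i = ε_ii · k_i · v_max`` exactly ``d_max``.  Exempt and
    isolated metabolites get ``ε_ii = 0``.
    """
    if d_max <= 0 or v_max <= 0:
        raise ValueError("d_max and v_max must be positive")
    if exempt_transport is None:
        exempt_transport = detect_simple_transport(model)
    if exempt_metabolites is None:
        exempt_metabolites = biomass_metabolites(model)
    exempt_transport = frozenset(exempt_transport)
    exempt_metabolites = frozenset(exempt_metabolites)

    spec = DilutionSpec(epsilon={}, d_max=d_max, v_max=v_max,
                        exempt_transport=exempt_transport,
                        exempt_metabolites=exempt_metabolites)
    sbin = build_binary_matrix(model, spec)
    k = np.asarray(sbin.sum(axis=1)).ravel()
    epsilon = {}
    for i, met in enumerate(model.metabolites):
        if met.id in exempt_metabolites or k[i] == 0:
            epsilon[met.id] = 0.0
        else:
            epsilon[met.id] = d_max / (k[i] * v_max)
    spec.epsilon = epsilon
    return spec


def default_spec(model: IrreversibleModel,
                 d_max: float = D_MAX_DEFAULT,
                 v_max: float = V_MAX_DEFAULT) -> DilutionSpec:
    """Spec with auto-detected transport and biomass exemptions."""
    return compute_epsilon(model, d_max=d_max, v_max=v_max)


def limed_matrix(model: IrreversibleModel,
                 spec: DilutionSpec) -> sparse.csr_matrix:
    """``S_limed = S − ε S^binary`` on the irreversible model."""
    S = model.stoichiometric_matrix()
    sbin = build_binary_matrix(model, spec)
    eps = sparse.diags([spec.epsilon.get(m.id, 0.0) for m in model.metabolites])
    return (S - eps @ sbin).tocsr()


def realized_dilution(model: IrreversibleModel, spec: DilutionSpec,
                      fluxes: Mapping[str, float]) -> dict:
    """Post-hoc ``b = ε S^binary v`` for a solved flux vector."""
    sbin = build_binary_matrix(model, spec)
    v = np.array([fluxes.get(r.id, 0.0) for r in model.reactions])
    activity = sbin @ v
    return {m.id: spec.epsilon.get(m.id, 0.0) * activity[i]
            for i, m in enumerate(model.metabolites)}
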