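"""Synthetic metabolic networks with planted ground truth.

Each motif reproduces a pedagogical failure mode of constraint-based
growth prediction on a handful of reactions, so every algorithm in the
package can be exercised — and checked against brute-force oracles —
without any external model:

* ``input_cycle`` — a metabolic cycle emitting a biomass by-product;
  classic FBA grows without any input flux, dilution-aware FBA does not.
* ``linear_chain`` — a biosynthesis chain; knocking any step is lethal
  and only downstream supplements rescue.
* ``branch_rescue`` — a branch point feeding two biomass precursors;
  each branch has its own rescuing supplement.
* ``dual_route_sl`` — two gene-labelled routes to one essential
  metabolite: each single knockout is viable, the double knockout is
  lethal, and a downstream supplement rescues the double mutant.
* ``isozyme_sl`` — one essential reaction catalyzed by two isozymes.
* ``transport_cheat`` — a by-product with no exporter plus a 1:1
  compartment shuttle; growth must stay impossible because exempt
  simple transport cannot manufacture dilution capacity.
* ``dead_end`` — k dead-end reactions grafted onto a viable core;
  exactly those k are blocked.

Coefficients are small integers so subset enumeration, truth tables and
per-reaction flux maximization remain exact oracles.  Generation is
deterministic given the motif parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .media import Media
from .model import (
    EvidenceRecord,
    GprRule,
    MetabolicModel,
    MetaboliteRecord,
    ReactionRecord,
    V_MAX_DEFAULT,
)

MOTIFS = ("input_cycle", "linear_chain", "branch_rescue", "dual_route_sl",
          "isozyme_sl", "transport_cheat", "dead_end")


@dataclass(frozen=True)
class FixtureSpec:
    motif: str
    params: tuple = ()  # sorted (key, value) pairs
    seed: int = 0


@dataclass
class Fixture:
    """A generated model plus machine-readable ground truth."""

    model: MetabolicModel
    media: Optional[Media] = None
    truth: dict = field(default_factory=dict)


def _met(model, mid, compartment):
    if not model.has_metabolite(mid):
        model.add_metabolite(MetaboliteRecord(id=mid, compartment=compartment))


def _rxn(model, rid, stoich, lb=0.0, ub=V_MAX_DEFAULT, gene=None, gpr=None,
         pathways=(), evidence=None):
    rule = gpr if gpr is not None else (
        GprRule.parse(gene) if gene else GprRule.empty())
    model.add_reaction(ReactionRecord(
        id=rid, stoichiometry=dict(stoich), lower_bound=lb, upper_bound=ub,
        gpr=rule, pathways=set(pathways), evidence=evidence))
    model.genes |= rule.genes()


def _exchange(model, met, uptake=0.0, v_max=V_MAX_DEFAULT):
    _met(model, met, "e")
    _rxn(model, f"EX_{met}", {met: -1.0}, lb=-float(uptake), ub=v_max)


def make_fixture(spec: FixtureSpec) -> Fixture:
    if spec.motif not in MOTIFS:
        raise ValueError(f"unknown motif {spec.motif!r}; choose from {MOTIFS}")
    builder = globals()[spec.motif]
    return builder(seed=spec.seed, **dict(spec.params))


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def input_cycle(n: int = 3, include_input: bool = True, seed: int = 0) -> Fixture:
    """Cycle of ``n`` metabolites emitting by-product P drained by biomass.

    The cycle carriers are catalytic: one turn converts nothing net but
    emits P, so classic FBA grows even with the input knocked out, while
    forced dilution of the carriers demands the input flux.
    """
    m = MetabolicModel(id=f"input_cycle_{n}")
    for i in range(n):
        _met(m, f"A{i}[c]", "c")
    _met(m, "P[c]", "c")
    _exchange(m, "S[e]", uptake=10.0)
    if include_input:
        _rxn(m, "R_in", {"S[e]": -1, "A0[c]": 1}, gene="g_input",
             pathways={"cycle_input"})
    for i in range(n):
        nxt = (i + 1) % n
        stoich = {f"A{i}[c]": -1, f"A{nxt}[c]": 1}
        if i == n - 1:
            stoich["P[c]"] = 1
        _rxn(m, f"R_cyc{i}", stoich, gene=f"g_cyc{i}", pathways={"cycle"})
    _rxn(m, "BIOMASS", {"P[c]": -1})
    m.objective = "BIOMASS"
    m.validate()
    return Fixture(model=m, media=Media("uptake_S", {"S[e]": 10.0}), truth={
        "input_gene": "g_input" if include_input else None,
        "fba_grows_without_input": True,
        "limed_grows_without_input": False,
    })


def linear_chain(n: int = 4, seed: int = 0) -> Fixture:
    """Uptake → M1 → … → Mn → biomass, one gene per step.

    Every step gene is essential on minimal medium; supplementing an
    intermediate rescues exactly the knockouts upstream of it.
    """
    m = MetabolicModel(id=f"linear_chain_{n}")
    _exchange(m, "S[e]", uptake=10.0)
    for i in range(1, n + 1):
        _met(m, f"M{i}[c]", "c")
    _rxn(m, "R_up", {"S[e]": -1, "M1[c]": 1}, gene="g0",
         pathways={"chain"})
    for i in range(1, n):
        _rxn(m, f"R{i}", {f"M{i}[c]": -1, f"M{i+1}[c]": 1}, gene=f"g{i}",
             pathways={"chain"})
    _rxn(m, "BIOMASS", {f"M{n}[c]": -1})
    m.objective = "BIOMASS"
    # supplement plumbing: exchange + transporter per intermediate
    for i in range(1, n + 1):
        _exchange(m, f"M{i}[e]", uptake=0.0)
        _rxn(m, f"T_M{i}", {f"M{i}[e]": -1, f"M{i}[c]": 1}, lb=0.0)
    m.validate()
    minimal = Media("chain_minimal", {"S[e]": 1.5})
    # gene gi blocks the step producing M(i+1); supplements at or below
    # the lesion do not rescue, strictly downstream ones do
    rescues = {f"g{i}": {f"M{j}[e]" for j in range(i + 1, n + 1)}
               for i in range(n)}
    return Fixture(model=m, media=minimal, truth={
        "essential_genes": {f"g{i}" for i in range(n)},
        "rescues": rescues,
        "supplements": [f"M{i}[e]" for i in range(1, n + 1)],
    })


def branch_rescue(seed: int = 0) -> Fixture:
    """A branch point feeding two biomass precursors."""
    m = MetabolicModel(id="branch_rescue")
    _exchange(m, "S[e]", uptake=10.0)
    for mid in ("A[c]", "B1[c]", "B2[c]"):
        _met(m, mid, "c")
    _rxn(m, "R_up", {"S[e]": -1, "A[c]": 1}, gene="g_up", pathways={"trunk"})
    _rxn(m, "R_b1", {"A[c]": -1, "B1[c]": 1}, gene="g_b1", pathways={"branch1"})
    _rxn(m, "R_b2", {"A[c]": -1, "B2[c]": 1}, gene="g_b2", pathways={"branch2"})
    _rxn(m, "BIOMASS", {"B1[c]": -1, "B2[c]": -1})
    m.objective = "BIOMASS"
    for mid in ("B1", "B2"):
        _exchange(m, f"{mid}[e]", uptake=0.0)
        _rxn(m, f"T_{mid}", {f"{mid}[e]": -1, f"{mid}[c]": 1})
    m.validate()
    return Fixture(model=m, media=Media("branch_minimal", {"S[e]": 1.5}), truth={
        "essential_genes": {"g_up", "g_b1", "g_b2"},
        "rescues": {"g_b1": {"B1[e]"}, "g_b2": {"B2[e]"}},
        "supplements": ["B1[e]", "B2[e]"],
    })


def dual_route_sl(shared_pathway: bool = True, seed: int = 0) -> Fixture:
    """Two gene-labelled routes to an essential metabolite Q.

    Route 1 (gene ``gA``) converts precursor K directly to intermediate
    G; route 2 (gene ``gB``) regenerates G from K and Q.  Q itself is
    made from G by an un-knocked synthetase.  Either single knockout
    leaves one route; the double knockout starves Q; supplementing G
    rescues the double mutant.  With ``shared_pathway`` both routes
    carry the same pathway tag (common-pathway synthetic lethality);
    otherwise they are tagged as two interacting pathways.
    """
    m = MetabolicModel(id="dual_route_sl")
    _exchange(m, "K[e]", uptake=10.0)
    for mid in ("K[c]", "G[c]", "Q[c]"):
        _met(m, mid, "c")
    p1 = "route_shared" if shared_pathway else "route_one"
    p2 = "route_shared" if shared_pathway else "route_two"
    _rxn(m, "T_K", {"K[e]": -1, "K[c]": 1})
    _rxn(m, "R_direct", {"K[c]": -1, "G[c]": 1}, gene="gA", pathways={p1})
    _rxn(m, "R_alt", {"K[c]": -1, "Q[c]": -1, "G[c]": 2}, gene="gB",
         pathways={p2})
    _rxn(m, "R_synth", {"G[c]": -1, "Q[c]": 1}, gene="g_synth",
         pathways={"synthesis"})
    _rxn(m, "BIOMASS", {"Q[c]": -1})
    m.objective = "BIOMASS"
    _exchange(m, "G[e]", uptake=0.0)
    _rxn(m, "T_G", {"G[e]": -1, "G[c]": 1})
    m.validate()
    return Fixture(model=m, media=Media("sl_minimal", {"K[e]": 10.0}), truth={
        "sl_pair": frozenset({"gA", "gB"}),
        "nonessential": ["gA", "gB"],
        "classification": "same_pathway" if shared_pathway
        else "interacting_pathways",
        "rescue_supplement": "G[e]",
    })


def isozyme_sl(seed: int = 0) -> Fixture:
    """One essential reaction catalyzed by either of two isozymes."""
    m = MetabolicModel(id="isozyme_sl")
    _exchange(m, "S[e]", uptake=10.0)
    _met(m, "A[c]", "c")
    _met(m, "B[c]", "c")
    _rxn(m, "R_up", {"S[e]": -1, "A[c]": 1})
    _rxn(m, "R_iso", {"A[c]": -1, "B[c]": 1}, gpr=GprRule.parse("gX or gY"),
         pathways={"core"})
    _rxn(m, "BIOMASS", {"B[c]": -1})
    m.objective = "BIOMASS"
    m.validate()
    return Fixture(model=m, media=Media("iso_minimal", {"S[e]": 10.0}), truth={
        "sl_pair": frozenset({"gX", "gY"}),
        "nonessential": ["gX", "gY"],
        "classification": "isozyme",
    })


def transport_cheat(seed: int = 0) -> Fixture:
    """A by-product with no exporter plus a 1:1 compartment shuttle.

    Biomass production co-produces W, which nothing consumes or exports.
    The reversible shuttle W[c]↔W[n] is a simple transport reaction; if
    it counted towards dilution, a high-flux shuttle loop would grant W
    enough dilution capacity to grow.  With the exemption in place the
    model must remain unable to grow.
    """
    m = MetabolicModel(id="transport_cheat")
    _exchange(m, "S[e]", uptake=10.0)
    for mid, comp in (("B[c]", "c"), ("W[c]", "c"), ("W[n]", "n")):
        _met(m, mid, comp)
    _rxn(m, "R_conv", {"S[e]": -1, "B[c]": 1, "W[c]": 1}, gene="g_conv")
    _rxn(m, "T_W", {"W[c]": -1, "W[n]": 1}, lb=-V_MAX_DEFAULT)
    _rxn(m, "BIOMASS", {"B[c]": -1})
    m.objective = "BIOMASS"
    m.validate()
    return Fixture(model=m, media=Media("cheat_minimal", {"S[e]": 10.0}), truth={
        "limed_grows": False,
        "shuttle": "T_W",
        "cheat_grows_without_exemption": True,
    })


def dead_end(k: int = 3, seed: int = 0) -> Fixture:
    """k dead-end reactions grafted onto a viable core."""
    m = MetabolicModel(id=f"dead_end_{k}")
    _exchange(m, "S[e]", uptake=10.0)
    _met(m, "A[c]", "c")
    _rxn(m, "R_up", {"S[e]": -1, "A[c]": 1}, gene="g_core")
    _rxn(m, "BIOMASS", {"A[c]": -1})
    m.objective = "BIOMASS"
    blocked = []
    for i in range(k):
        _met(m, f"D{i}[c]", "c")
        rid = f"R_dead{i}"
        _rxn(m, rid, {"A[c]": -1, f"D{i}[c]": 1})
        blocked.append(rid)
    m.validate()
    return Fixture(model=m, media=Media("dead_minimal", {"S[e]": 10.0}), truth={
        "blocked": set(blocked),
    })


# ---------------------------------------------------------------------------
# random models
# ---------------------------------------------------------------------------

def random_model(n_mets: int = 8, n_rxns: int = 12, seed: int = 0,
                 density: float = 0.35,
                 p_reversible: float = 0.3) -> MetabolicModel:
    """Connected random stoichiometric network with uptake and biomass.

    Internal reactions draw 1–2 substrates and 1–2 products with ±1/±2
    coefficients; a fraction is reversible.  Deterministic per seed.
    """
    if n_rxns < 1:
        raise ValueError("n_rxns must be >= 1")
    rng = np.random.default_rng(seed)
    m = MetabolicModel(id=f"random_{n_mets}x{n_rxns}_{seed}")
    mets = [f"X{i}[c]" for i in range(n_mets)]
    for mid in mets:
        _met(m, mid, "c")
    _exchange(m, "S[e]", uptake=V_MAX_DEFAULT)
    _rxn(m, "R_up", {"S[e]": -1, mets[0]: 1}, gene="g_up")
    target = mets[int(rng.integers(0, n_mets))]
    for j in range(n_rxns):
        n_sub = 1 + int(rng.random() < density)
        n_prod = 1 + int(rng.random() < density)
        picks = rng.choice(n_mets, size=min(n_sub + n_prod, n_mets),
                           replace=False)
        subs = picks[:n_sub]
        prods = picks[n_sub:]
        if len(prods) == 0:
            continue
        stoich = {}
        for i in subs:
            stoich[mets[i]] = -float(rng.integers(1, 3))
        for i in prods:
            stoich[mets[i]] = float(rng.integers(1, 3))
        lb = -V_MAX_DEFAULT if rng.random() < p_reversible else 0.0
        _rxn(m, f"R{j}", stoich, lb=lb, gene=f"g{j}",
             pathways={f"pw{int(rng.integers(0, 3))}"})
    _rxn(m, "BIOMASS", {target: -1})
    m.objective = "BIOMASS"
    m.validate()
    return m
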