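"""In-memory representation of constraint-based metabolic models.

A :class:`MetabolicModel` couples a stoichiometric matrix ``S`` with flux
bounds ``lb``/``ub``, a single biomass objective reaction and boolean
gene-protein-reaction (GPR) rules.  Reversible models can be rewritten as
fully irreversible ones (every flux non-negative) by splitting each
reversible reaction into a forward and a reverse child; the irreversible
form is what the dilution-aware solvers and the pruning LP operate on.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

#: Global default cap on any single flux, in mmol/gDW/h.
V_MAX_DEFAULT = 1000.0


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GprParseError(ValueError):
    """Raised when a gene-association string cannot be parsed."""


@dataclass(frozen=True)
class GprRule:
    """Boolean expression over gene ids.

    ``AND`` encodes an enzyme complex (all subunits required), ``OR``
    encodes isozymes (any one suffices).  The expression tree uses nested
    tuples: ``("gene", gid)``, ``("and", (children...))``,
    ``("or", (children...))`` or ``None`` for the empty rule.  An empty
    rule always evaluates true: the reaction is not gene-dependent
    (orphan or spontaneous).
    """

    expr: Optional[tuple] = None

    @staticmethod
    def empty() -> "GprRule":
        return GprRule(None)

    @staticmethod
    def parse(text: str) -> "GprRule":
        """Parse a parenthesized infix boolean expression.

        ``and`` / ``or`` are case-insensitive, matching the COBRA
        ``GENE_ASSOCIATION`` notes convention.  Everything else that is
        not a parenthesis is a gene id.
        """
        tokens = _TOKEN_RE.findall(text or "")
        if not tokens:
            return GprRule.empty()
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def take():
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            return tok

        def parse_or():
            terms = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                take()
                terms.append(parse_and())
            if len(terms) == 1:
                return terms[0]
            return ("or", tuple(terms))

        def parse_and():
            terms = [parse_atom()]
            while peek() is not None and peek().lower() == "and":
                take()
                terms.append(parse_atom())
            if len(terms) == 1:
                return terms[0]
            return ("and", tuple(terms))

        def parse_atom():
            tok = peek()
            if tok is None:
                raise GprParseError(f"unexpected end of GPR expression: {text!r}")
            if tok == "(":
                take()
                node = parse_or()
                if peek() != ")":
                    raise GprParseError(f"unbalanced parentheses in GPR: {text!r}")
                take()
                return node
            if tok == ")" or tok.lower() in ("and", "or"):
                raise GprParseError(f"unexpected token {tok!r} in GPR: {text!r}")
            return ("gene", take())

        node = parse_or()
        if pos != len(tokens):
            raise GprParseError(f"trailing tokens in GPR: {text!r}")
        return GprRule(node)

    @property
    def is_empty(self) -> bool:
        return self.expr is None

    def genes(self) -> frozenset:
        """All gene ids appearing as leaves."""
        out = set()

        def walk(node):
            if node is None:
                return
            if node[0] == "gene":
                out.add(node[1])
            else:
                for child in node[1]:
                    walk(child)

        walk(self.expr)
        return frozenset(out)

    def evaluate(self, knocked_out: Iterable[str]) -> bool:
        """True iff the rule holds with ``knocked_out`` genes absent.

        Genes not in ``knocked_out`` are assumed present; unknown leaves
        are treated as present.  The empty rule is always true.
        """
        ko = set(knocked_out)

        def walk(node):
            if node is None:
                return True
            kind = node[0]
            if kind == "gene":
                return node[1] not in ko
            if kind == "and":
                return all(walk(c) for c in node[1])
            return any(walk(c) for c in node[1])

        return walk(self.expr)

    def to_string(self) -> str:
        def render(node, parent=None):
            if node is None:
                return ""
            kind = node[0]
            if kind == "gene":
                return node[1]
            joiner = f" {kind} "
            inner = joiner.join(render(c, kind) for c in node[1])
            if parent is not None and parent != kind:
                return f"({inner})"
            return inner

        return render(self.expr)


def evaluate_gpr(rule: GprRule, knocked_out: Iterable[str],
                 known_genes: Optional[Iterable[str]] = None) -> bool:
    """Evaluate ``rule`` under a knockout set.

    Unknown gene ids in ``knocked_out`` (absent from ``known_genes``,
    when given) are reported via the module logger and ignored — no
    reaction depends on them.
    """
    ko = set(knocked_out)
    if known_genes is not None:
        unknown = ko - set(known_genes)
        if unknown:
            logger.warning("ignoring %d unknown knocked-out gene(s): %s",
                           len(unknown), sorted(unknown))
    return rule.evaluate(ko)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class EvidenceRecord:
    """Per-reaction evidence feeding the reconciliation weights.

    ``curated`` marks manual literature curation; curated reactions are
    never candidates for removal.  The three probabilities live in
    (0, 1]: pathway presence support, biochemical plausibility (enzyme
    function prediction) and thermodynamic plausibility (Gibbs
    free-energy estimate).
    """

    curated: bool = False
    pathway_support: float = 1.0
    p_biochem: float = 1.0
    p_thermo: float = 1.0


@dataclass
class MetaboliteRecord:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str = ""
    charge: int = 0

    def species_key(self) -> str:
        """Compartment-independent identity used to detect transport.

        Metabolite ids carry their compartment either as a bracketed
        suffix (``glc[c]``) or as an underscore suffix (``glc_c``); the
        key strips it.
        """
        if self.compartment:
            bracket = f"[{self.compartment}]"
            if self.id.endswith(bracket):
                return self.id[: -len(bracket)]
            underscore = f"_{self.compartment}"
            if self.id.endswith(underscore):
                return self.id[: -len(underscore)]
        return self.id


@dataclass
class ReactionRecord:
    id: str
    stoichiometry: dict = field(default_factory=dict)  # metabolite id -> coefficient
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = V_MAX_DEFAULT
    gpr: GprRule = field(default_factory=GprRule.empty)
    pathways: set = field(default_factory=set)
    evidence: Optional[EvidenceRecord] = None
    # back-reference for children of a split reversible reaction
    parent: Optional[str] = None
    direction: Optional[str] = None  # "fwd" | "rev"

    @property
    def is_exchange(self) -> bool:
        """Boundary reaction touching exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


FWD_SUFFIX = "__fwd"
REV_SUFFIX = "__rev"


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    ``objective`` names the single biomass reaction whose flux is
    maximized; its optimal value is the growth rate.
    """

    metabolites: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    objective: Optional[str] = None
    genes: set = field(default_factory=set)
    id: str = "model"

    def __post_init__(self):
        self._reindex()

    def _reindex(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- access -------------------------------------------------------
    def metabolite(self, met_id: str) -> MetaboliteRecord:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> ReactionRecord:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def metabolite_ids(self) -> list:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    @property
    def exchanges(self) -> list:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- structure ----------------------------------------------------
    def add_reaction(self, rxn: ReactionRecord):
        if rxn.id in self._rxn_index:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = len(self.reactions) - 1

    def add_metabolite(self, met: MetaboliteRecord):
        if met.id in self._met_index:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        self._met_index[met.id] = len(self.metabolites) - 1

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with one row per metabolite and one column per reaction."""
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                rows.append(self._met_index[met_id])
                cols.append(j)
                vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    def validate(self, v_max: float = V_MAX_DEFAULT):
        """Check structural invariants; raise ``ValueError`` on violation."""
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}")
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"reaction {rxn.id!r}: lb > ub")
            if rxn.lower_bound < -v_max or rxn.upper_bound > v_max:
                raise ValueError(f"reaction {rxn.id!r}: bounds exceed ±{v_max}")
            for gid in rxn.gpr.genes():
                if gid not in self.genes:
                    raise ValueError(
                        f"reaction {rxn.id!r}: GPR gene {gid!r} not in model genes")
        if self.objective is not None and self.objective not in self._rxn_index:
            raise ValueError(f"objective reaction {self.objective!r} not in model")

    # -- gene logic ---------------------------------------------------
    def reactions_requiring(self, genes: Iterable[str]) -> list:
        """Reaction ids whose GPR fails when ``genes`` are knocked out."""
        ko = set(genes)
        return [r.id for r in self.reactions if not r.gpr.evaluate(ko)]


class IrreversibleModel(MetabolicModel):
    """A model in which every reaction has ``lower_bound == 0``.

    Children of a split reversible parent carry ``parent``/``direction``
    back-references; :meth:`merge_fluxes` folds a child flux vector back
    onto the parent reactions as ``fwd − rev``.
    """

    def merge_fluxes(self, fluxes: Mapping[str, float]) -> dict:
        merged: dict = {}
        for rxn in self.reactions:
            pid = rxn.parent or rxn.id
            v = fluxes.get(rxn.id, 0.0)
            if rxn.direction == "rev":
                v = -v
            merged[pid] = merged.get(pid, 0.0) + v
        return merged

    def children_of(self, parent_id: str) -> list:
        return [r.id for r in self.reactions
                if (r.parent or r.id) == parent_id]


def split_reversible(model: MetabolicModel) -> IrreversibleModel:
    """Rewrite a model with all-non-negative fluxes.

    Reactions with ``lb >= 0`` are copied unchanged (back-reference to
    themselves, direction ``fwd``).  Reactions with ``lb < 0`` become two
    children: ``<id>__fwd`` with bounds ``[0, max(ub, 0)]`` carrying the
    original stoichiometry, and ``<id>__rev`` with bounds ``[0, -lb]``
    carrying its negation.  GPR, pathway and evidence annotations are
    copied to both children.
    """
    out = IrreversibleModel(
        metabolites=copy.deepcopy(model.metabolites),
        objective=None,
        genes=set(model.genes),
        id=model.id,
    )
    for rxn in model.reactions:
        if rxn.lower_bound >= 0:
            child = copy.deepcopy(rxn)
            child.parent = rxn.id
            child.direction = "fwd"
            out.add_reaction(child)
        else:
            fwd = copy.deepcopy(rxn)
            fwd.id = rxn.id + FWD_SUFFIX
            fwd.lower_bound = 0.0
            fwd.upper_bound = max(rxn.upper_bound, 0.0)
            fwd.parent = rxn.id
            fwd.direction = "fwd"
            out.add_reaction(fwd)
            rev = copy.deepcopy(rxn)
            rev.id = rxn.id + REV_SUFFIX
            rev.stoichiometry = {m: -c for m, c in rxn.stoichiometry.items()}
            rev.lower_bound = 0.0
            rev.upper_bound = -rxn.lower_bound
            rev.parent = rxn.id
            rev.direction = "rev"
            out.add_reaction(rev)
    if model.objective is not None:
        obj = model.objective
        if not out.has_reaction(obj):
            obj = model.objective + FWD_SUFFIX
        out.objective = obj
    return out


def apply_knockout(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Return a copy with gene-dependent reactions blocked.

    Every reaction whose GPR evaluates false under the knockout has both
    bounds set to zero; indices stay stable, which keeps repeated
    screens cheap.
    """
    ko = set(genes)
    unknown = ko - model.genes
    if unknown:
        logger.warning("knockout ignores %d gene(s) absent from the model: %s",
                       len(unknown), sorted(unknown))
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.gpr.evaluate(ko):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out
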