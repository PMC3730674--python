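"""Viability screens: gene essentiality, nutrient rescue, synthetic lethality.

Every screen follows the same recipe: knock out genes by blocking the
reactions whose GPR fails, bound the exchanges with the medium, maximize
biomass with dilution-aware FBA, and call the mutant viable when the
biomass flux exceeds a threshold (0.02 by default).  Screen accuracy is
summarized as sensitivity (fraction of experimentally viable mutants
predicted viable) and specificity (fraction of experimentally inviable
mutants predicted inviable).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .media import Media, build_media
from .model import MetabolicModel, V_MAX_DEFAULT, apply_knockout
from .reconcile import VIABILITY_THRESHOLD
from .solve import limed_fba, fba as plain_fba

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeResult:
    """Outcome of one knockout simulation."""

    genes: frozenset
    media: str
    biomass: float
    threshold: float = VIABILITY_THRESHOLD

    @property
    def viable(self) -> bool:
        return self.biomass > self.threshold


@dataclass
class ScreenSummary:
    """Confusion counts against an experimental truth table.

    "Positive" is the experimentally viable class: TP counts mutants
    viable in both experiment and simulation, TN mutants inviable in
    both.
    """

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class SyntheticLethalPair:
    genes: frozenset
    classification: str = ""  # isozyme | same_pathway | interacting_pathways
    rescues: list = field(default_factory=list)


def simulate_knockout(model: MetabolicModel, genes: Iterable[str],
                      media: Optional[Media],
                      threshold: float = VIABILITY_THRESHOLD,
                      v_max: float = V_MAX_DEFAULT,
                      method: str = "limed") -> PhenotypeResult:
    """Block gene-dependent reactions and maximize biomass."""
    genes = frozenset(genes)
    mutant = apply_knockout(model, genes) if genes else model
    solver = limed_fba if method == "limed" else plain_fba
    sol = solver(mutant, media, v_max=v_max)
    return PhenotypeResult(genes=genes,
                           media=media.name if media else "unbounded",
                           biomass=sol.objective_value, threshold=threshold)


def predict_essentiality(model: MetabolicModel, media: Optional[Media],
                         genes: Optional[Iterable[str]] = None,
                         truth: Optional[Mapping[str, str]] = None,
                         threshold: float = VIABILITY_THRESHOLD,
                         v_max: float = V_MAX_DEFAULT,
                         method: str = "limed"):
    """Single-gene knockout screen.

    Returns ``(results, summary)``; ``summary`` is ``None`` without a
    truth table (gene → "viable"/"inviable").  Genes absent from the
    model are skipped with a logged count.
    """
    if genes is None:
        genes = sorted(model.genes)
    results = []
    skipped = 0
    for gene in genes:
        if gene not in model.genes:
            skipped += 1
            continue
        results.append(simulate_knockout(model, {gene}, media,
                                         threshold=threshold, v_max=v_max,
                                         method=method))
    if skipped:
        logger.warning("essentiality screen skipped %d gene(s) absent "
                       "from the model", skipped)
    summary = None
    if truth is not None:
        summary = ScreenSummary()
        for res in results:
            (gene,) = res.genes
            if gene not in truth:
                continue
            observed_viable = truth[gene] == "viable"
            if observed_viable and res.viable:
                summary.tp += 1
            elif observed_viable and not res.viable:
                summary.fn += 1
            elif not observed_viable and not res.viable:
                summary.tn += 1
            else:
                summary.fp += 1
    return results, summary


def predict_rescue(model: MetabolicModel, minimal_media: Media, gene: str,
                   candidate_supplements: Sequence,
                   threshold: float = VIABILITY_THRESHOLD,
                   v_max: float = V_MAX_DEFAULT) -> list:
    """Test which supplements restore growth of an inviable mutant.

    Each candidate is a single metabolite id or a combination (tuple of
    ids).  A combination whose members include an already-rescuing
    single supplement is reported as implied without re-solving — the
    multi-substrate case adds no information beyond the single-substrate
    one.  Returns ``[(supplement set, PhenotypeResult, implied)]``.
    """
    base = simulate_knockout(model, {gene}, minimal_media,
                             threshold=threshold, v_max=v_max)
    if base.viable:
        raise ValueError(f"gene {gene!r} is not inviable on "
                         f"{minimal_media.name!r}: rescue is undefined")
    singles_rescuing = set()
    out = []
    normalized = [(c,) if isinstance(c, str) else tuple(c)
                  for c in candidate_supplements]
    # singles first so that supersets can be short-circuited
    for supplement in sorted(normalized, key=len):
        supset = frozenset(supplement)
        if len(supplement) > 1 and supset & singles_rescuing:
            implied_res = PhenotypeResult(genes=frozenset({gene}),
                                          media=minimal_media.name,
                                          biomass=float("nan"),
                                          threshold=threshold)
            out.append((supset, implied_res, True))
            continue
        media = build_media(minimal_media, supplement, model=model)
        res = simulate_knockout(model, {gene}, media,
                                threshold=threshold, v_max=v_max)
        if len(supplement) == 1 and res.viable:
            singles_rescuing |= supset
        out.append((supset, res, False))
    return out


def synthetic_lethal_screen(model: MetabolicModel, media: Optional[Media],
                            nonessential_genes: Sequence[str],
                            threshold: float = VIABILITY_THRESHOLD,
                            v_max: float = V_MAX_DEFAULT,
                            exhaustive: bool = True,
                            classify: bool = True) -> list:
    """Double-knockout screen over all unordered pairs.

    ``nonessential_genes`` must all be individually viable on ``media``.
    With ``exhaustive=False`` a pair is skipped (predicted viable)
    whenever the reactions blocked by the double knockout do not
    intersect the support of the wild-type optimal flux — a sound
    shortcut re-checked against the exhaustive result in the test suite.
    """
    for gene in nonessential_genes:
        single = simulate_knockout(model, {gene}, media,
                                   threshold=threshold, v_max=v_max)
        if not single.viable:
            raise ValueError(f"gene {gene!r} is individually inviable: "
                             "not eligible for a synthetic-lethal screen")
    support = None
    if not exhaustive:
        wt = limed_fba(model, media, v_max=v_max)
        support = {rid for rid, v in wt.fluxes.items() if abs(v) > 1e-9}
    pairs = []
    for g1, g2 in itertools.combinations(sorted(nonessential_genes), 2):
        if support is not None:
            blocked = set(model.reactions_requiring({g1, g2}))
            if not blocked & support:
                continue
        res = simulate_knockout(model, {g1, g2}, media,
                                threshold=threshold, v_max=v_max)
        if not res.viable:
            pair = SyntheticLethalPair(genes=frozenset({g1, g2}))
            if classify:
                pair.classification = classify_sl_pair(model, (g1, g2))
            pairs.append(pair)
    return pairs


def classify_sl_pair(model: MetabolicModel, pair: Sequence[str]) -> str:
    """Mechanistic class of a synthetic-lethal gene pair.

    ``isozyme``: the two genes appear in OR positions of one reaction's
    GPR (the reaction survives either single knockout but not the
    double).  ``same_pathway``: reactions unique to each gene share a
    pathway annotation.  Otherwise ``interacting_pathways``.
    """
    g1, g2 = pair
    for rxn in model.reactions:
        leaves = rxn.gpr.genes()
        if g1 in leaves and g2 in leaves:
            if (rxn.gpr.evaluate({g1}) and rxn.gpr.evaluate({g2})
                    and not rxn.gpr.evaluate({g1, g2})):
                return "isozyme"
    paths1 = {p for r in model.reactions if g1 in r.gpr.genes()
              for p in r.pathways}
    paths2 = {p for r in model.reactions if g2 in r.gpr.genes()
              for p in r.pathways}
    if paths1 & paths2:
        return "same_pathway"
    return "interacting_pathways"


def add_accumulation_sink(model: MetabolicModel, metabolite: str,
                          cap: float = V_MAX_DEFAULT) -> MetabolicModel:
    """Allow intracellular accumulation of one metabolite.

    Adds a sink reaction draining ``metabolite``; used to relax the
    steady-state constraint for compounds that are known to pile up in
    vivo (e.g. pathway intermediates behind a lesion).
    """
    from .model import ReactionRecord

    out = model.copy()
    out.add_reaction(ReactionRecord(
        id=f"SINK_{metabolite}",
        stoichiometry={metabolite: -1.0},
        lower_bound=0.0,
        upper_bound=cap,
        name=f"accumulation sink for {metabolite}",
    ))
    return out
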