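"""In-silico growth media.

A medium is a mapping from exchangeable (extracellular) metabolites to
maximum uptake rates in mmol/gDW/h.  Applying a medium to a model opens
the uptake direction of the matching exchange reactions up to the stated
cap and closes uptake for every other exchange; secretion stays open.
The conventional caps are 1.5 mmol/gDW/h for the limiting carbon source
and 3 mmol/gDW/h for nutrient supplements.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .model import MetabolicModel, V_MAX_DEFAULT

#: Default cap on the limiting carbon source, mmol/gDW/h.
CARBON_UPTAKE_DEFAULT = 1.5
#: Default cap on supplemental nutrients, mmol/gDW/h.
SUPPLEMENT_UPTAKE_DEFAULT = 3.0


@dataclass(frozen=True)
class Media:
    """Named set of uptake caps keyed by extracellular metabolite id."""

    name: str = "medium"
    uptakes: Mapping[str, float] = field(default_factory=dict)

    def with_supplements(self, supplements: Iterable[str],
                         cap: float = SUPPLEMENT_UPTAKE_DEFAULT) -> "Media":
        new = dict(self.uptakes)
        for met in supplements:
            new[met] = max(cap, new.get(met, 0.0))
        return Media(name=self.name + "+" + "+".join(supplements), uptakes=new)


def exchanged_metabolite(rxn) -> tuple:
    """(metabolite id, sign of its coefficient) for an exchange reaction."""
    (met_id, coef), = rxn.stoichiometry.items()
    return met_id, (1.0 if coef > 0 else -1.0)


def build_media(base: Media, supplements: Iterable[str],
                model: Optional[MetabolicModel] = None,
                cap: float = SUPPLEMENT_UPTAKE_DEFAULT) -> Media:
    """Return ``base`` plus supplement exchanges capped at ``cap``.

    When ``model`` is given, every supplement must be an extracellular
    metabolite with an exchange reaction; an unknown id raises a
    ``KeyError`` naming it.
    """
    supplements = list(supplements)
    if model is not None:
        exchangeable = {exchanged_metabolite(r)[0] for r in model.exchanges}
        for met in supplements:
            if met not in exchangeable:
                raise KeyError(
                    f"supplement {met!r} has no exchange reaction in the model")
    if not supplements:
        return base
    return base.with_supplements(supplements, cap=cap)


def apply_media(model: MetabolicModel, media: Optional[Media],
                v_max: float = V_MAX_DEFAULT) -> MetabolicModel:
    """Copy ``model`` with exchange bounds set by ``media``.

    Exchange reactions are written in the export direction
    (``met -> ∅``): uptake is negative flux, so the uptake cap ``u``
    becomes ``lb = -u``.  Exchanges whose metabolite is not in the
    medium get uptake closed.  ``media=None`` leaves bounds untouched.
    """
    out = model.copy()
    if media is None:
        return out
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        met_id, sign = exchanged_metabolite(rxn)
        uptake = media.uptakes.get(met_id, 0.0)
        if sign < 0:  # met -> ∅ : uptake is the reverse direction
            rxn.lower_bound = -float(uptake)
            rxn.upper_bound = v_max
        else:  # ∅ -> met : uptake is the forward direction
            rxn.upper_bound = float(uptake)
            rxn.lower_bound = -v_max
    return out


def open_all_exchanges(model: MetabolicModel,
                       v_max: float = V_MAX_DEFAULT) -> MetabolicModel:
    """Copy ``model`` with every exchange fully open (±v_max).

    This is the "unlimited nutrients" condition used when hunting for
    blocked reactions: every extracellular metabolite is treated as an
    available nutrient.  The biomass reaction is left untouched even
    when it is structurally a single-metabolite drain.
    """
    out = model.copy()
    for rxn in out.reactions:
        if rxn.is_exchange and rxn.id != out.objective:
            rxn.lower_bound = -v_max
            rxn.upper_bound = v_max
    return out


def load_media_tsv(path: str, name: Optional[str] = None) -> Media:
    """Read a two-column TSV (``metabolite_id``, ``max_uptake``)."""
    uptakes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "metabolite_id":
                continue
            uptakes[parts[0]] = float(parts[1])
    return Media(name=name or path, uptakes=uptakes)


def vogels_minimal(sucrose_cap: float = CARBON_UPTAKE_DEFAULT,
                   v_max: float = V_MAX_DEFAULT) -> Media:
    """Vogel's minimal medium with sucrose as the carbon source.

    The carbon source is capped at ``sucrose_cap``; salts, the nitrogen,
    sulfur and phosphate sources and biotin are treated as non-limiting
    (capped only by ``v_max``).  Metabolite ids follow the BioCyc-style
    naming shipped in ``data/vogels.tsv``; models using a different
    namespace should supply their own :class:`Media`.
    """
    ref = importlib.resources.files("farm").joinpath("data/vogels.tsv")
    uptakes = {}
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("metabolite_id"):
            continue
        met, role = line.split("\t")[:2]
        uptakes[met] = sucrose_cap if role == "carbon" else v_max
    return Media(name="vogels_sucrose", uptakes=uptakes)
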