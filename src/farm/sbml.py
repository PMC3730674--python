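"""Read and write COBRA-dialect SBML.

Writing emits SBML Level 3 with the ``fbc`` (flux balance constraints)
package — bounds, objective, chemical formulae, charges and gene-product
associations — plus classic COBRA ``Notes`` fields (``GENE_ASSOCIATION``,
``SUBSYSTEM``, evidence scores) so that legacy toolchains can consume the
file.  Reading accepts both dialects: fbc attributes are preferred, with
kinetic-law ``LOWER_BOUND``/``UPPER_BOUND`` parameters and Notes fields
as fallbacks.  All identifiers pass through the reversible codec in
:mod:`farm.identifiers`.
"""

from __future__ import annotations

import logging
import math
import re

import libsbml

from .identifiers import decode_identifier, encode_identifier
from .model import (
    EvidenceRecord,
    GprParseError,
    GprRule,
    MetabolicModel,
    MetaboliteRecord,
    ReactionRecord,
    V_MAX_DEFAULT,
)

logger = logging.getLogger(__name__)

_NOTE_LINE = re.compile(r"([A-Z_]+):\s*(.*?)\s*\Z")


class SbmlError(ValueError):
    pass


# ---------------------------------------------------------------------------
# notes helpers
# ---------------------------------------------------------------------------

def _notes_dict(sbase) -> dict:
    out = {}
    if not sbase.isSetNotes():
        return out
    text = sbase.getNotesString()
    # strip XML tags, keep line-wise "KEY: value" payloads
    for line in re.sub(r"<[^>]+>", "\n", text).splitlines():
        m = _NOTE_LINE.match(line.strip())
        if m:
            out[m.group(1)] = m.group(2)
    return out


def _set_notes(sbase, fields: dict):
    body = "".join(f"<p>{k}: {v}</p>" for k, v in fields.items() if v != "")
    if not body:
        return
    xml = ('<body xmlns="http://www.w3.org/1999/xhtml">' + body + "</body>")
    if sbase.setNotes(xml) != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise SbmlError(f"could not attach notes to {sbase.getId()!r}")


# ---------------------------------------------------------------------------
# GPR <-> fbc association trees
# ---------------------------------------------------------------------------

def _gpr_to_fbc(node, assoc_parent, fbc_model):
    kind = node[0]
    if kind == "gene":
        ref = assoc_parent.createGeneProductRef()
        ref.setGeneProduct("G_" + encode_identifier(node[1]))
        return
    container = (assoc_parent.createAnd() if kind == "and"
                 else assoc_parent.createOr())
    for child in node[1]:
        _gpr_to_fbc(child, container, fbc_model)


def _fbc_to_gpr(assoc) -> tuple:
    if assoc is None:
        return None
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        gid = assoc.getGeneProduct()
        return ("gene", decode_identifier(gid[2:] if gid.startswith("G_") else gid))
    op = "and" if code == libsbml.SBML_FBC_AND else "or"
    children = tuple(_fbc_to_gpr(assoc.getAssociation(i))
                     for i in range(assoc.getNumAssociations()))
    return (op, children)


# ---------------------------------------------------------------------------
# write
# ---------------------------------------------------------------------------

def write_cobra_sbml(model: MetabolicModel, path: str) -> None:
    """Serialize ``model`` to COBRA-compatible SBML Level 3 + fbc."""
    try:
        _write(model, path)
    except OSError as exc:
        raise SbmlError(f"cannot write SBML to {path!r}: {exc}") from exc


def _write(model: MetabolicModel, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(encode_identifier(model.id or "model"))
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(False)

    compartments = sorted({m.compartment or "c" for m in model.metabolites}) or ["c"]
    for comp in compartments:
        c = sm.createCompartment()
        c.setId(encode_identifier(comp))
        c.setName(comp)
        c.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId("M_" + encode_identifier(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(encode_identifier(met.compartment or "c"))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        spf = sp.getPlugin("fbc")
        if met.formula:
            spf.setChemicalFormula(met.formula)
        spf.setCharge(int(met.charge))
        _set_notes(sp, {"FORMULA": met.formula, "CHARGE": str(met.charge)})

    for gene in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gp.setId("G_" + encode_identifier(gene))
        gp.setLabel(gene)

    bound_params = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"FB_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId("R_" + encode_identifier(rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            if coef < 0:
                ref = sr.createReactant()
            else:
                ref = sr.createProduct()
            ref.setSpecies("M_" + encode_identifier(met_id))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rf = sr.getPlugin("fbc")
        rf.setLowerFluxBound(bound_param(rxn.lower_bound))
        rf.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            gpa = rf.createGeneProductAssociation()
            _gpr_to_fbc(rxn.gpr.expr, gpa, fbc)
        notes = {
            "GENE_ASSOCIATION": rxn.gpr.to_string(),
            "SUBSYSTEM": ";".join(sorted(rxn.pathways)),
        }
        if rxn.evidence is not None:
            ev = rxn.evidence
            notes.update({
                "CURATED": "true" if ev.curated else "false",
                "PATHWAY_SUPPORT": repr(float(ev.pathway_support)),
                "P_BIOCHEM": repr(float(ev.p_biochem)),
                "P_THERMO": repr(float(ev.p_thermo)),
            })
        _set_notes(sr, notes)

    if model.objective is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + encode_identifier(model.objective))
        fo.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise SbmlError(f"libsbml failed to write {path!r}")


# ---------------------------------------------------------------------------
# read
# ---------------------------------------------------------------------------

def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def read_cobra_sbml(path: str) -> MetabolicModel:
    """Parse a COBRA-dialect SBML file into a :class:`MetabolicModel`."""
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        raise SbmlError(f"cannot parse SBML {path!r}: " + "; ".join(msgs))
    sm = doc.getModel()
    if sm is None:
        raise SbmlError(f"no model element in {path!r}")
    fbc = sm.getPlugin("fbc")

    model = MetabolicModel(id=decode_identifier(sm.getId() or "model"))

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        notes = _notes_dict(sp)
        spf = sp.getPlugin("fbc")
        formula = ""
        charge = 0
        if spf is not None and spf.isSetChemicalFormula():
            formula = spf.getChemicalFormula()
        elif "FORMULA" in notes:
            formula = notes["FORMULA"]
        if spf is not None and spf.isSetCharge():
            charge = spf.getCharge()
        elif "CHARGE" in notes:
            charge = int(float(notes["CHARGE"]))
        model.add_metabolite(MetaboliteRecord(
            id=decode_identifier(_strip_prefix(sp.getId(), "M_")),
            name=sp.getName(),
            compartment=decode_identifier(sp.getCompartment()),
            formula=formula,
            charge=charge,
        ))

    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            model.genes.add(decode_identifier(_strip_prefix(gp.getId(), "G_")))

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = decode_identifier(_strip_prefix(sr.getId(), "R_"))
        stoich = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = decode_identifier(_strip_prefix(ref.getSpecies(), "M_"))
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = decode_identifier(_strip_prefix(ref.getSpecies(), "M_"))
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}

        lb, ub = _read_bounds(sr, sm)
        notes = _notes_dict(sr)
        gpr = _read_gpr(sr, notes, rid)
        pathways = {p for p in notes.get("SUBSYSTEM", "").split(";") if p}
        evidence = None
        if "CURATED" in notes:
            evidence = EvidenceRecord(
                curated=notes["CURATED"].lower() == "true",
                pathway_support=float(notes.get("PATHWAY_SUPPORT", 1.0)),
                p_biochem=float(notes.get("P_BIOCHEM", 1.0)),
                p_thermo=float(notes.get("P_THERMO", 1.0)),
            )
        model.add_reaction(ReactionRecord(
            id=rid, name=sr.getName(), stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=gpr,
            pathways=pathways, evidence=evidence,
        ))
        model.genes |= gpr.genes()

    model.objective = _read_objective(sm, fbc)
    if model.objective is None and model.reactions:
        raise SbmlError(f"{path!r} defines no objective reaction")
    model._reindex()
    model.validate()
    return model


def _read_bounds(sr, sm) -> tuple:
    rf = sr.getPlugin("fbc")
    if rf is not None and rf.isSetLowerFluxBound():
        lb = sm.getParameter(rf.getLowerFluxBound()).getValue()
        ub = sm.getParameter(rf.getUpperFluxBound()).getValue()
        return lb, ub
    kl = sr.getKineticLaw()
    if kl is not None:  # legacy COBRA dialect
        lb = ub = None
        for i in range(kl.getNumParameters()):
            p = kl.getParameter(i)
            if p.getId() == "LOWER_BOUND":
                lb = p.getValue()
            elif p.getId() == "UPPER_BOUND":
                ub = p.getValue()
        if lb is not None and ub is not None:
            return lb, ub
    lb = -V_MAX_DEFAULT if sr.getReversible() else 0.0
    return lb, V_MAX_DEFAULT


def _read_gpr(sr, notes: dict, rid: str) -> GprRule:
    text = notes.get("GENE_ASSOCIATION", "")
    if text:
        try:
            return GprRule.parse(text)
        except GprParseError:
            logger.warning("reaction %s: unparseable GENE_ASSOCIATION %r; "
                           "treating as gene-independent", rid, text)
            return GprRule.empty()
    rf = sr.getPlugin("fbc")
    if rf is not None and rf.isSetGeneProductAssociation():
        expr = _fbc_to_gpr(rf.getGeneProductAssociation().getAssociation())
        return GprRule(expr)
    return GprRule.empty()


def _read_objective(sm, fbc):
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getObjective(fbc.getActiveObjectiveId()) or fbc.getObjective(0)
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            if fo.getCoefficient() != 0:
                return decode_identifier(_strip_prefix(fo.getReaction(), "R_"))
    # legacy dialect: OBJECTIVE_COEFFICIENT kinetic-law parameter
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        kl = sr.getKineticLaw()
        if kl is None:
            continue
        for j in range(kl.getNumParameters()):
            p = kl.getParameter(j)
            if p.getId() == "OBJECTIVE_COEFFICIENT" and p.getValue() != 0:
                return decode_identifier(_strip_prefix(sr.getId(), "R_"))
    return None
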