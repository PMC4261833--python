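"""SBML Level 2 I/O in the COBRA dialect.

The supported dialect is the one used by the classic COBRA Toolbox exports:
flux bounds as ``LOWER_BOUND`` / ``UPPER_BOUND`` kinetic-law parameters,
the objective as ``OBJECTIVE_COEFFICIENT``, gene associations as
``GENE_ASSOCIATION:`` lines in the reaction notes, and extracellular
boundary species flagged with ``boundaryCondition``. Species formulas and
charges travel in ``FORMULA:`` / ``CHARGE:`` notes lines. Writing then
reading a model is the identity on metabolites, reactions, bounds, gene
associations and the objective.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import libsbml

from .network import (
    DEFAULT_LB,
    DEFAULT_UB,
    CATEGORIES,
    Metabolite,
    Model,
    Reaction,
    split_compartment,
)

__all__ = ["read_sbml", "write_sbml"]

_NOTE_RE = {
    "gene_association": re.compile(r"GENE_ASSOCIATION:\s*([^<\n]*)"),
    "formula": re.compile(r"FORMULA:\s*([^<\n]*)"),
    "charge": re.compile(r"CHARGE:\s*(-?\d+)"),
    "category": re.compile(r"CATEGORY:\s*([^<\n]*)"),
}


def _note(value_lines: list[str]) -> str:
    ps = "".join(f"<p>{line}</p>" for line in value_lines)
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{ps}</body>'


def _extract(notes: str, key: str) -> str | None:
    m = _NOTE_RE[key].search(notes or "")
    if m:
        val = m.group(1).strip()
        return val or None
    return None


def _species_sid(met_id: str) -> str:
    base, comp = split_compartment(met_id)
    sid = f"M_{base}" + (f"_{comp}" if comp else "")
    return re.sub(r"\W", "_", sid)


def _rxn_sid(rxn_id: str) -> str:
    return "R_" + re.sub(r"\W", "_", rxn_id)


def write_sbml(model: Model, path: str | Path) -> None:
    """Serialise ``model`` as SBML L2 (COBRA dialect)."""
    doc = libsbml.SBMLDocument(2, 1)
    sm = doc.createModel()
    sm.setId(re.sub(r"\W", "_", model.id) or "model")

    comps = sorted({m.compartment or "c" for m in model.metabolites.values()})
    for c in comps:
        comp = sm.createCompartment()
        comp.setId(c)
        comp.setSize(1.0)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_species_sid(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment or "c")
        sp.setBoundaryCondition(bool(met.boundary))
        sp.setInitialConcentration(0.0)
        lines = []
        if met.formula is not None:
            lines.append(f"FORMULA: {met.formula}")
        if met.charge is not None:
            lines.append(f"CHARGE: {met.charge}")
        if lines:
            sp.setNotes(_note(lines))

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(_rxn_sid(rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(bool(rxn.reversible))
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_species_sid(met_id))
            ref.setStoichiometry(abs(float(coef)))
        kl = sr.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pid, value in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            ("OBJECTIVE_COEFFICIENT", 1.0 if model.objective == rxn.id else 0.0),
            ("FLUX_VALUE", 0.0),
        ):
            par = kl.createParameter()
            par.setId(pid)
            par.setValue(float(value))
        lines = [f"GENE_ASSOCIATION: {rxn.gene_association}"]
        if rxn.category != "core":
            lines.append(f"CATEGORY: {rxn.category}")
        sr.setNotes(_note(lines))

    libsbml.writeSBMLToFile(doc, str(path))


def _restore_met_id(sid: str, compartment: str) -> str:
    base = sid[2:] if sid.startswith("M_") else sid
    if compartment and base.endswith(f"_{compartment}"):
        base = base[: -(len(compartment) + 1)]
        return f"{base}[{compartment}]"
    return base


def read_sbml(path: str | Path) -> Model:
    """Parse an SBML L2 COBRA-dialect file into a :class:`Model`.

    Reactions whose kinetic law lacks flux bounds get defaults (reversible:
    -1000/1000, irreversible: 0/1000) with a warning; a species reference
    that resolves to no declared species raises an error naming the
    reaction.
    """
    doc = libsbml.readSBML(str(path))
    if doc.getModel() is None:
        raise ValueError(f"not a parseable SBML file: {path}")
    sm = doc.getModel()
    model = Model(id=sm.getId() or "model")

    sid_to_id: dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        notes = sp.getNotesString() if sp.isSetNotes() else ""
        charge = _extract(notes, "charge")
        met_id = _restore_met_id(sp.getId(), sp.getCompartment())
        met = Metabolite(
            id=met_id,
            name=sp.getName() or "",
            compartment=sp.getCompartment(),
            formula=_extract(notes, "formula"),
            charge=int(charge) if charge is not None else None,
            boundary=bool(sp.getBoundaryCondition()),
        )
        sid_to_id[sp.getId()] = met.id
        model.add_metabolite(met)

    objective = None
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = sr.getId()
        rid = rid[2:] if rid.startswith("R_") else rid
        stoich: dict[str, float] = {}
        for ref, sign in [
            (sr.getReactant(j), -1.0) for j in range(sr.getNumReactants())
        ] + [(sr.getProduct(j), 1.0) for j in range(sr.getNumProducts())]:
            species = ref.getSpecies()
            if species not in sid_to_id:
                raise ValueError(
                    f"reaction {rid}: unresolved species reference {species!r}"
                )
            met_id = sid_to_id[species]
            stoich[met_id] = stoich.get(met_id, 0.0) + sign * ref.getStoichiometry()
        reversible = bool(sr.getReversible())
        lb = ub = obj_coef = None
        if sr.isSetKineticLaw():
            kl = sr.getKineticLaw()
            for j in range(kl.getNumParameters()):
                par = kl.getParameter(j)
                if par.getId() == "LOWER_BOUND":
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND":
                    ub = par.getValue()
                elif par.getId() == "OBJECTIVE_COEFFICIENT":
                    obj_coef = par.getValue()
        if lb is None or ub is None:
            warnings.warn(
                f"reaction {rid}: missing flux bounds, applying defaults "
                f"({'reversible' if reversible else 'irreversible'})"
            )
            lb = DEFAULT_LB if reversible else 0.0
            ub = DEFAULT_UB
        notes = sr.getNotesString() if sr.isSetNotes() else ""
        category = _extract(notes, "category") or "core"
        if category not in CATEGORIES:
            category = "core"
        rxn = Reaction(
            id=rid,
            stoichiometry=stoich,
            reversible=reversible,
            lower_bound=lb,
            upper_bound=ub,
            gene_association=_extract(notes, "gene_association") or "",
            category=category,
            name=sr.getName() or "",
        )
        model.add_reaction(rxn)
        if obj_coef:
            objective = rid
    model.objective = objective
    return model
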