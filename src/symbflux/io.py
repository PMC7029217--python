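"""Readers and writers for stoichiometric models.

Two dialects are supported:

* a COBRA-community JSON schema (``id`` / ``metabolites`` / ``reactions`` /
  ``genes`` with ``lower_bound`` / ``upper_bound`` /
  ``gene_reaction_rule`` keys), so published COBRA JSON exports such as
  the iCC541 bacteroid reconstruction load directly;
* SBML Level 3 with the FBC package (bounds as parameters, GPRs as
  gene-product associations, the objective as an FBC objective).

Reaction kind (internal / transport / exchange / objective) is stored in
the reaction notes on write and inferred from structure when absent, so
third-party files load without modification.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Dict, Optional, Union

import libsbml

from .formulas import ElementalFormula, FormulaError
from .model import DEFAULT_BOUND, MetabolicModel, MetaboliteRecord, ModelError, ReactionRecord


class ModelIOError(ValueError):
    """Raised when a model file cannot be parsed or written."""


def _infer_kind(stoich: Dict[str, float], compartments: Dict[str, str]) -> str:
    if len(stoich) == 1:
        return "exchange"
    comps = {compartments.get(met, "c") for met in stoich}
    if len(comps) > 1:
        return "transport"
    return "internal"


# ----------------------------------------------------------------------
# JSON dialect
# ----------------------------------------------------------------------

def _model_to_json_dict(model: MetabolicModel) -> dict:
    mets = []
    for met in model.metabolites:
        entry = {
            "id": met.id,
            "name": met.name,
            "compartment": met.compartment,
            "charge": met.charge,
            "formula": str(met.formula),
        }
        mets.append(entry)
    rxns = []
    for rxn in model.reactions:
        entry = {
            "id": rxn.id,
            "name": rxn.name,
            "metabolites": dict(rxn.stoichiometry),
            "lower_bound": rxn.lower_bound,
            "upper_bound": rxn.upper_bound,
            "objective_coefficient": 1.0 if rxn.id == model.objective_id else 0.0,
            "notes": {"kind": rxn.kind},
        }
        if rxn.gpr:
            # empty GPRs are omitted, not emitted as empty associations
            entry["gene_reaction_rule"] = rxn.gpr
        rxns.append(entry)
    return {
        "id": model.id,
        "version": "1",
        "metabolites": mets,
        "reactions": rxns,
        "genes": [{"id": g, "name": g} for g in model.genes],
        "compartments": {m.compartment: m.compartment for m in model.metabolites},
    }


def _model_from_json_dict(doc: dict) -> MetabolicModel:
    try:
        raw_mets = doc["metabolites"]
        raw_rxns = doc["reactions"]
    except KeyError as exc:
        raise ModelIOError(f"JSON model missing required key {exc}") from None
    metabolites = []
    compartments: Dict[str, str] = {}
    for entry in raw_mets:
        try:
            formula = ElementalFormula.parse(entry.get("formula") or "")
        except FormulaError:
            formula = ElementalFormula({})  # unparseable formulas -> unknown
        met = MetaboliteRecord(
            id=entry["id"],
            name=entry.get("name", ""),
            formula=formula,
            charge=int(entry.get("charge") or 0),
            compartment=entry.get("compartment") or "c",
        )
        metabolites.append(met)
        compartments[met.id] = met.compartment
    reactions = []
    objective_id: Optional[str] = None
    for entry in raw_rxns:
        stoich = {m: float(c) for m, c in entry.get("metabolites", {}).items()}
        kind = (entry.get("notes") or {}).get("kind") or _infer_kind(stoich, compartments)
        lb = entry.get("lower_bound")
        ub = entry.get("upper_bound")
        rxn = ReactionRecord(
            id=entry["id"],
            name=entry.get("name", ""),
            stoichiometry=stoich,
            lower_bound=-DEFAULT_BOUND if lb is None else float(lb),
            upper_bound=DEFAULT_BOUND if ub is None else float(ub),
            gpr=entry.get("gene_reaction_rule", "") or "",
            kind=kind,
        )
        reactions.append(rxn)
        if float(entry.get("objective_coefficient") or 0.0) != 0.0:
            objective_id = rxn.id
    genes = [g["id"] if isinstance(g, dict) else str(g) for g in doc.get("genes", [])]
    try:
        return MetabolicModel(
            metabolites=metabolites,
            reactions=reactions,
            genes=genes,
            objective_id=objective_id,
            id=doc.get("id", "model"),
        )
    except ModelError as exc:
        raise ModelIOError(str(exc)) from exc


# ----------------------------------------------------------------------
# SBML L3 + FBC
# ----------------------------------------------------------------------

_SBML_REPLACEMENTS = {".": "__DOT__", "-": "__DASH__", ":": "__COLON__"}


def _sbml_id(raw: str) -> str:
    out = raw
    for ch, repl in _SBML_REPLACEMENTS.items():
        out = out.replace(ch, repl)
    return out


def _from_sbml_id(raw: str) -> str:
    out = raw
    for ch, repl in _SBML_REPLACEMENTS.items():
        out = out.replace(repl, ch)
    return out


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_id(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    comps = sorted({m.compartment for m in model.metabolites}) or ["c"]
    for comp in comps:
        c = sbml_model.createCompartment()
        c.setId(_sbml_id(comp))
        c.setConstant(True)
        c.setSize(1.0)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId("M_" + _sbml_id(met.id))
        sp.setName(met.name)
        sp.setCompartment(_sbml_id(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        splug.setCharge(met.charge)
        if not met.formula.is_unknown:
            integral = all(
                float(n).is_integer() for n in met.formula.counts.values()
            )
            if integral:
                splug.setChemicalFormula(str(met.formula))
            else:
                # FBC chemicalFormula forbids fractional counts
                # (pseudo-metabolite formulas); keep those in the notes
                sp.setNotes(
                    '<body xmlns="http://www.w3.org/1999/xhtml">'
                    f"<p>formula: {met.formula}</p></body>"
                )

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _sbml_id(gene))
        gp.setLabel(gene)

    # bounds as shared-by-value parameters
    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId("R_" + _sbml_id(rxn.id))
        rx.setName(rxn.name)
        rx.setReversible(rxn.lower_bound < 0)
        rx.setFast(False)
        rx.setNotes(
            f'<body xmlns="http://www.w3.org/1999/xhtml"><p>kind: {rxn.kind}</p></body>'
        )
        for met_id, coeff in rxn.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies("M_" + _sbml_id(met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr:
            assoc = rplug.createGeneProductAssociation()
            # tokens are matched against gene-product labels (the raw ids)
            assoc.setAssociation(rxn.gpr, False, False)

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sbml_id(model.objective_id))
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelIOError(f"cannot write SBML to {path}")


def _association_to_infix(assoc: libsbml.FbcAssociation, labels: Dict[str, str]) -> str:
    if isinstance(assoc, libsbml.GeneProductRef):
        return labels[assoc.getGeneProduct()]
    parts = [
        _association_to_infix(assoc.getAssociation(i), labels)
        for i in range(assoc.getNumAssociations())
    ]
    if isinstance(assoc, libsbml.FbcAnd):
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        return "(" + " or ".join(parts) + ")"
    raise ModelIOError(f"unsupported GPR association node {type(assoc).__name__}")


def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelIOError(
            f"SBML parse failure in {path} at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelIOError(f"{path} contains no SBML model element")
    mplug = sbml_model.getPlugin("fbc")

    def strip(prefix: str, raw: str) -> str:
        return _from_sbml_id(raw[len(prefix):] if raw.startswith(prefix) else raw)

    metabolites = []
    compartments: Dict[str, str] = {}
    for sp in sbml_model.getListOfSpecies():
        splug = sp.getPlugin("fbc")
        formula = ElementalFormula({})
        charge = 0
        if splug is not None:
            if splug.isSetChemicalFormula():
                try:
                    formula = ElementalFormula.parse(splug.getChemicalFormula())
                except FormulaError:
                    formula = ElementalFormula({})
            if splug.isSetCharge():
                charge = splug.getCharge()
        if formula.is_unknown and sp.isSetNotes():
            match = re.search(r"formula:\s*([A-Za-z0-9.]+)", sp.getNotesString())
            if match:
                try:
                    formula = ElementalFormula.parse(match.group(1))
                except FormulaError:
                    pass
        met = MetaboliteRecord(
            id=strip("M_", sp.getId()),
            name=sp.getName(),
            formula=formula,
            charge=charge,
            compartment=_from_sbml_id(sp.getCompartment()) or "c",
        )
        metabolites.append(met)
        compartments[met.id] = met.compartment

    gene_labels: Dict[str, str] = {}
    genes = []
    if mplug is not None:
        for gp in mplug.getListOfGeneProducts():
            label = gp.getLabel() or strip("G_", gp.getId())
            gene_labels[gp.getId()] = label
            genes.append(label)

    objective_id: Optional[str] = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        active = mplug.getActiveObjective()
        for fo in active.getListOfFluxObjectives():
            if fo.getCoefficient() != 0:
                objective_id = strip("R_", fo.getReaction())

    reactions = []
    for rx in sbml_model.getListOfReactions():
        stoich: Dict[str, float] = {}
        for ref in rx.getListOfReactants():
            met = strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            met = strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        gpr = ""
        rplug = rx.getPlugin("fbc")
        if rplug is not None:
            for getter, default, is_lower in (
                (rplug.getLowerFluxBound, -DEFAULT_BOUND, True),
                (rplug.getUpperFluxBound, DEFAULT_BOUND, False),
            ):
                pid = getter()
                par = sbml_model.getParameter(pid) if pid else None
                value = par.getValue() if par is not None else default
                if is_lower:
                    lb = value
                else:
                    ub = value
            assoc = rplug.getGeneProductAssociation()
            if assoc is not None and assoc.getAssociation() is not None:
                gpr = _association_to_infix(assoc.getAssociation(), gene_labels)
        kind = None
        if rx.isSetNotes():
            notes = rx.getNotesString()
            for candidate in ("internal", "transport", "exchange", "objective"):
                if f"kind: {candidate}" in notes:
                    kind = candidate
                    break
        if kind is None:
            kind = _infer_kind(stoich, compartments)
        if math.isinf(lb):
            lb = -DEFAULT_BOUND
        if math.isinf(ub):
            ub = DEFAULT_BOUND
        reactions.append(
            ReactionRecord(
                id=strip("R_", rx.getId()),
                name=rx.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                kind=kind,
            )
        )

    try:
        return MetabolicModel(
            metabolites=metabolites,
            reactions=reactions,
            genes=genes,
            objective_id=objective_id,
            id=_from_sbml_id(sbml_model.getId()) or "model",
        )
    except ModelError as exc:
        raise ModelIOError(str(exc)) from exc


# ----------------------------------------------------------------------
# Public API
# ----------------------------------------------------------------------

def read_model(path: Union[str, Path], format: Optional[str] = None) -> MetabolicModel:
    """Read a model from ``path`` in the ``sbml`` or ``json`` dialect.

    ``format`` defaults to the file extension (``.xml``/``.sbml`` -> SBML,
    ``.json`` -> JSON).
    """
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model file {path} does not exist")
    fmt = (format or _guess_format(path)).lower()
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelIOError(f"JSON parse failure in {path}: {exc}") from exc
        return _model_from_json_dict(doc)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ModelIOError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write ``model`` so that :func:`read_model` returns an equal model."""
    path = Path(path)
    fmt = (format or _guess_format(path)).lower()
    if fmt == "json":
        path.write_text(json.dumps(_model_to_json_dict(model), indent=1, sort_keys=False))
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ModelIOError(f"unknown model format {fmt!r}")


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ModelIOError(f"cannot guess model format from suffix {suffix!r}")
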