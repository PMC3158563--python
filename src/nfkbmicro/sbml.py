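"""SBML Level 3 import/export of the reaction network.

The exported document carries two compartments (cytoplasm of size ``kv``,
nucleus of size 1 — so ``kv`` is recoverable from the compartment sizes),
all species with their canonical initial concentrations, every rate
constant as a global parameter, and each reaction with its kinetic law as
an amount flux (concentration rate × source-compartment volume).  The
TNFα stimulus appears as a non-constant parameter ``TNF``.

On import, kinetic laws are parsed back to symbolic form and checked
against the package's own rate laws for the variant named in the model
id; mismatches and unmapped species are listed in a validation report
(an imported law that parses but differs is reported, never silently
dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import libsbml
import sympy as sp

from .model import (NUCLEAR, PARAM_NAMES, SPECIES, ModelSystem, ModelVariant,
                    ParameterSet, ValidationError, _sym, build_model)

__all__ = ["SBMLError", "ValidationReport", "write_sbml", "read_sbml"]

_MODEL_ID_PREFIX = "microglial_nfkb"


class SBMLError(ValueError):
    pass


@dataclass
class ValidationReport:
    mismatched_laws: List[str] = field(default_factory=list)
    unmapped_species: List[str] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.mismatched_laws or self.unmapped_species)


def _variant_id(variant: ModelVariant) -> str:
    return "__".join([_MODEL_ID_PREFIX, variant.degradation_pathway,
                      variant.ikk_kinetics, variant.a20_feedback])


def _parse_variant_id(model_id: str) -> ModelVariant:
    parts = model_id.split("__")
    if len(parts) != 4 or parts[0] != _MODEL_ID_PREFIX:
        raise SBMLError(f"model id {model_id!r} does not encode a known variant")
    return ModelVariant(*parts[1:])


def _formula(expr: sp.Expr) -> str:
    return str(expr).replace("**", "^")


def write_sbml(system: ModelSystem, path: str) -> None:
    """Serialize a compiled model (full network only) to SBML Level 3."""
    if system.driven is not None:
        raise SBMLError("only the full (non-driven) model can be exported")
    params = system.params
    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId(_variant_id(system.variant))

    for cid, size in (("cytoplasm", params["kv"]), ("nucleus", 1.0)):
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setSize(size)
        comp.setConstant(True)

    initial = {"NFkB": params["NFkB_tot"], "IKKn": params["IKK_tot"]}
    for name in SPECIES:
        spc = model.createSpecies()
        spc.setId(name)
        spc.setCompartment("nucleus" if name in NUCLEAR else "cytoplasm")
        spc.setInitialConcentration(initial.get(name, 0.0))
        spc.setHasOnlySubstanceUnits(False)
        spc.setBoundaryCondition(False)
        spc.setConstant(False)

    for name in PARAM_NAMES:
        if name == "kv":
            continue  # encoded as the compartment-size ratio
        par = model.createParameter()
        par.setId(name)
        par.setValue(params[name])
        par.setConstant(True)
    tnf = model.createParameter()
    tnf.setId("TNF")
    tnf.setValue(1.0)
    tnf.setConstant(False)

    kv_sym = _sym("kv")
    for rx in system.reactions:
        r = model.createReaction()
        r.setId(rx.name)
        r.setReversible(False)
        for sp_name, nu in rx.stoich.items():
            ref = r.createReactant() if nu < 0 else r.createProduct()
            ref.setSpecies(sp_name)
            ref.setStoichiometry(abs(nu))
            ref.setConstant(True)
        v_src = sp.Integer(1) if rx.compartment == "nucleus" else kv_sym
        amount_rate = sp.together(rx.rate * v_src).subs(kv_sym, _sym("cytoplasm"))
        law = r.createKineticLaw()
        ast = libsbml.parseL3Formula(_formula(amount_rate))
        if ast is None:
            raise SBMLError(f"could not serialize rate law of {rx.name}")
        law.setMath(ast)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SBMLError(f"could not write SBML to {path}")


def read_sbml(path: str) -> Tuple[ModelSystem, ParameterSet, ValidationReport]:
    """Load an SBML file written by (or compatible with) this package.

    Returns the compiled system for the encoded variant, the parameter
    set, and a validation report comparing every kinetic law in the file
    against the package's rate laws (the report is advisory: where laws
    differ, the file's content is flagged rather than silently replaced).
    """
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise SBMLError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}")
    model = doc.getModel()
    if model is None:
        raise SBMLError("file contains no SBML model")
    variant = _parse_variant_id(model.getId())

    comps = {model.getCompartment(i).getId(): model.getCompartment(i).getSize()
             for i in range(model.getNumCompartments())}
    if "cytoplasm" not in comps or "nucleus" not in comps:
        raise SBMLError("expected compartments 'cytoplasm' and 'nucleus'")
    kv = comps["cytoplasm"] / comps["nucleus"]

    values: Dict[str, float] = {"kv": kv}
    for i in range(model.getNumParameters()):
        par = model.getParameter(i)
        if par.getId() in PARAM_NAMES:
            values[par.getId()] = par.getValue()
    missing = [n for n in PARAM_NAMES if n not in values]
    if missing:
        raise SBMLError(f"missing parameters in SBML: {missing}")

    report = ValidationReport()
    file_species = [model.getSpecies(i).getId()
                    for i in range(model.getNumSpecies())]
    report.unmapped_species = [s for s in file_species if s not in SPECIES]
    for s in SPECIES:
        if s not in file_species:
            report.notes.append(f"species {s} absent from file")

    # NFkB_tot / IKK_tot may instead be encoded as initial concentrations
    init = {model.getSpecies(i).getId(): model.getSpecies(i).getInitialConcentration()
            for i in range(model.getNumSpecies())}
    values.setdefault("NFkB_tot", init.get("NFkB", 0.0))
    values.setdefault("IKK_tot", init.get("IKKn", 0.0))

    # permissive bounds: the file is authoritative about its own values
    bounds = {n: (min(v * 0.999, v / 1000.0), max(v * 1000.0, v + 1.0))
              for n, v in values.items()}
    params = ParameterSet(values, bounds)
    system = build_model(variant, params)

    expected = {rx.name: rx for rx in system.reactions}
    local = {name: _sym(name) for name in list(SPECIES) + list(PARAM_NAMES) + ["TNF"]}
    local["cytoplasm"] = _sym("kv")
    local["nucleus"] = sp.Integer(1)
    kv_sym = _sym("kv")
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        rid = r.getId()
        formula = libsbml.formulaToL3String(r.getKineticLaw().getMath())
        try:
            got = sp.sympify(formula.replace("^", "**"), locals=local)
        except (sp.SympifyError, SyntaxError):
            report.mismatched_laws.append(f"{rid}: unparseable law {formula!r}")
            continue
        if rid not in expected:
            report.mismatched_laws.append(f"{rid}: no matching reaction in this package")
            continue
        rx = expected[rid]
        v_src = sp.Integer(1) if rx.compartment == "nucleus" else kv_sym
        want = rx.rate * v_src
        if sp.simplify(got - want) != 0:
            report.mismatched_laws.append(
                f"{rid}: law {formula!r} differs from the package form")
    return system, params, report
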