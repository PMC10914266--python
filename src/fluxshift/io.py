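"""Read and write constraint-based models: SBML L3+fbc and COBRA-style JSON.

SBML handling goes through python-libsbml; JSON is the plain COBRA schema
(keys: metabolites, reactions, genes, lower_bound, upper_bound,
gene_reaction_rule, objective_coefficient).  Bounds missing from a file
default to [-1000, 1000] for reversible and [0, 1000] for irreversible
reactions.
"""

from __future__ import annotations

import json
from pathlib import Path

import libsbml
import numpy as np

from .model import (
    DEFAULT_BOUND,
    GprExpression,
    MetabolicModel,
    ModelValidationError,
    parse_gpr,
)

__all__ = ["read_model", "write_model", "read_json_model", "write_json_model",
           "read_sbml_model", "write_sbml_model"]


def read_model(path, fmt: str = "auto") -> MetabolicModel:
    """Load a model from SBML (L3 + fbc) or COBRA JSON.

    ``fmt`` is one of ``sbml``, ``cobra-json``, ``auto``; auto-detection is
    by file suffix (.xml/.sbml vs .json).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"model file not found: {path}")
    if fmt == "auto":
        fmt = "cobra-json" if path.suffix.lower() == ".json" else "sbml"
    if fmt == "cobra-json":
        return read_json_model(path)
    if fmt == "sbml":
        return read_sbml_model(path)
    raise ValueError(f"unknown model format: {fmt!r}")


def write_model(model: MetabolicModel, path, fmt: str = "auto") -> None:
    path = Path(path)
    if fmt == "auto":
        fmt = "cobra-json" if path.suffix.lower() == ".json" else "sbml"
    if fmt == "cobra-json":
        write_json_model(model, path)
    elif fmt == "sbml":
        write_sbml_model(model, path)
    else:
        raise ValueError(f"unknown model format: {fmt!r}")


# ---------------------------------------------------------------------------
# COBRA JSON
# ---------------------------------------------------------------------------


def read_json_model(path) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    met_ids = [m["id"] for m in doc.get("metabolites", [])]
    met_names = {m["id"]: m.get("name", "") for m in doc.get("metabolites", [])}
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    rxns = doc.get("reactions", [])
    rxn_ids = [r["id"] for r in rxns]

    S = np.zeros((len(met_ids), len(rxns)))
    lb = np.empty(len(rxns))
    ub = np.empty(len(rxns))
    gpr = []
    obj = np.zeros(len(rxns))
    for j, r in enumerate(rxns):
        for mid, coeff in r.get("metabolites", {}).items():
            if mid not in met_index:
                raise ModelValidationError(
                    f"reaction {r['id']!r} references undeclared metabolite {mid!r}"
                )
            S[met_index[mid], j] = float(coeff)
        lo = r.get("lower_bound")
        hi = r.get("upper_bound")
        if lo is None or hi is None:
            # reversibility decides the default lower bound
            rev = bool(r.get("reversible", lo is None and hi is None))
            lo = -DEFAULT_BOUND if rev else 0.0 if lo is None else lo
            hi = DEFAULT_BOUND if hi is None else hi
        lb[j], ub[j] = float(lo), float(hi)
        gpr.append(parse_gpr(r.get("gene_reaction_rule", "")))
        obj[j] = float(r.get("objective_coefficient", 0.0))

    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lb=lb,
        ub=ub,
        gpr=gpr,
        objective_coeffs=obj,
        name=doc.get("id", Path(path).stem),
        metabolite_names=met_names,
    )


def write_json_model(model: MetabolicModel, path) -> None:
    doc = {
        "id": model.name,
        "metabolites": [
            {"id": mid, "name": model.metabolite_names.get(mid, "")}
            for mid in model.metabolite_ids
        ],
        "genes": [{"id": g} for g in sorted(model.gene_ids)],
        "reactions": [],
    }
    for j, rid in enumerate(model.reaction_ids):
        rows = np.nonzero(model.S[:, j])[0]
        doc["reactions"].append(
            {
                "id": rid,
                "metabolites": {model.metabolite_ids[i]: model.S[i, j] for i in rows},
                "lower_bound": model.lb[j],
                "upper_bound": model.ub[j],
                "gene_reaction_rule": model.gpr[j].to_string(),
                "objective_coefficient": model.objective_coeffs[j],
            }
        )
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc
# ---------------------------------------------------------------------------


def _association_to_tree(assoc, gene_map):
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        return gene_map.get(assoc.getGeneProduct(), assoc.getGeneProduct())
    children = tuple(
        _association_to_tree(assoc.getAssociation(i), gene_map)
        for i in range(assoc.getNumAssociations())
    )
    if assoc.isFbcAnd():
        return ("and", children)
    if assoc.isFbcOr():
        return ("or", children)
    raise ModelValidationError("unsupported GPR association node in SBML")


def read_sbml_model(path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise IOError(f"SBML parse error: {err.getMessage().strip()}")
    sb = doc.getModel()
    if sb is None:
        raise IOError(f"no model element in SBML file: {path}")
    fbc = sb.getPlugin("fbc")

    met_ids, met_names = [], {}
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are outside the balanced system
        met_ids.append(sp.getId())
        met_names[sp.getId()] = sp.getName() or ""
    met_index = {mid: i for i, mid in enumerate(met_ids)}

    gene_map = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_map[gp.getId()] = gp.getLabel() or gp.getId()

    n = sb.getNumReactions()
    rxn_ids, gpr = [], []
    S = np.zeros((len(met_ids), n))
    lb = np.empty(n)
    ub = np.empty(n)
    obj = np.zeros(n)

    for j in range(n):
        rx = sb.getReaction(j)
        rxn_ids.append(rx.getId())
        for k in range(rx.getNumReactants()):
            sr = rx.getReactant(k)
            if sr.getSpecies() in met_index:
                S[met_index[sr.getSpecies()], j] -= sr.getStoichiometry()
        for k in range(rx.getNumProducts()):
            sr = rx.getProduct(k)
            if sr.getSpecies() in met_index:
                S[met_index[sr.getSpecies()], j] += sr.getStoichiometry()

        rfbc = rx.getPlugin("fbc")
        lo = hi = None
        if rfbc is not None:
            plo = sb.getParameter(rfbc.getLowerFluxBound() or "")
            phi = sb.getParameter(rfbc.getUpperFluxBound() or "")
            lo = plo.getValue() if plo is not None else None
            hi = phi.getValue() if phi is not None else None
        if lo is None:
            lo = -DEFAULT_BOUND if rx.getReversible() else 0.0
        if hi is None:
            hi = DEFAULT_BOUND
        lb[j], ub[j] = lo, hi

        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            tree = _association_to_tree(
                rfbc.getGeneProductAssociation().getAssociation(), gene_map
            )
            gpr.append(GprExpression(tree))
        else:
            gpr.append(GprExpression(None))

    if fbc is not None:
        active = fbc.getActiveObjective()
        if active is not None:
            rix = {rid: j for j, rid in enumerate(rxn_ids)}
            for i in range(active.getNumFluxObjectives()):
                fo = active.getFluxObjective(i)
                if fo.getReaction() in rix:
                    obj[rix[fo.getReaction()]] = fo.getCoefficient()

    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lb=lb,
        ub=ub,
        gpr=gpr,
        objective_coeffs=obj,
        name=sb.getId() or Path(path).stem,
        metabolite_names=met_names,
    )


def _tree_to_association(node, parent, gene_ids):
    if isinstance(node, str):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_sbml_gene_id(node))
        return
    op, children = node
    assoc = parent.createAnd() if op == "and" else parent.createOr()
    for child in children:
        _tree_to_association(child, assoc, gene_ids)


def _sbml_gene_id(gene: str) -> str:
    # SBML SIds cannot start with a digit or contain '.'
    safe = "".join(c if c.isalnum() or c == "_" else "_" for c in gene)
    return f"G_{safe}"


def write_sbml_model(model: MetabolicModel, path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(_sbml_gene_id(model.name)[2:] or "model")
    fbc = sb.getPlugin("fbc")
    fbc.setStrict(True)

    comp = sb.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    comp.setSize(1.0)

    for mid in model.metabolite_ids:
        sp = sb.createSpecies()
        sp.setId(mid)
        sp.setName(model.metabolite_names.get(mid, ""))
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for g in sorted(model.gene_ids):
        gp = fbc.createGeneProduct()
        gp.setId(_sbml_gene_id(g))
        gp.setLabel(g)

    bound_params = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sb.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for j, rid in enumerate(model.reaction_ids):
        rx = sb.createReaction()
        rx.setId(rid)
        rx.setReversible(bool(model.lb[j] < 0))
        rx.setFast(False)
        for i in np.nonzero(model.S[:, j])[0]:
            coeff = model.S[i, j]
            sr = rx.createReactant() if coeff < 0 else rx.createProduct()
            sr.setSpecies(model.metabolite_ids[i])
            sr.setStoichiometry(abs(float(coeff)))
            sr.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(float(model.lb[j])))
        rfbc.setUpperFluxBound(bound_param(float(model.ub[j])))
        if not model.gpr[j].is_empty:
            gpa = rfbc.createGeneProductAssociation()
            _tree_to_association(model.gpr[j].tree, gpa, model.gene_ids)

    if np.any(model.objective_coeffs != 0):
        objective = fbc.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        fbc.setActiveObjectiveId("obj")
        for j in np.nonzero(model.objective_coeffs)[0]:
            fo = objective.createFluxObjective()
            fo.setReaction(model.reaction_ids[j])
            fo.setCoefficient(float(model.objective_coeffs[j]))

    libsbml.writeSBMLToFile(doc, str(path))
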