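"""Reading and writing the model and table formats.

Two model serializations are supported:

* SBML Level 3 with the FBC v2 package (flux bounds, objective, gene-product
  associations), via python-libsbml;
* a plain JSON dialect (metabolites, reactions with lb/ub/gpr/objective, S as
  coordinate triplets) convenient for fixtures and scripting.

Plus tab-separated readers/writers for expression matrices, objective files
(one reaction id per line), constraint overrides and all result tables.
TSV conventions: header row, UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gpr import GPRRule
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ModelFormatError",
    "read_model_json",
    "write_model_json",
    "read_sbml",
    "write_sbml",
    "read_model",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_objective_file",
    "read_constraint_tsv",
]


class ModelFormatError(ValueError):
    """A model file violates the expected schema."""


# ----------------------------------------------------------------- JSON

def write_model_json(model: MetabolicModel, path) -> None:
    coo = model.S.tocoo()
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "objective": r.objective_coefficient,
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
        "S": [
            [int(i), int(j), float(v)]
            for i, j, v in zip(coo.row, coo.col, coo.data)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_model_json(path) -> MetabolicModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    for key in ("metabolites", "reactions", "S"):
        if key not in doc:
            raise ModelFormatError(f"model JSON missing key {key!r}: {path}")
    mets = []
    for entry in doc["metabolites"]:
        if "id" not in entry:
            raise ModelFormatError(f"metabolite entry missing key 'id': {path}")
        mets.append(
            Metabolite(
                id=entry["id"],
                name=entry.get("name", ""),
                compartment=entry.get("compartment", ""),
            )
        )
    rxns = []
    seen = set()
    for entry in doc["reactions"]:
        for key in ("id", "lb", "ub"):
            if key not in entry:
                raise ModelFormatError(
                    f"reaction entry missing key {key!r}: {path}"
                )
        if entry["id"] in seen:
            raise ModelFormatError(f"duplicate reaction id {entry['id']!r}: {path}")
        seen.add(entry["id"])
        rxns.append(
            Reaction(
                id=entry["id"],
                name=entry.get("name", ""),
                lower_bound=float(entry["lb"]),
                upper_bound=float(entry["ub"]),
                gpr=GPRRule.parse(entry.get("gpr", "")),
                objective_coefficient=float(entry.get("objective", 0.0)),
            )
        )
    rows, cols, vals = [], [], []
    for trip in doc["S"]:
        if len(trip) != 3:
            raise ModelFormatError(f"S triplet of length {len(trip)}: {path}")
        rows.append(int(trip[0]))
        cols.append(int(trip[1]))
        vals.append(float(trip[2]))
    S = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(mets), len(rxns))
    ).tocsc()
    return MetabolicModel(
        id=doc.get("id", path.stem),
        metabolites=mets,
        reactions=rxns,
        S=S,
        genes=list(doc.get("genes", [])),
    )


# ----------------------------------------------------------------- SBML

def _sbml_gpr_to_string(assoc) -> str:
    """Serialize an FBC association tree to the and/or string convention."""

    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return assoc.getGeneProduct()
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [
            _sbml_gpr_to_string(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [
            _sbml_gpr_to_string(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " or ".join(parts) + ")"
    raise ModelFormatError(f"unsupported FBC association node: {assoc}")


def read_sbml(path) -> MetabolicModel:
    import libsbml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromString(path.read_text(encoding="utf-8"))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelFormatError(
            f"SBML parse error in {path}: "
            f"{doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR).getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"no <model> element in {path}")
    fbc = sbml_model.getPlugin("fbc")
    if fbc is None:
        raise ModelFormatError(f"SBML file lacks the FBC package: {path}")

    # gene id mapping: geneProduct SBML id -> label (the biological gene id)
    gene_label: Dict[str, str] = {}
    for i in range(fbc.getNumGeneProducts()):
        gp = fbc.getGeneProduct(i)
        gene_label[gp.getId()] = gp.getLabel() or gp.getId()

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    obj_coefs: Dict[str, float] = {}
    active = fbc.getActiveObjective()
    if active is not None:
        for i in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(i)
            obj_coefs[fo.getReaction()] = fo.getCoefficient()

    mets = []
    met_idx: Dict[str, int] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp_ = sbml_model.getSpecies(i)
        if sp_.getBoundaryCondition():
            continue
        met_idx[sp_.getId()] = len(mets)
        mets.append(
            Metabolite(
                id=sp_.getId(),
                name=sp_.getName() or "",
                compartment=sp_.getCompartment() or "",
            )
        )

    rxns: List[Reaction] = []
    rows, cols, vals = [], [], []
    for j in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(j)
        rfbc = rx.getPlugin("fbc")
        if rfbc is None or not rfbc.isSetLowerFluxBound() or not rfbc.isSetUpperFluxBound():
            raise ModelFormatError(
                f"reaction {rx.getId()!r} lacks FBC flux bounds: {path}"
            )
        lb = params.get(rfbc.getLowerFluxBound())
        ub = params.get(rfbc.getUpperFluxBound())
        if lb is None or ub is None:
            raise ModelFormatError(
                f"reaction {rx.getId()!r} references an undefined bound "
                f"parameter: {path}"
            )
        gpa = rfbc.getGeneProductAssociation()
        gpr_str = ""
        if gpa is not None:
            gpr_str = _sbml_gpr_to_string(gpa.getAssociation())
        try:
            gpr = GPRRule.parse(gpr_str)
        except ValueError as exc:
            raise ModelFormatError(
                f"unparseable GPR on reaction {rx.getId()!r}: {exc}"
            )
        # rename geneProduct ids to labels
        if gene_label and not gpr.is_empty:
            remapped = " ".join(
                gene_label.get(tok, tok) if tok not in ("and", "or", "(", ")")
                else tok
                for tok in gpr_str.replace("(", " ( ").replace(")", " ) ").split()
            )
            gpr = GPRRule.parse(remapped)
        rxns.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=gpr,
                objective_coefficient=float(obj_coefs.get(rx.getId(), 0.0)),
            )
        )
        for side, sign in ((rx.getListOfReactants(), -1.0), (rx.getListOfProducts(), 1.0)):
            for k in range(len(side)):
                ref = side.get(k)
                if ref.getSpecies() not in met_idx:
                    continue  # boundary species
                rows.append(met_idx[ref.getSpecies()])
                cols.append(j)
                vals.append(sign * ref.getStoichiometry())

    S = sp.coo_matrix((vals, (rows, cols)), shape=(len(mets), len(rxns))).tocsc()
    return MetabolicModel(
        id=sbml_model.getId() or path.stem,
        metabolites=mets,
        reactions=rxns,
        S=S,
        genes=sorted(gene_label.values()) if gene_label else [],
    )


def _gpr_to_sbml_assoc(node, fbc_assoc_parent, libsbml) -> None:
    """Recursively build the FBC association tree under ``fbc_assoc_parent``."""

    if isinstance(node, str):
        ref = fbc_assoc_parent.createGeneProductRef()
        ref.setGeneProduct(_gene_sbml_id(node))
        return
    op, children = node
    sub = (
        fbc_assoc_parent.createAnd()
        if op == "and"
        else fbc_assoc_parent.createOr()
    )
    for child in children:
        _gpr_to_sbml_assoc(child, sub, libsbml)


def _gene_sbml_id(gene: str) -> str:
    # SBML SIds must match [A-Za-z_][A-Za-z0-9_]*
    safe = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in gene)
    if not safe or not (safe[0].isalpha() or safe[0] == "_"):
        safe = "G_" + safe
    return safe


def write_sbml(model: MetabolicModel, path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_gene_sbml_id(model.id))
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(True)

    compartments = sorted({m.compartment or "c" for m in model.metabolites})
    for cid in compartments:
        comp = sm.createCompartment()
        comp.setId(_gene_sbml_id(cid))
        comp.setConstant(True)

    for m in model.metabolites:
        s = sm.createSpecies()
        s.setId(m.id)
        s.setName(m.name)
        s.setCompartment(_gene_sbml_id(m.compartment or "c"))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    for g in model.genes:
        gp = mfbc.createGeneProduct()
        gp.setId(_gene_sbml_id(g))
        gp.setLabel(g)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    obj = mfbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    mfbc.setActiveObjectiveId("obj")

    Scsc = model.S.tocsc()
    for j, r in enumerate(model.reactions):
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(r.lower_bound))
        rfbc.setUpperFluxBound(bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            gpa = rfbc.createGeneProductAssociation()
            _gpr_to_sbml_assoc(r.gpr.root, gpa, libsbml)
        if r.objective_coefficient != 0.0:
            fo = obj.createFluxObjective()
            fo.setReaction(r.id)
            fo.setCoefficient(float(r.objective_coefficient))
        col = Scsc[:, j].tocoo()
        for i, v in zip(col.row, col.data):
            ref = rx.createReactant() if v < 0 else rx.createProduct()
            ref.setSpecies(model.metabolites[i].id)
            ref.setStoichiometry(abs(float(v)))
            ref.setConstant(True)

    Path(path).write_text(
        libsbml.writeSBMLToString(doc), encoding="utf-8"
    )


def read_model(path) -> MetabolicModel:
    """Dispatch on extension: .json -> JSON dialect, else SBML."""

    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_model_json(path)
    return read_sbml(path)


# ------------------------------------------------------------- tables

def read_expression_tsv(path) -> pd.DataFrame:
    """Expression matrix: first column gene id, remaining columns samples."""

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ModelFormatError(f"duplicate gene id in expression matrix: {dup!r}")
    return df.astype(float)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_objective_file(path) -> List[str]:
    """Objective file: plain text, one reaction id per line; each line is one
    single-reaction objective to screen."""

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [
        ln.strip()
        for ln in path.read_text(encoding="utf-8").splitlines()
    ]
    return [ln for ln in lines if ln and not ln.startswith("#")]


def read_constraint_tsv(path) -> Dict[str, Tuple[float, float]]:
    """Constraint-override file: TSV with columns reaction_id, lb, ub."""

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    required = {"reaction_id", "lb", "ub"}
    if not required.issubset(df.columns):
        raise ModelFormatError(
            f"constraint file missing columns {sorted(required - set(df.columns))}"
        )
    return {
        str(row.reaction_id): (float(row.lb), float(row.ub))
        for row in df.itertuples()
    }
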