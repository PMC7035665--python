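"""Shared fixtures and independent oracles.

All test inputs are generated programmatically (fluxtk.fixtures); a
session-scoped tree of serialized fixture files (SBML + JSON + expression
TSV) is built under a temporary directory at session start.

The oracles here are deliberately independent of the code paths they
check: dense scipy.linprog formulations for FBA/consistency, a brute-force
GPR truth evaluator, and cobra (GLPK via optlang) as a second LP backend.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterable, Optional, Set, Tuple

import numpy as np
import pytest
from scipy.optimize import linprog

import fluxtk as fk


@pytest.fixture(scope="session")
def toylin():
    return fk.make_toy("TOYLIN")


@pytest.fixture(scope="session")
def toy3():
    return fk.make_toy("TOY3")


@pytest.fixture(scope="session")
def toy3x2():
    return fk.make_toy("TOY3X2")


@pytest.fixture(scope="session")
def toybr():
    return fk.make_toy("TOYBR")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """tests/data tree: every toy in both model dialects + expression TSV."""

    root = tmp_path_factory.mktemp("data")
    for name in fk.fixtures.TOY_NAMES:
        model = fk.make_toy(name)
        fk.write_model_json(model, root / f"{name}.json")
        fk.write_sbml(model, root / f"{name}.xml")
    toy3 = fk.make_toy("TOY3")
    expr = fk.make_expression(toy3, {"s1": {"g1"}, "s2": {"g2"}}, 100.0, 1.0)
    fk.write_expression_tsv(expr, root / "expr_toy3.tsv")
    return root


# ------------------------------------------------------------- oracles

def dense_fba(model, deleted_reactions: Set[str] = frozenset(), sense="max",
              objective: Optional[str] = None) -> float:
    """Independent dense-LP FBA: mutant objective value, 0 if infeasible."""

    n = model.n_reactions
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    for i, r in enumerate(model.reactions):
        if r.id in deleted_reactions:
            lb[i] = ub[i] = 0.0
    if objective is None:
        c = np.array([r.objective_coefficient for r in model.reactions])
    else:
        c = np.zeros(n)
        c[[r.id for r in model.reactions].index(objective)] = 1.0
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=model.S.toarray(),
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        return 0.0
    assert res.status == 0, res.message
    return sign * res.fun


def eval_rule(node, deleted: Set[str]) -> bool:
    """Brute-force GPR truth evaluator over the raw expression tree."""

    if node is None:
        return True
    if isinstance(node, str):
        return node not in deleted
    op, children = node
    vals = [eval_rule(c, deleted) for c in children]
    return all(vals) if op == "and" else any(vals)


def reactions_disabled_by(model, deleted_genes: Set[str]) -> Set[str]:
    return {
        r.id
        for r in model.reactions
        if r.gpr.root is not None and not eval_rule(r.gpr.root, deleted_genes)
    }


def exhaustive_gene_ko(model, objective=None) -> Dict:
    """Unreduced enumeration of all single genes and all unordered pairs."""

    wt = dense_fba(model, objective=objective)
    singles = {
        g: dense_fba(model, reactions_disabled_by(model, {g}), objective=objective)
        for g in model.genes
    }
    pairs = {
        tuple(sorted(p)): dense_fba(
            model, reactions_disabled_by(model, set(p)), objective=objective
        )
        for p in combinations(model.genes, 2)
    }
    return {"wt": wt, "singles": singles, "pairs": pairs}


def reactions_touching(model, mets: Set[str]) -> Set[str]:
    S = model.S.tocsr()
    midx = model.metabolite_index
    out = set()
    for met in mets:
        row = S[midx[met]].tocoo()
        out.update(model.reactions[j].id for j, v in zip(row.col, row.data) if v != 0)
    return out


def exhaustive_met_ko(model, objective=None) -> Dict:
    wt = dense_fba(model, objective=objective)
    mids = model.metabolite_ids
    singles = {
        m: dense_fba(model, reactions_touching(model, {m}), objective=objective)
        for m in mids
    }
    pairs = {
        tuple(sorted(p)): dense_fba(
            model, reactions_touching(model, set(p)), objective=objective
        )
        for p in combinations(mids, 2)
    }
    return {"wt": wt, "singles": singles, "pairs": pairs}


def subset_is_consistent(model, subset: Set[str], epsilon: float) -> bool:
    """Definitional flux consistency of a reaction subset: every member can
    carry |v| >= epsilon with all non-members clamped to zero."""

    rids = [r.id for r in model.reactions]
    lb = np.array([
        r.lower_bound if r.id in subset else 0.0 for r in model.reactions
    ])
    ub = np.array([
        r.upper_bound if r.id in subset else 0.0 for r in model.reactions
    ])
    A_eq = model.S.toarray()
    b_eq = np.zeros(model.n_metabolites)
    for rid in subset:
        j = rids.index(rid)
        best = 0.0
        for sign in (1.0, -1.0):
            c = np.zeros(len(rids))
            c[j] = -sign  # maximize sign * v_j
            res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=list(zip(lb, ub)), method="highs")
            if res.status == 0:
                best = max(best, abs(res.fun))
        if best < epsilon:
            return False
    return True


def to_cobra(model):
    """Convert to a cobra model (GLPK backend) for second-opinion solves."""

    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    rxns = []
    for j, r in enumerate(model.reactions):
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    Scsc = model.S.tocsc()
    for j, r in enumerate(model.reactions):
        col = Scsc[:, j].tocoo()
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[model.metabolites[i].id]: float(v) for i, v in zip(col.row, col.data)}
        )
    objective = {
        cm.reactions.get_by_id(r.id): r.objective_coefficient
        for r in model.reactions
        if r.objective_coefficient != 0.0
    }
    if objective:
        cm.objective = sum(
            coef * rxn.flux_expression for rxn, coef in objective.items()
        )
    return cm
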