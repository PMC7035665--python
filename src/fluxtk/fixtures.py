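"""Deterministic generators for test inputs.

Canonical toy networks:

* ``TOYLIN`` — a strict linear chain: EX_A imports A (cap 10), R1 converts
  A -> B gated by "g1 and g2", EX_B exports B (objective). Every reaction is
  essential; each of g1, g2 is singly lethal.
* ``TOY3`` — TOYLIN with the conversion split into two parallel isozyme
  branches R1 (gpr g1) and R2 (gpr g2): no single gene is lethal but the
  {g1, g2} pair is synthetic lethal.
* ``TOY3X2`` — TOY3 with stoichiometric coefficient 2 on R2's product side
  (2 A -> B via intermediate scaling), to catch S-matrix sign/scale bugs.
* ``TOYBR`` — TOYLIN plus a dead-end branch R3: A -> C gated by g4 whose
  exchange EX_C is closed, so R3/EX_C can never carry flux (fastcc prunes
  them; g4 is never a knockout candidate).

Plus a generator of random flux-consistent parallel-chain models and of
synthetic on/off expression matrices.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Set

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gpr import GPRRule
from .model import MetabolicModel, Metabolite, Reaction

__all__ = ["make_toy", "make_random_model", "make_expression", "TOY_NAMES"]

TOY_NAMES = ("TOYLIN", "TOY3", "TOY3X2", "TOYBR")

_BIG = 1000.0


def _model(name, met_ids, rxn_specs) -> MetabolicModel:
    """rxn_specs: (id, {met: coef}, lb, ub, gpr, objective)."""

    mets = [Metabolite(id=m, name=m, compartment="c") for m in met_ids]
    midx = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    rxns = []
    for j, (rid, stoich, lb, ub, gpr, obj) in enumerate(rxn_specs):
        rxns.append(
            Reaction(
                id=rid,
                name=rid,
                lower_bound=lb,
                upper_bound=ub,
                gpr=GPRRule.parse(gpr),
                objective_coefficient=obj,
            )
        )
        for met, coef in stoich.items():
            rows.append(midx[met])
            cols.append(j)
            vals.append(float(coef))
    S = sp.coo_matrix((vals, (rows, cols)), shape=(len(mets), len(rxns))).tocsc()
    return MetabolicModel(id=name, metabolites=mets, reactions=rxns, S=S)


def make_toy(name: str) -> MetabolicModel:
    """Build one of the canonical toy models by name."""

    if name == "TOYLIN":
        return _model(
            name,
            ["A", "B"],
            [
                ("EX_A", {"A": 1}, 0.0, 10.0, "", 0.0),
                ("R1", {"A": -1, "B": 1}, 0.0, _BIG, "g1 and g2", 0.0),
                ("EX_B", {"B": -1}, 0.0, _BIG, "", 1.0),
            ],
        )
    if name == "TOY3":
        return _model(
            name,
            ["A", "B"],
            [
                ("EX_A", {"A": 1}, 0.0, 10.0, "", 0.0),
                ("R1", {"A": -1, "B": 1}, 0.0, _BIG, "g1", 0.0),
                ("R2", {"A": -1, "B": 1}, 0.0, _BIG, "g2", 0.0),
                ("EX_B", {"B": -1}, 0.0, _BIG, "", 1.0),
            ],
        )
    if name == "TOY3X2":
        # branch R2 consumes two A per B: scale-sensitive variant of TOY3
        return _model(
            name,
            ["A", "B"],
            [
                ("EX_A", {"A": 1}, 0.0, 10.0, "", 0.0),
                ("R1", {"A": -1, "B": 1}, 0.0, _BIG, "g1", 0.0),
                ("R2", {"A": -2, "B": 1}, 0.0, _BIG, "g2", 0.0),
                ("EX_B", {"B": -1}, 0.0, _BIG, "", 1.0),
            ],
        )
    if name == "TOYBR":
        return _model(
            name,
            ["A", "B", "C"],
            [
                ("EX_A", {"A": 1}, 0.0, 10.0, "", 0.0),
                ("R1", {"A": -1, "B": 1}, 0.0, _BIG, "g1 and g2", 0.0),
                ("EX_B", {"B": -1}, 0.0, _BIG, "", 1.0),
                ("R3", {"A": -1, "C": 1}, 0.0, _BIG, "g4", 0.0),
                ("EX_C", {"C": -1}, 0.0, 0.0, "", 0.0),
            ],
        )
    raise KeyError(f"unknown toy model name: {name!r}; choose from {TOY_NAMES}")


def make_random_model(
    n_paths: int,
    path_len: int,
    reversible_frac: float = 0.0,
    seed: int = 0,
) -> MetabolicModel:
    """Random flux-consistent model: ``n_paths`` parallel chains of
    ``path_len`` internal reactions each, from a shared imported substrate
    to a shared exported product (the objective). Each internal reaction is
    assigned 1-2 random genes joined by a random and/or; a ``reversible_frac``
    fraction of internal reactions is made reversible. Consistency holds by
    construction: every chain can carry the full import flux."""

    if n_paths < 1 or path_len < 1:
        raise ValueError("n_paths and path_len must be >= 1")
    rng = np.random.default_rng(seed)
    mets: List[str] = ["SUB", "PROD"]
    specs = [("EX_SUB", {"SUB": 1}, 0.0, 10.0, "", 0.0)]
    n_genes = max(2, n_paths * path_len)
    gene_pool = [f"g{i+1}" for i in range(n_genes)]
    used_genes: Set[str] = set()
    for p in range(n_paths):
        prev = "SUB"
        for s in range(path_len):
            last = s == path_len - 1
            nxt = "PROD" if last else f"I{p+1}_{s+1}"
            if not last:
                mets.append(nxt)
            k = int(rng.integers(1, 3))
            gs = list(rng.choice(gene_pool, size=k, replace=False))
            used_genes.update(gs)
            gpr = gs[0] if k == 1 else f"{gs[0]} {'and' if rng.random() < 0.5 else 'or'} {gs[1]}"
            rev = rng.random() < reversible_frac
            specs.append(
                (
                    f"P{p+1}_S{s+1}",
                    {prev: -1, nxt: 1},
                    -_BIG if rev else 0.0,
                    _BIG,
                    gpr,
                    0.0,
                )
            )
            prev = nxt
    specs.append(("EX_PROD", {"PROD": -1}, 0.0, _BIG, "", 1.0))
    return _model(f"random_{n_paths}x{path_len}_s{seed}", mets, specs)


def make_expression(
    model: MetabolicModel,
    pattern: Dict[str, Iterable[str]],
    on_value: float = 100.0,
    off_value: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Synthetic on/off expression matrix (genes x samples), emulating an
    RSEM-style quantification: genes in a sample's on-set get ``on_value``,
    others ``off_value``, plus optional gaussian noise, truncated at 0."""

    if on_value < 0 or off_value < 0:
        raise ValueError("on/off values must be nonnegative")
    for sample, genes in pattern.items():
        unknown = set(genes) - set(model.genes)
        if unknown:
            raise KeyError(f"sample {sample!r} references unknown genes {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    samples = list(pattern)
    data = np.empty((len(model.genes), len(samples)))
    for j, sample in enumerate(samples):
        on = set(pattern[sample])
        base = np.array(
            [on_value if g in on else off_value for g in model.genes]
        )
        if noise_sd > 0:
            base = base + rng.normal(0.0, noise_sd, size=base.shape)
        data[:, j] = np.maximum(base, 0.0)
    return pd.DataFrame(data, index=pd.Index(model.genes, name="gene"), columns=samples)
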