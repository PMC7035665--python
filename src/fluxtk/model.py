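"""Core data structures of a genome-scale metabolic model.

A model is the stoichiometric matrix S (m metabolites x n reactions),
per-reaction flux bounds and objective coefficients, and the GPR rules
linking reactions to genes. Steady-state flux vectors v satisfy S v = 0
with lb <= v <= ub componentwise (flux units, conventionally
mmol gDW^-1 h^-1). Reversibility is encoded solely by lb < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .gpr import GPRRule

__all__ = ["Metabolite", "Reaction", "MetabolicModel", "validate"]


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GPRRule = field(default_factory=GPRRule)
    objective_coefficient: float = 0.0


@dataclass
class MetabolicModel:
    """Stoichiometry, bounds, objective and gene associations.

    ``S`` is stored sparse (CSC) with shape (len(metabolites),
    len(reactions)); column order matches ``reactions``. ``genes`` is the
    ordered union of all gene ids appearing in GPR rules (extra declared
    genes are flagged by :func:`validate`).
    """

    id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    S: sp.csc_matrix
    genes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S, dtype=float)
        if not self.genes:
            self.genes = sorted(
                set().union(*[r.gpr.genes() for r in self.reactions], set())
            )

    # --- index helpers -------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def metabolite_index(self) -> Dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> Dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    # --- numeric views -------------------------------------------------
    def bounds_arrays(
        self, overrides: Optional[Dict[str, Tuple[float, float]]] = None
    ) -> Tuple[np.ndarray, np.ndarray]:
        """(lb, ub) vectors, with per-reaction overrides applied."""

        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        if overrides:
            ridx = self.reaction_index
            for rid, (lo, hi) in overrides.items():
                if rid not in ridx:
                    raise KeyError(f"unknown reaction id in overrides: {rid!r}")
                if not (np.isfinite(lo) or lo == -np.inf) or np.isnan(lo) or np.isnan(hi):
                    raise ValueError(f"NaN bound for reaction {rid!r}")
                if lo > hi:
                    raise ValueError(
                        f"override lower bound > upper bound for {rid!r}"
                    )
                lb[ridx[rid]] = lo
                ub[ridx[rid]] = hi
        return lb, ub

    def objective_array(self, objective: Optional[str] = None) -> np.ndarray:
        """Objective coefficient vector c; ``objective`` (a reaction id)
        replaces the model's own objective with the unit vector e_i."""

        if objective is None:
            return np.array(
                [r.objective_coefficient for r in self.reactions], dtype=float
            )
        c = np.zeros(self.n_reactions)
        try:
            c[self.reaction_index[objective]] = 1.0
        except KeyError:
            raise KeyError(f"unknown objective reaction id: {objective!r}")
        return c

    # --- structural edits ---------------------------------------------
    def with_bounds(
        self, overrides: Dict[str, Tuple[float, float]]
    ) -> "MetabolicModel":
        """Copy of the model with bound overrides baked in."""

        lb, ub = self.bounds_arrays(overrides)
        rxns = [
            replace(r, lower_bound=float(lb[i]), upper_bound=float(ub[i]))
            for i, r in enumerate(self.reactions)
        ]
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=rxns,
            S=self.S,
            genes=list(self.genes),
        )

    def subnetwork_bounds(self, keep: Sequence[str]) -> Dict[str, Tuple[float, float]]:
        """Bound overrides that zero out every reaction not in ``keep``.

        Keeps reaction indices aligned with the parent model (used for
        context-specific submodels built from an inclusion column).
        """

        keep_set = set(keep)
        return {
            r.id: (0.0, 0.0) for r in self.reactions if r.id not in keep_set
        }


def validate(model: MetabolicModel) -> List[str]:
    """Check the model invariants; returns a list of human-readable
    violations (empty iff the model is well formed). Never raises."""

    out: List[str] = []
    seen = set()
    for m in model.metabolites:
        if not m.id:
            out.append("metabolite with empty id")
        elif m.id in seen:
            out.append(f"duplicate metabolite id: {m.id}")
        seen.add(m.id)
    seen = set()
    for r in model.reactions:
        if not r.id:
            out.append("reaction with empty id")
        elif r.id in seen:
            out.append(f"duplicate reaction id: {r.id}")
        seen.add(r.id)
        if r.lower_bound > r.upper_bound:
            out.append(
                f"reaction {r.id}: lower bound {r.lower_bound} exceeds "
                f"upper bound {r.upper_bound}"
            )
        if not np.isfinite(r.objective_coefficient):
            out.append(f"reaction {r.id}: non-finite objective coefficient")

    m, n = model.S.shape
    if m != model.n_metabolites or n != model.n_reactions:
        out.append(
            f"S shape {model.S.shape} does not match "
            f"({model.n_metabolites} metabolites, {model.n_reactions} reactions)"
        )
    else:
        if model.S.nnz and not np.all(np.isfinite(model.S.data)):
            out.append("S contains non-finite coefficients")
        col_nnz = np.diff(model.S.indptr)
        for j in np.flatnonzero(col_nnz == 0):
            out.append(
                f"reaction {model.reactions[j].id}: empty stoichiometry column"
            )

    declared = set(model.genes)
    used = set().union(*[r.gpr.genes() for r in model.reactions], set())
    for g in sorted(used - declared):
        out.append(f"gene {g} referenced by a GPR but absent from genes list")
    for g in sorted(declared - used):
        out.append(f"gene {g} declared but unused by any GPR")
    return out
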