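"""Linear programs over the steady-state flux polytope.

Flux balance analysis (FBA) optimizes a linear objective c^T v subject to
S v = 0 and lb <= v <= ub. The flux-sum minimization solves
min sum|v| over the same polytope with the extra constraint that the
objective stays at its wild-type optimum f; its nonzero-flux support J is
the basis of the knockout search reduction. Flux variability analysis (FVA)
computes per-reaction flux ranges at a given fraction of the optimum.

All LPs go through a single backend contract (sparse constraint matrix,
row/column bounds, objective, sense); the default backend is HiGHS through
scipy.optimize.linprog. Any LP method satisfying the feasibility and
optimality tolerances is acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "LPError",
    "FBASolution",
    "SupportSet",
    "FVAResult",
    "solve_lp",
    "solve_fba",
    "minimize_total_flux",
    "fva",
]

#: |v| below this is treated as zero when forming the support set J
ZERO_TOL = 1e-6
#: relative relaxation of the objective-fixing constraint in Eq.-2-type LPs
OPT_RELAX = 1e-6


class LPError(RuntimeError):
    """LP backend failure; carries the backend status message."""


@dataclass
class FBASolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: np.ndarray
    reaction_ids: List[str] = field(default_factory=list)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return float(self.fluxes[self.reaction_ids.index(reaction_id)])


@dataclass(frozen=True)
class SupportSet:
    """Reactions carrying nonzero flux in the minimum-total-flux solution at
    the wild-type optimum, plus the genes and metabolites touching them."""

    reactions: frozenset
    genes: frozenset
    metabolites: frozenset


@dataclass
class FVAResult:
    reaction_ids: List[str]
    min_flux: np.ndarray
    max_flux: np.ndarray

    def __getitem__(self, reaction_id: str) -> Tuple[float, float]:
        i = self.reaction_ids.index(reaction_id)
        return float(self.min_flux[i]), float(self.max_flux[i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "reaction_id": self.reaction_ids,
                "min_flux": self.min_flux,
                "max_flux": self.max_flux,
            }
        )


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[sp.spmatrix],
    b_eq: Optional[np.ndarray],
    A_ub: Optional[sp.spmatrix],
    b_ub: Optional[np.ndarray],
    bounds: Sequence[Tuple[float, float]],
    sense: str = "min",
    method: str = "highs",
) -> Tuple[str, float, Optional[np.ndarray]]:
    """Backend entry point. Returns (status, objective in the caller's
    sense, primal vector or None)."""

    if np.any(np.isnan(c)):
        raise LPError("NaN in objective vector")
    for lo, hi in bounds:
        if np.isnan(lo) or np.isnan(hi):
            raise LPError("NaN in variable bounds")
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(bounds),
        method=method,
    )
    status = _STATUS.get(res.status, "error")
    if status in ("error", "iteration_limit"):
        raise LPError(f"LP backend failed: {res.message}")
    if status != "optimal":
        return status, np.nan, None
    return status, sign * float(res.fun), np.asarray(res.x, dtype=float)


def solve_fba(
    model: MetabolicModel,
    sense: str = "max",
    bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None,
    objective: Optional[str] = None,
) -> FBASolution:
    """Flux balance analysis: optimize c^T v s.t. S v = 0, lb <= v <= ub.

    ``bound_overrides`` maps reaction ids to replacement (lb, ub) pairs —
    the hook through which knockouts and context-specific submodels enter.
    ``objective`` (a reaction id) optionally replaces the model objective.
    """

    lb, ub = model.bounds_arrays(bound_overrides)
    if np.any(np.isnan(lb)) or np.any(np.isnan(ub)):
        raise LPError("NaN in flux bounds")
    c = model.objective_array(objective)
    status, fval, x = solve_lp(
        c,
        A_eq=model.S.tocsr(),
        b_eq=np.zeros(model.n_metabolites),
        A_ub=None,
        b_ub=None,
        bounds=list(zip(lb, ub)),
        sense=sense,
    )
    fluxes = x if x is not None else np.full(model.n_reactions, np.nan)
    return FBASolution(
        status=status,
        objective_value=fval,
        fluxes=fluxes,
        reaction_ids=model.reaction_ids,
    )


def minimize_total_flux(
    model: MetabolicModel,
    f: float,
    sense: str = "max",
    bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None,
    objective: Optional[str] = None,
    zero_tol: float = ZERO_TOL,
) -> Tuple[FBASolution, SupportSet]:
    """Minimize sum|v| subject to the FBA constraints and c^T v held at the
    wild-type optimum f.

    Formulated with auxiliary variables t_i >= |v_i| (t - v >= 0 and
    t + v >= 0), minimizing sum t. The optimum-fixing equality is relaxed to
    c^T v >= f - |f|*1e-6 (sense=max; mirrored for min) for numerical
    robustness. Returns the solution (objective_value = the attained
    sum|v|) and the support set J = {i : |v_i| > zero_tol} with the genes
    and metabolites participating in J.
    """

    n = model.n_reactions
    m = model.n_metabolites
    lb, ub = model.bounds_arrays(bound_overrides)
    c_obj = model.objective_array(objective)

    S = model.S.tocsr()
    A_eq = sp.hstack([S, sp.csr_matrix((m, n))], format="csr")
    b_eq = np.zeros(m)

    eye = sp.identity(n, format="csr")
    # v - t <= 0  and  -v - t <= 0
    A_ub_rows = [sp.hstack([eye, -eye]), sp.hstack([-eye, -eye])]
    b_ub = np.zeros(2 * n)
    if np.any(c_obj != 0.0):
        relax = abs(f) * OPT_RELAX
        if sense == "max":
            # c^T v >= f - relax   ->   -c^T v <= -(f - relax)
            row = sp.hstack(
                [sp.csr_matrix(-c_obj), sp.csr_matrix((1, n))]
            )
            A_ub_rows.append(row)
            b_ub = np.concatenate([b_ub, [-(f - relax)]])
        else:
            row = sp.hstack([sp.csr_matrix(c_obj), sp.csr_matrix((1, n))])
            A_ub_rows.append(row)
            b_ub = np.concatenate([b_ub, [f + relax]])
    A_ub = sp.vstack(A_ub_rows, format="csr")

    t_hi = np.maximum(np.abs(lb), np.abs(ub))
    bounds = list(zip(lb, ub)) + [(0.0, float(h)) for h in t_hi]
    cost = np.concatenate([np.zeros(n), np.ones(n)])

    status, total, x = solve_lp(cost, A_eq, b_eq, A_ub, b_ub, bounds, "min")
    if status != "optimal":
        raise LPError(
            f"flux-sum minimization {status}: objective value f={f} is "
            f"inconsistent with the model constraints"
        )
    v = x[:n]
    support_idx = np.flatnonzero(np.abs(v) > zero_tol)
    rxn_ids = frozenset(model.reactions[i].id for i in support_idx)
    genes = frozenset().union(
        *[model.reactions[i].gpr.genes() for i in support_idx], frozenset()
    )
    Scsc = model.S.tocsc()
    met_rows = set()
    for i in support_idx:
        met_rows.update(Scsc[:, i].tocoo().row.tolist())
    mets = frozenset(model.metabolites[i].id for i in met_rows)
    sol = FBASolution(
        status="optimal",
        objective_value=float(total),
        fluxes=v,
        reaction_ids=model.reaction_ids,
    )
    return sol, SupportSet(reactions=rxn_ids, genes=genes, metabolites=mets)


def _fva_one(args):
    (S, m, lb, ub, c_row, c_rhs, j) = args
    n = len(lb)
    cj = np.zeros(n)
    cj[j] = 1.0
    out = []
    for sense in ("min", "max"):
        status, val, _ = solve_lp(
            cj, S, np.zeros(m), c_row, c_rhs, list(zip(lb, ub)), sense
        )
        if status != "optimal":
            raise LPError(f"FVA subproblem for column {j} was {status}")
        out.append(val)
    return j, out[0], out[1]


def fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
    workers: int = 1,
    bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None,
    objective: Optional[str] = None,
) -> FVAResult:
    """Flux variability analysis.

    Solves the wild-type FBA (max) first, then per selected reaction the
    min and max of v_i subject to the FBA constraints plus
    c^T v >= fraction_of_optimum * f (omitted when the objective vector is
    all zero). Results are independent of ``workers``.
    """

    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    lb, ub = model.bounds_arrays(bound_overrides)
    c_obj = model.objective_array(objective)
    wt = solve_fba(model, "max", bound_overrides, objective)
    if not wt.optimal:
        raise LPError(f"wild-type FBA is {wt.status}; FVA aborted")

    if np.any(c_obj != 0.0):
        c_row = sp.csr_matrix(-c_obj)
        c_rhs = np.array([-fraction_of_optimum * wt.objective_value])
    else:
        c_row, c_rhs = None, None

    rxn_ids = model.reaction_ids
    if reactions is None:
        sel = list(range(model.n_reactions))
    else:
        ridx = model.reaction_index
        sel = [ridx[r] for r in reactions]

    S = model.S.tocsr()
    m = model.n_metabolites
    jobs = [(S, m, lb, ub, c_row, c_rhs, j) for j in sel]
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers, backend="threading")(
            delayed(_fva_one)(job) for job in jobs
        )
    else:
        results = [_fva_one(job) for job in jobs]
    results.sort(key=lambda t: t[0])
    return FVAResult(
        reaction_ids=[rxn_ids[j] for j, _, _ in results],
        min_flux=np.array([lo for _, lo, _ in results]),
        max_flux=np.array([hi for _, _, hi in results]),
    )
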