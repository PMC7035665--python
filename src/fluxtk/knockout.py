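"""Genome-wide single/double gene and metabolite knockout screens.

The search-space reduction: first minimize total flux at the wild-type
optimum to obtain the small support set J of reactions that carry flux in
a parsimonious optimal state. Only the genes (or metabolites) participating
in J can lower the optimum when deleted; all other targets are emitted
unevaluated with ratio 1. For double deletions this shrinks the LP grid
from (total targets)^2 to (candidate targets)^2 — e.g. 2194 genes with 251
candidates: 4,813,636 down to 63,001 LPs under the full-grid counting
convention (see :func:`lp_budget`).

For double deletions the candidate relation is second order: besides pairs
within genes(J), each viable candidate g is also paired with the genes of
the support recomputed under g's deletion — otherwise a synthetic-lethal
pair split across two alternate optimal branches (each branch alone able to
carry the optimum) would be missed. A residual approximation remains, as in
flux-support reduction generally: a pair with neither member in the
wild-type support is skipped even though exotic alternate optima could in
principle make it consequential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .lp import LPError, SupportSet, minimize_total_flux, solve_fba
from .model import MetabolicModel

__all__ = [
    "KnockoutRecord",
    "KnockoutTable",
    "evaluate_gpr",
    "apply_gene_deletion",
    "apply_metabolite_deletion",
    "candidate_sets",
    "single_gene_ko",
    "double_gene_ko",
    "single_met_ko",
    "double_met_ko",
    "lp_budget",
]

LETHALITY_CUTOFF = 0.01

Target = Union[str, Tuple[str, str]]


@dataclass(frozen=True)
class KnockoutRecord:
    target: Target  # gene/metabolite id, or sorted pair
    mutant_objective: float
    wild_type_objective: float
    ratio: float
    status: str  # optimal | infeasible
    evaluated: bool

    def is_lethal(self, cutoff: float = LETHALITY_CUTOFF) -> bool:
        return self.evaluated and self.ratio < cutoff


@dataclass
class KnockoutTable:
    objective_id: str
    wild_type_objective: float
    records: List[KnockoutRecord]
    lethality_cutoff: float = LETHALITY_CUTOFF

    def record(self, target: Target) -> KnockoutRecord:
        key = _norm_target(target)
        for rec in self.records:
            if rec.target == key:
                return rec
        raise KeyError(f"no knockout record for target {target!r}")

    def lethals(self) -> List[Target]:
        return [r.target for r in self.records if r.is_lethal(self.lethality_cutoff)]

    def synthetic_lethals(self) -> List[Tuple[str, str]]:
        """Pairs lethal in combination while both singles are viable."""

        singles = {
            r.target: r.ratio for r in self.records if isinstance(r.target, str)
        }
        out = []
        for r in self.records:
            if not isinstance(r.target, tuple) or not r.evaluated:
                continue
            a, b = r.target
            if (
                r.ratio < self.lethality_cutoff
                and singles.get(a, 1.0) >= self.lethality_cutoff
                and singles.get(b, 1.0) >= self.lethality_cutoff
            ):
                out.append(r.target)
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            t1, t2 = (r.target, "") if isinstance(r.target, str) else r.target
            rows.append(
                {
                    "target_1": t1,
                    "target_2": t2,
                    "mutant_objective": r.mutant_objective,
                    "wild_type_objective": r.wild_type_objective,
                    "ratio": r.ratio,
                    "evaluated": r.evaluated,
                    "lethal": r.is_lethal(self.lethality_cutoff),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "target_1",
                "target_2",
                "mutant_objective",
                "wild_type_objective",
                "ratio",
                "evaluated",
                "lethal",
            ],
        )


def _norm_target(target: Target) -> Target:
    if isinstance(target, tuple):
        a, b = target
        return (a, b) if a <= b else (b, a)
    return target


def evaluate_gpr(rule, deleted: Iterable[str]) -> bool:
    """Boolean GPR value with the deleted genes False and all others True;
    the empty rule is True (reaction not gene-associated)."""

    return rule.evaluate(frozenset(deleted))


def apply_gene_deletion(
    model: MetabolicModel, genes: Iterable[str]
) -> Dict[str, Tuple[float, float]]:
    """Bound overrides realizing a gene deletion: every reaction whose GPR
    evaluates False under the deletion is clamped to (0, 0)."""

    deleted = frozenset(genes)
    unknown = deleted - set(model.genes)
    if unknown:
        raise KeyError(f"unknown gene id(s): {sorted(unknown)}")
    return {
        r.id: (0.0, 0.0)
        for r in model.reactions
        if not r.gpr.is_empty and not r.gpr.evaluate(deleted)
    }


def apply_metabolite_deletion(
    model: MetabolicModel,
    metabolites: Iterable[str],
    substrate_only: bool = False,
) -> Dict[str, Tuple[float, float]]:
    """Bound overrides realizing a metabolite knockout (anti-metabolite
    model): block every reaction with nonzero stoichiometry for any listed
    metabolite. With ``substrate_only``, only reactions consuming the
    metabolite (negative coefficient) are blocked."""

    dels = set(metabolites)
    midx = model.metabolite_index
    unknown = dels - set(midx)
    if unknown:
        raise KeyError(f"unknown metabolite id(s): {sorted(unknown)}")
    rows = [midx[m] for m in dels]
    out: Dict[str, Tuple[float, float]] = {}
    Scsr = model.S.tocsr()
    hit = set()
    for i in rows:
        row = Scsr[i].tocoo()
        for j, v in zip(row.col, row.data):
            if v == 0:
                continue
            if substrate_only and v > 0:
                continue
            hit.add(j)
    for j in sorted(hit):
        out[model.reactions[j].id] = (0.0, 0.0)
    return out


def candidate_sets(
    model: MetabolicModel,
    objective: Optional[str] = None,
    bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None,
) -> SupportSet:
    """Wild-type FBA followed by flux-sum minimization; returns the support
    set J with its participating genes and metabolites — the only knockout
    candidates that can affect the wild-type optimum."""

    wt = solve_fba(model, "max", bound_overrides, objective)
    if not wt.optimal:
        raise LPError(f"wild-type FBA is {wt.status}")
    _, support = minimize_total_flux(
        model, wt.objective_value, "max", bound_overrides, objective
    )
    return support


def _mutant_objective(
    model: MetabolicModel,
    overrides: Dict[str, Tuple[float, float]],
    objective: Optional[str],
    base_overrides: Optional[Dict[str, Tuple[float, float]]],
) -> Tuple[float, str]:
    merged = dict(base_overrides or {})
    merged.update(overrides)
    sol = solve_fba(model, "max", merged, objective)
    if sol.status == "infeasible":
        # no feasible steady state => no growth, report 0 under maximization
        return 0.0, "infeasible"
    if not sol.optimal:
        raise LPError(f"mutant FBA is {sol.status}")
    return sol.objective_value, "optimal"


def _ratio(mutant: float, wild_type: float) -> float:
    if wild_type == 0.0:
        return 0.0
    return mutant / wild_type


def _objective_list(
    model: MetabolicModel, objectives: Optional[Sequence[str]]
) -> List[Optional[str]]:
    if objectives is None:
        return [None]
    return list(objectives)


def _solve_targets(jobs, workers):
    if workers > 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=workers, backend="threading")(
            delayed(job)() for job in jobs
        )
    return [job() for job in jobs]


def _single_ko(
    model: MetabolicModel,
    objectives: Optional[Sequence[str]],
    targets: Optional[Iterable[str]],
    all_targets: Sequence[str],
    candidate_of: str,
    deleter,
    workers: int,
    lethality_cutoff: float,
    bound_overrides: Optional[Dict[str, Tuple[float, float]]],
) -> List[KnockoutTable]:
    tables = []
    for obj in _objective_list(model, objectives):
        wt = solve_fba(model, "max", bound_overrides, obj)
        if not wt.optimal:
            raise LPError(f"wild-type FBA is {wt.status}")
        f = wt.objective_value
        support = candidate_sets(model, obj, bound_overrides)
        candidates = getattr(support, candidate_of)
        requested = list(targets) if targets is not None else list(all_targets)

        def make_job(t):
            def job():
                mut, status = _mutant_objective(
                    model, deleter(model, {t}), obj, bound_overrides
                )
                return KnockoutRecord(
                    target=t,
                    mutant_objective=mut,
                    wild_type_objective=f,
                    ratio=_ratio(mut, f),
                    status=status,
                    evaluated=True,
                )

            return job

        eval_targets = [t for t in requested if t in candidates]
        solved = _solve_targets([make_job(t) for t in eval_targets], workers)
        by_target = {r.target: r for r in solved}
        records = []
        for t in requested:
            if t in by_target:
                records.append(by_target[t])
            else:
                records.append(
                    KnockoutRecord(
                        target=t,
                        mutant_objective=f,
                        wild_type_objective=f,
                        ratio=1.0,
                        status="optimal",
                        evaluated=False,
                    )
                )
        tables.append(
            KnockoutTable(
                objective_id=obj or "model_objective",
                wild_type_objective=f,
                records=records,
                lethality_cutoff=lethality_cutoff,
            )
        )
    return tables


def single_gene_ko(
    model: MetabolicModel,
    objectives: Optional[Sequence[str]] = None,
    genes: Optional[Iterable[str]] = None,
    workers: int = 1,
    lethality_cutoff: float = LETHALITY_CUTOFF,
    bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None,
) -> List[KnockoutTable]:
    """Genome-wide single gene knockout; one table per objective.

    Genes outside the candidate set are emitted with evaluated=False and
    ratio 1; candidates are solved as FBA with the gene's deletion bounds.
    A gene is called lethal iff its ratio falls below ``lethality_cutoff``.
    """

    return _single_ko(
        model,
        objectives,
        genes,
        model.genes,
        "genes",
        apply_gene_deletion,
        workers,
        lethality_cutoff,
        bound_overrides,
    )


def single_met_ko(
    model: MetabolicModel,
    objectives: Optional[Sequence[str]] = None,
    metabolites: Optional[Iterable[str]] = None,
    workers: int = 1,
    lethality_cutoff: float = LETHALITY_CUTOFF,
    bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None,
) -> List[KnockoutTable]:
    """Genome-wide single metabolite knockout (anti-metabolite screen)."""

    return _single_ko(
        model,
        objectives,
        metabolites,
        model.metabolite_ids,
        "metabolites",
        apply_metabolite_deletion,
        workers,
        lethality_cutoff,
        bound_overrides,
    )


def _double_ko(
    model: MetabolicModel,
    objectives: Optional[Sequence[str]],
    all_targets: Sequence[str],
    candidate_of: str,
    deleter,
    workers: int,
    lethality_cutoff: float,
    bound_overrides: Optional[Dict[str, Tuple[float, float]]],
    include_unevaluated_pairs: bool,
) -> List[KnockoutTable]:
    tables = []
    single_fn = {
        "genes": single_gene_ko,
        "metabolites": single_met_ko,
    }[candidate_of]
    for obj in _objective_list(model, objectives):
        single_tables = single_fn(
            model,
            [obj] if obj is not None else None,
            None,
            workers,
            lethality_cutoff,
            bound_overrides,
        )
        singles = single_tables[0]
        f = singles.wild_type_objective
        support = candidate_sets(model, obj, bound_overrides)
        candidates = sorted(t for t in all_targets if t in getattr(support, candidate_of))

        # second-order candidates: for each viable first deletion, the
        # support of the surviving optimum names the partners that could
        # complete a synthetic-lethal pair across alternate optima
        extra_pairs = set()
        for g in candidates:
            rec = singles.record(g)
            if not rec.evaluated or rec.ratio < lethality_cutoff:
                continue
            merged = dict(bound_overrides or {})
            merged.update(deleter(model, {g}))
            try:
                sub_support = candidate_sets(model, obj, merged)
            except LPError:
                continue
            for h in getattr(sub_support, candidate_of):
                if h != g and h in all_targets:
                    extra_pairs.add(tuple(sorted((g, h))))

        def make_job(pair):
            def job():
                mut, status = _mutant_objective(
                    model, deleter(model, set(pair)), obj, bound_overrides
                )
                return KnockoutRecord(
                    target=pair,
                    mutant_objective=mut,
                    wild_type_objective=f,
                    ratio=_ratio(mut, f),
                    status=status,
                    evaluated=True,
                )

            return job

        pairs = sorted(
            {tuple(sorted(p)) for p in combinations(candidates, 2)} | extra_pairs
        )
        solved = _solve_targets([make_job(p) for p in pairs], workers)
        records = list(singles.records) + list(solved)
        if include_unevaluated_pairs:
            evaluated_pairs = set(pairs)
            for pair in combinations(sorted(all_targets), 2):
                if tuple(sorted(pair)) in evaluated_pairs:
                    continue
                records.append(
                    KnockoutRecord(
                        target=tuple(sorted(pair)),
                        mutant_objective=f,
                        wild_type_objective=f,
                        ratio=1.0,
                        status="optimal",
                        evaluated=False,
                    )
                )
        tables.append(
            KnockoutTable(
                objective_id=obj or "model_objective",
                wild_type_objective=f,
                records=records,
                lethality_cutoff=lethality_cutoff,
            )
        )
    return tables


def double_gene_ko(
    model: MetabolicModel,
    objectives: Optional[Sequence[str]] = None,
    workers: int = 1,
    lethality_cutoff: float = LETHALITY_CUTOFF,
    bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None,
    include_unevaluated_pairs: bool = True,
) -> List[KnockoutTable]:
    """Genome-wide double gene knockout.

    The table contains both the single-gene records (the grid diagonal,
    reused rather than re-solved) and one record per unordered candidate
    pair; pairs involving a non-candidate gene are emitted unevaluated.
    A pair is synthetic lethal iff its ratio is below the cutoff while both
    single deletions are viable (see KnockoutTable.synthetic_lethals).
    """

    return _double_ko(
        model,
        objectives,
        model.genes,
        "genes",
        apply_gene_deletion,
        workers,
        lethality_cutoff,
        bound_overrides,
        include_unevaluated_pairs,
    )


def double_met_ko(
    model: MetabolicModel,
    objectives: Optional[Sequence[str]] = None,
    workers: int = 1,
    lethality_cutoff: float = LETHALITY_CUTOFF,
    bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None,
    include_unevaluated_pairs: bool = True,
) -> List[KnockoutTable]:
    """Genome-wide double metabolite knockout; contract mirrors
    :func:`double_gene_ko` with metabolite candidates."""

    return _double_ko(
        model,
        objectives,
        model.metabolite_ids,
        "metabolites",
        apply_metabolite_deletion,
        workers,
        lethality_cutoff,
        bound_overrides,
        include_unevaluated_pairs,
    )


def lp_budget(total_targets: int, candidate_targets: int) -> Tuple[int, int]:
    """LP counts before/after the support-set reduction under the full-grid
    convention: naive = total^2, reduced = candidates^2 (the count the
    reduction is reported against; e.g. 2194 genes, 251 candidates ->
    4,813,636 vs 63,001)."""

    if total_targets < 0 or candidate_targets < 0:
        raise ValueError("target counts must be nonnegative")
    if candidate_targets > total_targets:
        raise ValueError("candidate_targets cannot exceed total_targets")
    return total_targets**2, candidate_targets**2
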