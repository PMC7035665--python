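# fluxtk

Constraint-based metabolic modeling for genome-scale models and cohorts of
expression profiles: flux balance analysis (FBA), flux variability analysis
(FVA), genome-wide single/double gene and metabolite knockout screens with a
flux-support search reduction, artificially-centered hit-and-run (ACHR)
sampling of the flux polytope, expression-driven context-specific model
extraction (FASTCC consistency pruning + FASTCORE), and a one-command
pipeline that turns a gene-expression matrix into per-sample models and
their modeling results.

It is written for systems biologists who want these screens scriptable in
Python over SBML (Level 3 + FBC) or a plain JSON model dialect, with every
analysis reproducible from a seed.

## The model

A metabolic network with m metabolites and n reactions is summarized by its
stoichiometric matrix S (m × n). Steady-state flux vectors v satisfy

    S v = 0,   lb ≤ v ≤ ub,

and FBA optimizes a linear objective cᵀv (typically biomass production)
over this polytope:

    max / min cᵀv   s.t.   S v = 0,  lb ≤ v ≤ ub.

**Knockout screens.** Deleting gene set G clamps to zero every reaction
whose gene–protein–reaction (GPR) boolean rule evaluates false with G
false; deleting a metabolite clamps every reaction it touches
(anti-metabolite model). Screening all gene pairs of a genome-scale model
naively costs (n_genes)² LPs. The reduction: solve

    min Σ|v|   s.t.   S v = 0,  lb ≤ v ≤ ub,  cᵀv = f

(f the wild-type optimum); the support J = {i : |vᵢ| > 0} is small, and
only genes/metabolites participating in J can lower the optimum. With 2194
genes and 251 support genes the double-knockout grid drops from 4,813,636
to 63,001 LPs. For double deletions the candidate relation is second order:
each viable candidate is additionally paired against the support recomputed
under its own deletion, so synthetic-lethal pairs split across alternate
optimal branches are still found. A pair is synthetic lethal when the
double mutant's objective ratio falls below the lethality cutoff (default
0.01) while both single deletions are viable.

**Sampling.** ACHR draws near-uniform samples from the flux polytope:
LP-generated warmup points seed a direction pool and a running center; each
step moves the current point along a direction from the center toward a
random pool point, by a step length uniform over the feasible segment.

**Context-specific extraction.** Per sample, gene expression is mapped onto
reactions through the GPR rules (AND = min, OR = max); reactions scoring at
or above the cutoff form the core, and FASTCORE extracts a small
flux-consistent subnetwork containing the core from a FASTCC-consistent
input model.

## Worked example

TOY3 is a four-reaction toy: substrate import `EX_A` (capacity 10), two
parallel isozyme branches `R1` (gene g1) and `R2` (gene g2) converting A to
B, and export `EX_B` as objective.

```python
import fluxtk as fk

model = fk.make_toy("TOY3")
print(fk.solve_fba(model).objective_value)     # 10.0

support = fk.candidate_sets(model)
print(sorted(support.reactions))               # ['EX_A', 'EX_B', 'R1']
print(sorted(support.genes))                   # ['g1']

table = fk.double_gene_ko(model)[0]
print(table.to_frame().to_string(index=False))
print(table.synthetic_lethals())               # [('g1', 'g2')]
```

The knockout table this prints:

```
target_1 target_2  mutant_objective  wild_type_objective  ratio  evaluated  lethal
      g1                       10.0                 10.0    1.0       True   False
      g2                       10.0                 10.0    1.0      False   False
      g1       g2              -0.0                 10.0   -0.0       True    True
```

Reading it: either single deletion reroutes flux through the other branch
(ratio 1.0, viable; g2 was never solved because deleting it cannot touch
the parsimonious support — `evaluated False`), but the pair severs both
branches and abolishes the objective, a synthetic-lethal pair. On a
genome-scale instance the same reduction is what makes the pair screen
tractable: `fk.lp_budget(2194, 251)` → `(4813636, 63001)`.

The same operations are available from the shell:

```bash
fluxtk fba --model toy3.json                      # model_objective  optimal  10
fluxtk doubleGeneKO --model toy3.json --out dko.tsv
fluxtk mcmc --model toy3.json --points 2000 --steps 1000 --seed 1 --out s.tsv
fluxtk run params.txt                             # the one-command pipeline
```

where `params.txt` holds `key = value` lines (model, expression,
objectives, cutoff, ncpu, out, ...). The pipeline writes
`inclusion_matrix.tsv`, `fva.tsv`, the four knockout tables,
`mcmc_samples/<sample>.tsv` and a checksummed `manifest.json` under the
output directory.

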