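# Methods

## Scope and model assumptions

fluxtk analyses steady-state flux distributions of genome-scale metabolic
models: flux vectors v with S v = 0 inside box bounds lb ≤ v ≤ ub (flux
units are those of the model, conventionally mmol·gDW⁻¹·h⁻¹). Bounds are
closed intervals; reversibility is encoded solely by lb < 0. Objectives are
linear (cᵀv); thermodynamic/loop-law constraints, quadratic objectives
(MOMA) and kinetics are out of scope. GPR rules are monotone boolean
expressions over gene ids (AND/OR, no negation — negation does not occur in
metabolic GPRs); the empty rule means "not gene-associated" and always
evaluates true.

## Linear programming

All LPs go through one backend contract (sparse constraint matrix, row and
column bounds, objective, sense) implemented on HiGHS via
`scipy.optimize.linprog`. The contract is solver-agnostic: any LP method
meeting the feasibility tolerances is acceptable, and the test suite
cross-checks objective values against an independent dense formulation and
against a GLPK-based solver (cobra) to 1e-7.

*Flux-sum minimization.* min Σ|v| at a fixed objective value f is
linearized with auxiliary variables tᵢ ≥ |vᵢ| (tᵢ ≥ vᵢ, tᵢ ≥ −vᵢ,
minimize Σt). The optimum-fixing constraint is relaxed to
cᵀv ≥ f − |f|·1e−6 (mirrored for minimization objectives): an exact
equality against a floating-point optimum is numerically brittle. Support
membership uses zero_tol = 1e−6 in flux units, matching common LP
feasibility tolerances.

*FVA.* Default fraction_of_optimum = 1.0 — variability at the optimal
state; the near-optimality constraint cᵀv ≥ fraction·f is omitted when the
objective vector is zero. Per-reaction subproblems are embarrassingly
parallel; the `workers` parameter only batches them (threaded joblib) and
results are bit-identical for any worker count.

## Knockout screens and the support reduction

Deleting genes G zero-bounds every reaction whose GPR is false under G;
deleting metabolites zero-bounds every reaction with nonzero stoichiometry
for them. Metabolite deletion blocks producers *and* consumers by default —
the anti-metabolite analogy (an analogue jamming every enzyme that binds
the metabolite) does not settle the direction question, so a
`substrate_only` option restricts blocking to consumers.

Only targets participating in the parsimonious optimal support J can lower
the wild-type optimum: if a deletion disables no reaction of J, the
J-solution survives it. Non-candidates are therefore emitted unevaluated
with ratio 1. For pairs, candidacy is second order: a synthetic-lethal pair
{g, h} with both singles viable must have one member (say g) in genes(J),
and h must appear in the support recomputed under g's deletion — otherwise
the g-mutant's parsimonious solution would survive h's deletion. The
double screen therefore evaluates all candidate–candidate pairs plus the
pairs found by re-deriving the support under each viable candidate's
deletion. Pairs outside this relation cannot be synthetic lethal (the
property suite verifies this by exhaustive enumeration on every fixture
model); their records carry evaluated = false.

An infeasible mutant LP under maximization is reported as objective 0: no
feasible steady state means no growth. The lethality cutoff on the
mutant/wild-type ratio defaults to 0.01 — growth below 1 % of wild type is
biologically indistinguishable from none at LP tolerances.

`lp_budget` reports the full-grid counting convention (total², candidate²):
it is the convention under which the reduction of a 2194-gene double
screen to 251 candidates reads 4,813,636 → 63,001 LPs. The solver itself
enumerates each unordered pair once; the two numbers answer different
questions (grid size vs. work done) and are kept separate on purpose.

## ACHR sampling

Warmup points are LP vertices: the flux vectors attaining each reaction's
FVA minimum and maximum (2n points), topped up with optima of random
sparse ±1 objectives when more are requested. The sampler keeps a pool of
points (warmup plus previously emitted samples; a warmup-only pool is an
option) and a running center (incremental mean over all accepted states).
Each step: draw a pool point, take the unit direction from the center to
it, compute the feasible step interval from the bounds, draw the step
length uniformly, move, update the center. One sample is emitted every
n_steps steps; defaults are n_points = 2000 and n_steps = 1000.

Numerical drift control: directions between feasible points lie in
null(S) exactly, but floating-point error accumulates over millions of
steps. Each direction is projected onto an orthonormal null-space basis of
S (dense, computed once — appropriate at the model sizes sampled here),
and the current point is re-projected every 1000 steps. Measured drift
after 2 × 10⁶ steps is ~1e−14, far inside the 1e−7 contract on
max |S v|. Degenerate directions (pool point within 1e−12 of the center)
are re-drawn up to a retry limit; a polytope that is a single point is
detected and yields a constant chain rather than an error.

One chain is one seed (`numpy.random.default_rng`); identical
(model, warmup, seed) gives bit-identical chains. Convergence diagnostics
beyond the distributional tests (uniformity on a segment, analytic
triangle moments) are out of scope.

## Context-specific extraction

Expression-to-reaction mapping aggregates through the GPR: AND = min (a
complex is limited by its scarcest subunit), OR = max (isozymes are
interchangeable); genes absent from the column score 0. Reactions with no
GPR score +∞ — absence of gene evidence is not evidence of absence — but
are *not* placed in the expression core: they join a context model only
when the extractor needs them. The expression cutoff is closed
(score ≥ cutoff), switchable to strict.

FASTCC is implemented as the definitional fixed point: iteratively remove
every reaction whose maximal |flux| in the current subnetwork (two LPs)
falls below ε, until none remains; the certificates (each survivor can
carry ≥ ε, each removal cannot in the survivors' subnetwork) are re-proved
by an independent dense LP in the tests. FASTCORE alternates the two LPs
of the standard procedure: LP7 maximizes how many pending core reactions
reach ε; LP10 realizes the reached ones while minimizing total flux
through non-core (penalty) reactions, on a polytope scaled by 1e5 with the
support threshold kept at 0.99 ε — the scaling is what keeps a supporting
reaction whose stoichiometry ties it to a small fraction of a core flux
above threshold. Reversible core reactions that resist forward are flipped
and retried, with a singleton fallback; an unreachable core reaction
raises an error naming it. Containment and consistency of the output are
guaranteed; minimality is heuristic (exact at fixture scale, verified by
exhaustive subset search).

ε = 1e−4 flux units throughout, the customary consistency threshold —
comfortably above LP tolerance (1e−9) and below any biologically relevant
flux.

## Pipeline

The parameter file is `key = value` lines or JSON by extension. Per-sample
submodels are realized as (0, 0) bound overrides on excluded reactions, so
reaction indices stay aligned with the inclusion-matrix rows. Stages per
sample run in a fixed order (reconstruction → FVA → geneKO ×2 → metKO ×2 →
sampling); sampling is on by default and gated by `run_mcmc`, since
cohort-scale sampling dominates runtime. A stage failure marks the sample
failed in the manifest and the run continues. The manifest records the
config snapshot and sha256 checksums of every output; outputs are
byte-identical for any `ncpu`.

## Synthetic data

The fixture generators define the regimes the tests probe. The toys pin
down one mechanism each: TOYLIN (essential chain), TOY3 (parallel isozymes
— synthetic lethality across alternate optima), TOY3X2 (stoichiometric
coefficient 2 — catches S-matrix sign/scale bugs), TOYBR (dead-end branch —
consistency pruning and candidate exclusion). Random models are parallel
chains between a shared substrate (import capped at 10) and product, with
1–2 random genes per reaction and a configurable reversible fraction;
they are flux-consistent and solvable by construction. Expression
matrices are on/off (defaults 100 vs 1 against the cutoff 75, the
presence/absence regime of RSEM-quantified data) with optional truncated
gaussian noise.

What the generators do not emulate: realistic network topology (loops,
cofactor coupling, compartments), correlated expression, dosage effects,
or genome-scale dimensions. Passing tests certify algorithmic correctness
at desk scale — oracle equivalence, certificates, determinism — not
biological fidelity on human-scale models.

## Problem sizes and tolerances in the shipped checks

The acceptance script samples 2000 points × 1000 steps on two models
(TOY3, random 4×3 chains) and reports the measured max |S v| (observed
~1e−14, bound 1e−7). Distributional tests use 2000 points with shorter
burn-in per point (10–100 steps), chosen as the decorrelation scale of
these low-dimensional polytopes; moment checks use 3 analytic standard
errors, the uniformity check a 99 % Kolmogorov–Smirnov band. Exhaustive
knockout and subset-search oracles run on models with ≤ 10 genes and ≤ 14
reactions, where enumeration is exact and fast.

## Known limitations

- Triple and higher-order knockouts are not supported.
- The double-knockout reduction, like any support-based screen, reports
  unevaluated pairs as ratio 1 by fiat; the guarantee proved and tested is
  "no synthetic-lethal pair is missed", not "every unevaluated pair's
  exact ratio is 1".
- The dense null-space projection in the sampler is quadratic in n and
  meant for models up to a few thousand reactions; beyond that a sparse
  QR/iterative projector would be needed.
- FASTCORE minimality is heuristic; alternative extractors (mCADRE, GIMME,
  tINIT) are not implemented.
- Alternate-optima ambiguity in the flux-sum support makes J itself
  solver-dependent; all shipped contracts are stated so that results do
  not depend on which optimal support the backend returns.
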