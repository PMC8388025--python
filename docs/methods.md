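# Methods

This note documents the models, numerical choices, and design decisions
behind strainbench, and what the test fixtures do and do not demonstrate.

## Constraint-based core

A model is a stoichiometric matrix `S` (metabolites × reactions), flux
bounds, GPR rules, and one objective (biomass) reaction. All simulators work
on the steady-state polytope `{v : S v = 0, lb ≤ v ≤ ub}`. Directionality is
encoded purely by bounds — there is no separate reversibility flag, so the
bounds are the single source of truth. Infinite bounds from input files are
clamped to ±1000 mmol·gDW⁻¹·h⁻¹, the usual convention that keeps every LP
bounded.

Simulators consume *views*: copy-on-write overlays that merge bounds with
precedence candidate constraints > environmental conditions (medium) >
model defaults, mirroring how a strain-design run layers a mutant on a
medium on a model. Views also carry extra linear constraints (the protein
pool), so every method honours them without special cases. The base model
is never mutated — an evolutionary run evaluates thousands of candidate
views against one shared model.

### Solver backend

One backend, scipy's HiGHS (`scipy.optimize.milp`), serves both LP and
MILP behind a small problem-container contract. No quadratic capability is
configured, so classical MOMA raises a capability error pointing to lMOMA;
this keeps the workbench runnable on a ubiquitous solver stack while the
method roster stays honest about what it solves. Feasibility and equality
assertions use a tolerance of 1e-6; LP solutions are never rounded. Ties
among alternate optima are resolved by the solver — tests assert objective
values and invariants, never full flux vectors, except where the optimum is
provably unique.

### Method contracts

- **pFBA** fixes the objective flux by *equality* at `fraction × optimum`
  (default 1.0) and minimizes `Σ|v|` via split variables; the reported
  objective value is the stage-1 optimum, the minimal total flux is reported
  separately.
- **FVA** constrains the objective to ≥ `fraction × optimum` and solves two
  LPs per queried reaction.
- **lMOMA / ROOM** default their reference to the *wild-type pFBA*
  distribution (the paper-adjacent literature is split between FBA and pFBA
  references; pFBA is unique more often, and the choice is logged). ROOM's
  window parameters default to δ = 0.03, ε = 0.001, the canonical values
  from the ROOM literature.

## GPR algebra

GPRs parse into And/Or trees (`and` binds tighter than `or`). Deletions use
Boolean evaluation; expression levels substitute gene folds (1 = wild type)
and reduce And/Or with min/max — a complex is limited by its scarcest
subunit, isozymes contribute their best. The reductions are injectable
(e.g. `sum` for additive isozymes). Reaction folds map to bounds against
the wild-type flux `w`:

- γ < 1 caps the flux at `γ·w` preserving the wild-type sign;
- γ > 1 raises the lower bound toward `γ·w` (clamped into the original
  bounds) rather than widening the range — over-expression should *force*
  flux, not merely permit it;
- γ > 1 with `w = 0` is a no-op: there is no direction in which to force an
  unused reaction. Decoders log this case per candidate.

Missing genes default to level 1: modification sets are sparse and
unmentioned genes are unchanged.

## Regulation

Regulatory rules are Boolean (`target = expr`, operators and/or/not,
`env_`-prefixed signals). The update scheme is synchronous — the classical
choice for regulatory FBA — and a trajectory that enters a cycle is
collapsed by element-wise AND (a gene is on only if on throughout the
cycle), which is the conservative reading. rFBA here is the single-step
variant (steady state, then one FBA): it is used as a mutant-evaluation
routine inside optimization loops, not as a time-course simulator.

srFBA solves one MILP: a binary per regulatory identifier, rules linearized
with standard AND/OR/NOT encodings, and reaction fluxes coupled to their
GPR binaries via `lb·b ≤ v ≤ ub·b`. Cyclic binaries are left free
(optimistic), so srFBA and rFBA agree on acyclic networks and may diverge
on cycles — a documented asymmetry between the conservative iterative route
and the optimistic joint optimum.

In regulatory problems a Boolean regulator admits no fractional level:
γ = 0 (and any γ < 1) freezes it off, γ > 1 freezes it on. Metabolic gene
levels are applied *after* the regulatory steady state, so direct
modifications override regulatory silencing; the order is fixed and logged.

## Enzymatic constraints

The single-pool formulation adds `Σ (MW_j/kcat_j)·v_j ≤ P_pool` over
parameterized reactions — the same constraint semantics as pool-constrained
enzyme models that introduce pseudo-metabolites, at a fraction of the
surface area. Parameterized reactions must be irreversible; a provided
utility splits reversible reactions explicitly (implicit model surgery is
error-prone). Enzyme-level modifications cap a reaction's usage at
`γ ×` its wild-type usage; over-expression relaxes the per-reaction cap
while the global pool still binds.

## Objectives and evaluation

BPCY is `v_bio·v_prod`, normalized by `|v_sub|` when a substrate is
configured (both forms are standard; the choice is explicit in config and
zero-uptake cases return 0 rather than raising). WYIELD fixes biomass at
`objective_fraction` (default 1.0) of the mutant optimum, runs FVA on the
product and returns `α·v_max + (1−α)·v_min` with α defaulting to the
unbiased midpoint 0.5. Infeasible candidates never raise inside a run: they
get worst-case sentinel fitness and are dominated by every feasible
candidate. Evaluations are cached by decoded constraint map (bounded LRU),
keyed additionally by candidate size only when a modification-count
objective is present.

## Evolutionary engine

Candidates are variable-length sets of (target, level) pairs. Mutation
applies at most one of add/remove/change-target/change-level with
probabilities (0.3, 0.3, 0.2, 0.2) renormalized over the applicable moves;
crossover is uniform over the set union with shared modifications copied to
both children; defaults are balanced-exploration choices over a set
representation, all config-exposed. GA uses binary tournaments and elitism
of one on the first objective (or a configured weighted sum); SA runs a
Metropolis chain with geometric cooling (budgeted as generations ×
population size steps for comparability); NSGA-II is the standard (μ+λ)
scheme with fast non-dominated sorting and crowding. A single seeded
`random.Random` stream drives everything; no global RNG is touched, so runs
are bit-reproducible.

The archive keeps feasible, mutually non-dominated individuals,
deduplicated by decoded constraints and truncated by crowding distance
beyond its capacity (default 100).

## Fixtures and what they show

`TOY1` is a six-reaction branch-point network in which biomass and product
compete for a common precursor: it has hand-derivable optima for every
simulation method (growth 5, product locked at 0 at the optimum; throttling
the competing branch frees product at a growth cost). `TOYREG` adds a
two-rule repression cascade (signal → TF ⊣ gene) whose knockout-rescue
behaviour is enumerable by hand. `TOY1-ENZ` prices both branches at 0.1
g·h/mmol against a 0.6 g/gDW pool, capping growth at 3. `random_model`
generates seeded parallel-pathway networks (guaranteed viable, ≤ ~10
reactions) for oracle sweeps.

Test oracles are independent of the implementation path: FBA optima are
checked against exhaustive vertex enumeration of the flux polytope and
against a second, structurally different LP encoding built directly on
`scipy.optimize.linprog`; pFBA/lMOMA/FVA use the second encoding only,
since a convex piecewise-linear minimum need not sit on a vertex.

These fixtures exercise every code path at desk scale, but they are not
genome-scale models: they contain no cofactor cycles, no alternate-optima
degeneracy beyond the product branch, no realistic GPR complexity, and LP
conditioning issues that appear at scale are out of reach. Passing tests
demonstrate correctness of the formulations and algorithms, not predictive
accuracy on real organisms.

## Problem sizes in the shipped runs

The acceptance script and tests run NSGA-II at population 20 for 20
generations on candidate spaces of ≤ 112 candidates (exhaustively
enumerated for ground truth), GA/SA at population 16 for 15 generations on
a 10-candidate deletion space, and oracle sweeps over 20 seeded random
models — sizes chosen so the whole suite re-derives every number in
seconds while still covering every method and operator.

## Known limitations

- No quadratic MOMA, no SPEA2/NSGA-III, no bilevel deterministic designs
  (e.g. OptKnock-style MILP), no dynamic/time-course rFBA, no thermodynamic
  or ME/ETFL constraints, no parallel evaluation.
- SBML is read (Level 3 + FBC v2, via cobra) but not written; the JSON
  dialect is the round-trip format.
- The regulatory OU vocabulary covers up/down/delete over regulatory and
  metabolic targets, not transcription-factor activity scoring or TRN
  inference.
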