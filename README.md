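# strainbench

A computational strain-optimization workbench for metabolic engineering.
Given a constraint-based metabolic model, strainbench searches for small
sets of genetic modifications — deletions and over-/under-expression of
reactions, genes, enzymes, or regulatory variables — that maximize the
production of a target metabolite while keeping the organism viable. It is
aimed at researchers designing microbial cell factories who want to combine
phenotype simulation methods and evolutionary search in one place.

## What it computes

The workbench has three layers.

**Phenotype simulation.** All methods operate on the steady-state flux cone
`{v : S v = 0, lb ≤ v ≤ ub}` of a genome-scale or toy model with
stoichiometric matrix `S`:

- **FBA** — maximize the objective (biomass) flux `c·v`.
- **pFBA** — fix the objective at (a fraction of) its optimum, then minimize
  total flux `Σ|v_i|` (split variables `v = v⁺ − v⁻`).
- **FVA** — per-reaction `min`/`max` flux at ≥ a fraction of the optimum.
- **lMOMA** — mutant prediction minimizing the L1 distance `Σ|v_i − w_i|`
  to a wild-type reference `w` (default: wild-type pFBA).
- **ROOM** — MILP minimizing the number of fluxes leaving a tolerance window
  `[w_i − δ|w_i| − ε, w_i + δ|w_i| + ε]` (defaults δ = 0.03, ε = 0.001).
- **rFBA / srFBA** — integration of a Boolean transcriptional-regulatory
  network: iteratively (synchronous steady state, then FBA) or as one MILP
  with linearized Boolean rules coupled to reaction bounds.
- **Protein pool** — an sMOMENT-style enzymatic budget
  `Σ (MW_j / kcat_j) v_j ≤ P_pool` honoured by every method.

Classical quadratic MOMA is only available when a quadratic-capable backend
is configured; the shipped scipy/HiGHS backend covers LP and MILP, and lMOMA
is the linear surrogate.

**Problem definition.** A problem fixes the target space (reactions, genes,
enzymes, regulatory variables), the strategy (KO or OU over a discrete level
grid, default powers of two from 1/32 to 32), the environment (growth medium
as bound overrides), and 1–4 objectives. Gene modifications propagate
through GPR rules: Boolean for deletions, and with the (AND, OR) operators
replaced by (min, max) — overridable — for expression levels. Objective
functions:

- **BPCY** — biomass-product coupled yield `v_bio · v_prod` (divided by
  `|v_sub|` when a substrate is configured), evaluated with a configurable
  phenotype method;
- **WYIELD** — `α·v_max + (1−α)·v_min` of the product flux (FVA at the
  mutant's predicted growth), plus target-flux, growth, and
  modification-count objectives.

**Optimization.** Single-objective GA and SA, and multi-objective NSGA-II,
evolve candidate modification sets and return an archive of non-dominated
solutions. Runs are bit-reproducible from the seed.

## GPR grammar

```
expr    = term , { ("or" | "|") , term } ;
term    = factor , { ("and" | "&") , factor } ;
factor  = [ "not" | "!" ] , atom ;          (* regulatory rules only *)
atom    = identifier | "true" | "false" | "(" , expr , ")" ;
```

Operators are case-insensitive; `and` binds tighter than `or`. Regulatory
rule files contain one `target = <expr>` per line; environment signals are
prefixed `env_`.

## Worked example

`examples/minimal_workflow.py` runs the four-step workflow — load a model,
choose objectives, instantiate the problem, run — on the bundled TOY1
branch-point model (substrate A splits into branches A→B and A→C; biomass
consumes B + C; B can instead be exported as product P):

```python
model = load_model("examples/TOY1.json")
f1 = BPCY(biomass_id, product_id, method="lMOMA")
f2 = WYIELD(biomass_id, product_id)
problem = GOUProblem(model, [f1, f2])
ea = EA(problem)
archive = ea.run()
```

Output (abridged):

```
non-dominated solutions: 15
  g1:2;g2:0.25              BPCY=  0.0000  WYIELD= 10.0000
  g2:0.0625                 BPCY=  1.4648  WYIELD=  4.6875
  g2:0.25;g3:16             BPCY=  4.6875  WYIELD=  3.7500
  g2:0.5;g3:16              BPCY=  6.2500  WYIELD=  2.5000
```

Each row is one strategy (`target:level`; level 1 = wild type, < 1
under-expression, > 1 over-expression). Throttling the competing branch gene
`g2` frees the B precursor for product export: the further it is
under-expressed the higher the guaranteed yield (WYIELD) but the lower the
growth-coupled yield (BPCY), and the archive exposes that trade-off. Forcing
flux through `g1`'s branch (`g1:2`) maximizes product at zero growth.

The same runs from the shell:

```bash
strainbench export-fixture --output-dir out   # TOY1 + example config
strainbench optimize  --config out/config.yaml
strainbench enumerate --config out/config.yaml   # exact front, brute force
strainbench simulate  --config out/config.yaml --method FBA
```

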