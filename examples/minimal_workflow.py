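"""Minimal four-step strain-design workflow on the TOY1 branch-point model.

(i) load a model, (ii) choose the optimization objectives, (iii) instantiate
the problem, (iv) run the optimization — here maximizing the biomass-product
coupled yield (evaluated with lMOMA) together with the weighted product
yield, over gene over-/under-expression candidates.
"""

from pathlib import Path

from strainbench import BPCY, EA, GOUProblem, WYIELD, load_model

biomass_id = "R_biomass"
product_id = "EX_P"

# (i) load a model
model = load_model(Path(__file__).parent / "TOY1.json")

# (ii) choose the optimization objectives
f1 = BPCY(biomass_id, product_id, method="lMOMA")
f2 = WYIELD(biomass_id, product_id)

# (iii) instantiate the problem
problem = GOUProblem(model, [f1, f2])

# (iv) run the optimization
ea = EA(problem)
archive = ea.run()

print(f"non-dominated solutions: {len(archive)}")
for ind in archive.members():
    b, w = ind.fitness.values
    print(f"  {ind.candidate.label():24s}  BPCY={b:8.4f}  WYIELD={w:8.4f}")
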