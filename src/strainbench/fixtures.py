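"""Deterministic toy models and scenarios used by every test and example.

No downloads, no external data: each generator builds its objects in memory
and can export them to the package's plain-text formats.

``TOY1`` is a four-metabolite branch-point network: substrate A is taken up
(capacity 10) and split between two branches, A->B (gene g1) and A->C (gene
g2); biomass consumes B and C one-to-one, while B can instead be diverted to
the product P (catalysed by g3, or by the g1/g4 complex). Growth and product
formation therefore compete for B: wild-type FBA growth is 5 with zero
product, and throttling the g2 branch frees B for product export. Every
documented optimum is hand-derivable by enumerating the vertices of the
six-reaction flux cone.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Optional

from .enzymes import EnzymeParams
from .gpr import parse_gpr
from .model import MetabolicModel, Metabolite, Reaction
from .regulatory import RegulatoryNetwork, RegulatoryRule
from .gpr import parse_bool_expr

__all__ = ["ToyScenario", "toy_model", "toy_regulatory", "toy_enzymatic", "random_model"]


@dataclass
class ToyScenario:
    model: MetabolicModel
    network: Optional[RegulatoryNetwork] = None
    enzymes: Optional[EnzymeParams] = None
    #: scenario tag -> (expected value, derivation note); each entry is
    #: re-verified in the test suite by an independent oracle.
    documented_optima: dict = field(default_factory=dict)


def toy_model() -> MetabolicModel:
    """TOY1 — the branch-point toy network (6 reactions, 4 genes)."""
    metabolites = [Metabolite(x) for x in ("A", "B", "C", "P")]
    reactions = [
        Reaction("R_up", {"A": 1.0}, 0.0, 10.0),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 10.0, parse_gpr("g1")),
        Reaction("R2", {"A": -1.0, "C": 1.0}, 0.0, 10.0, parse_gpr("g2")),
        Reaction("R3", {"B": -1.0, "P": 1.0}, 0.0, 10.0, parse_gpr("g3 or (g1 and g4)")),
        Reaction("R_biomass", {"B": -1.0, "C": -1.0}, 0.0, 10.0),
        Reaction("EX_P", {"P": -1.0}, 0.0, 10.0),
    ]
    return MetabolicModel(
        metabolites, reactions, {"g1", "g2", "g3", "g4"}, "R_biomass"
    )


def toy_regulatory() -> RegulatoryNetwork:
    """TOYREG — TF t1 is induced by signal env_s1 and represses gene g2."""
    return RegulatoryNetwork(
        [
            RegulatoryRule("t1", parse_bool_expr("env_s1")),
            RegulatoryRule("g2", parse_bool_expr("not t1")),
        ]
    )


def toy_enzymatic() -> EnzymeParams:
    """TOY1-ENZ — unit-MW enzymes with kcat 10 on both branches (specific
    cost 0.1 g·h/mmol each) and a pool of 0.6 g/gDW, capping R1 + R2 at 6."""
    return EnzymeParams(entries={"R1": (10.0, 1.0), "R2": (10.0, 1.0)}, pool=0.6)


def toy_scenario() -> ToyScenario:
    """TOY1 with its regulatory and enzymatic layers and the hand-derived
    optima the acceptance suite re-verifies."""
    return ToyScenario(
        model=toy_model(),
        network=toy_regulatory(),
        enzymes=toy_enzymatic(),
        documented_optima={
            "fba_growth": (5.0, "10 units of A split 5/5 into B and C; biomass = min(B, C)"),
            "growth_without_g1": (0.0, "R1 off leaves no B for biomass"),
            "growth_g2_half": (2.5, "R2 capped at 0.5*5; biomass = C = 2.5"),
            "product_max_g2_half": (5.0, "B surplus 10 - 2*2.5 routed through R3"),
            "rfba_growth_s1_on": (0.0, "t1 on represses g2; no C"),
            "rfba_growth_s1_off": (5.0, "all genes on; wild type"),
            "enzyme_pool_growth": (3.0, "0.1*(R1+R2) <= 0.6 caps R1+R2 at 6, split 3/3"),
        },
    )


def random_model(n_linear_pathways: int, seed: int) -> MetabolicModel:
    """A random branched substrate->biomass network of parallel two-step
    linear pathways with one-gene GPRs, plus a product branch.

    Substrate S enters with a random uptake capacity; each pathway i runs
    S -> M_i -> B with random step capacities (gene ``g_i``); biomass drains
    B (the objective); a product branch S -> P -> (gene ``g_prod``) competes
    for substrate. Construction guarantees a feasible, growing wild type.
    With one pathway the FBA optimum is the minimum capacity along the chain.
    """
    if not 1 <= n_linear_pathways <= 20:
        raise ValueError("n_linear_pathways must lie in [1, 20]")
    rng = _random.Random(seed)
    metabolites = [Metabolite("S"), Metabolite("B_pre"), Metabolite("P")]
    uptake = round(rng.uniform(4.0, 12.0), 2)
    reactions = [Reaction("R_up", {"S": 1.0}, 0.0, uptake)]
    genes: set[str] = set()
    for i in range(1, n_linear_pathways + 1):
        mid = f"M{i}"
        metabolites.append(Metabolite(mid))
        cap1 = round(rng.uniform(1.0, 8.0), 2)
        cap2 = round(rng.uniform(1.0, 8.0), 2)
        gene = f"g{i}"
        genes.add(gene)
        reactions.append(
            Reaction(f"P{i}a", {"S": -1.0, mid: 1.0}, 0.0, cap1, parse_gpr(gene))
        )
        reactions.append(
            Reaction(f"P{i}b", {mid: -1.0, "B_pre": 1.0}, 0.0, cap2, parse_gpr(gene))
        )
    genes.add("g_prod")
    reactions.append(
        Reaction("R_prod", {"S": -1.0, "P": 1.0}, 0.0,
                 round(rng.uniform(1.0, 6.0), 2), parse_gpr("g_prod"))
    )
    reactions.append(Reaction("EX_P", {"P": -1.0}, 0.0, 10.0))
    reactions.append(Reaction("R_biomass", {"B_pre": -1.0}, 0.0, 100.0))
    return MetabolicModel(metabolites, reactions, genes, "R_biomass")
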