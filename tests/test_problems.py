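"""Problem definitions, candidate decoding, and the BPCY/WYIELD objectives."""

import math

import pytest

from strainbench.errors import ConfigurationError, DecodeError
from strainbench.model import EnvironmentalConditions, FluxDistribution
from strainbench.problems import (
    BPCY,
    WYIELD,
    Candidate,
    GKOProblem,
    GOUProblem,
    ObjectiveSpec,
    OptORFProblem,
    Problem,
    ROUProblem,
    bpcy,
    decode,
    enumerate_candidates,
    evaluate,
    wild_type_reference,
    wyield,
)
from strainbench.simulation import SimulationResult, fba

APPROX = dict(abs=1e-6)


@pytest.fixture
def gou_problem(toy1):
    return GOUProblem(
        toy1,
        [BPCY("R_biomass", "EX_P", method="pFBA"), WYIELD("R_biomass", "EX_P")],
        level_grid=[0, 0.25, 0.5, 2],
        max_modifications=2,
    )


class TestWildTypeReference:
    def test_unique_parsimonious_fluxes(self, gou_problem):
        ref = wild_type_reference(gou_problem)
        expected = {"R_up": 10, "R1": 5, "R2": 5, "R3": 0, "R_biomass": 5, "EX_P": 0}
        for rid, w in expected.items():
            assert ref[rid] == pytest.approx(w, **APPROX)

    def test_cached_object_is_reused(self, gou_problem):
        assert wild_type_reference(gou_problem) is wild_type_reference(gou_problem)

    def test_zero_growth_wild_type_rejected(self, toy1):
        problem = GKOProblem(
            toy1, [BPCY("R_biomass", "EX_P")],
            env=EnvironmentalConditions({"R_up": (0.0, 0.0)}),
        )
        with pytest.raises(ConfigurationError):
            wild_type_reference(problem)


class TestDecode:
    def test_single_gene_knockout(self, toy1):
        problem = GKOProblem(toy1, [BPCY("R_biomass", "EX_P")])
        assert decode(problem, Candidate.of(("g1", 0.0))) == {"R1": (0.0, 0.0)}

    def test_isozyme_backup_keeps_reaction_open(self, toy1):
        problem = GKOProblem(toy1, [BPCY("R_biomass", "EX_P")])
        # R3 is catalysed by g3 OR (g1 AND g4): deleting g4 changes nothing
        assert decode(problem, Candidate.of(("g4", 0.0))) == {}

    def test_gene_under_expression(self, gou_problem):
        assert decode(gou_problem, Candidate.of(("g2", 0.5))) == {"R2": (0.0, 2.5)}

    def test_optorf_tf_deletion_restores_gene(self, toy1, toyreg):
        problem = OptORFProblem(
            toy1, [BPCY("R_biomass", "EX_P")], toyreg, signals={"env_s1": True}
        )
        assert decode(problem, Candidate.of(("t1", 0.0))) == {}

    def test_regulatory_gene_off_downstream(self, toy1, toyreg):
        problem = OptORFProblem(
            toy1, [BPCY("R_biomass", "EX_P")], toyreg, signals={"env_s1": False}
        )
        # deleting metabolic gene g2 directly closes R2
        assert decode(problem, Candidate.of(("g2", 0.0))) == {"R2": (0.0, 0.0)}

    def test_unknown_target_rejected(self, gou_problem):
        with pytest.raises(DecodeError):
            decode(gou_problem, Candidate.of(("g99", 0.0)))

    def test_too_many_modifications_rejected(self, gou_problem):
        cand = Candidate.of(("g1", 0.0), ("g2", 0.0), ("g3", 0.0))
        with pytest.raises(DecodeError):
            decode(gou_problem, cand)

    def test_decode_is_deterministic_and_hashable(self, gou_problem):
        cand = Candidate.of(("g2", 0.5), ("g3", 0.0))
        first = decode(gou_problem, cand)
        second = decode(gou_problem, cand)
        assert first == second
        assert hash(tuple(sorted(first.items()))) == hash(tuple(sorted(second.items())))


class TestObjectives:
    def test_bpcy_with_substrate_normalization(self):
        result = SimulationResult(
            "optimal", 2.5,
            FluxDistribution({"bio": 2.5, "prod": 5.0, "sub": -10.0}), "FBA",
        )
        assert bpcy(result, "bio", "prod", "sub") == pytest.approx(1.25)

    def test_bpcy_zero_product(self):
        result = SimulationResult(
            "optimal", 2.5, FluxDistribution({"bio": 2.5, "prod": 0.0}), "FBA"
        )
        assert bpcy(result, "bio", "prod") == 0.0

    def test_bpcy_without_substrate(self):
        result = SimulationResult(
            "optimal", 2.5, FluxDistribution({"bio": 2.5, "prod": 5.0}), "FBA"
        )
        assert bpcy(result, "bio", "prod") == pytest.approx(12.5)

    def test_bpcy_zero_growth_and_zero_uptake_guards(self):
        dead = SimulationResult(
            "optimal", 0.0, FluxDistribution({"bio": 0.0, "prod": 5.0, "sub": -10.0}), "FBA"
        )
        assert bpcy(dead, "bio", "prod", "sub") == 0.0
        no_uptake = SimulationResult(
            "optimal", 2.5, FluxDistribution({"bio": 2.5, "prod": 5.0, "sub": 0.0}), "FBA"
        )
        assert bpcy(no_uptake, "bio", "prod", "sub") == 0.0

    def test_wyield_under_expression_scenario(self, toy1, gou_problem):
        view = gou_problem.base_view().with_bounds(
            decode(gou_problem, Candidate.of(("g2", 0.5)))
        )
        value, ok = wyield(view, "R_biomass", "EX_P", alpha=0.5)
        assert ok
        assert value == pytest.approx(2.5, **APPROX)

    def test_wyield_alpha_zero_is_pessimistic(self, toy1, gou_problem):
        view = gou_problem.base_view().with_bounds(
            decode(gou_problem, Candidate.of(("g2", 0.5)))
        )
        value, _ = wyield(view, "R_biomass", "EX_P", alpha=0.0)
        assert value == pytest.approx(0.0, **APPROX)

    def test_wyield_wild_type_is_degenerate(self, toy1):
        value, ok = wyield(toy1, "R_biomass", "EX_P", alpha=0.5)
        assert ok and value == pytest.approx(0.0, **APPROX)


class TestEvaluate:
    def test_under_expression_trade_off(self, gou_problem):
        fitness = evaluate(gou_problem, Candidate.of(("g2", 0.5)))
        assert fitness.feasible
        assert fitness.values[0] == pytest.approx(0.0, **APPROX)  # pFBA kills product
        assert fitness.values[1] == pytest.approx(2.5, **APPROX)

    def test_essential_deletion_is_feasible_but_worthless(self, gou_problem):
        fitness = evaluate(gou_problem, Candidate.of(("g1", 0.0)))
        assert fitness.feasible
        assert fitness.values[0] == pytest.approx(0.0, **APPROX)

    def test_redundant_ko_targets_do_not_change_fitness(self, toy1):
        problem = GKOProblem(
            toy1, [BPCY("R_biomass", "EX_P"), WYIELD("R_biomass", "EX_P")]
        )
        lone = evaluate(problem, Candidate.of(("g2", 0.0)))
        padded = evaluate(problem, Candidate.of(("g2", 0.0), ("g4", 0.0)))
        assert lone == padded  # g4's deletion disables no additional reaction

    def test_gene_and_reaction_routes_agree(self, toy1):
        objectives = [BPCY("R_biomass", "EX_P"), WYIELD("R_biomass", "EX_P")]
        gko = GKOProblem(toy1, objectives)
        rko = Problem(toy1, objectives, target_space="reactions", strategy="KO")
        gene_fit = evaluate(gko, Candidate.of(("g2", 0.0)))
        reaction_fit = evaluate(rko, Candidate.of(("R2", 0.0)))
        assert gene_fit.values == pytest.approx(reaction_fit.values, **APPROX)

    def test_enzyme_problem_route(self, toy1, toy_enz):
        problem = Problem(
            toy1, [ObjectiveSpec(kind="growth", method="FBA")],
            target_space="enzymes", strategy="OU", enzymes=toy_enz,
            level_grid=[0, 0.5, 2],
        )
        half = evaluate(problem, Candidate.of(("R2", 0.5)))
        assert half.values[0] == pytest.approx(1.5, **APPROX)
        dead = evaluate(problem, Candidate.of(("R1", 0.0)))
        assert dead.values[0] == pytest.approx(0.0, **APPROX)


class TestEnumeration:
    def test_gko_space_size(self, toy1):
        problem = GKOProblem(
            toy1, [BPCY("R_biomass", "EX_P")], max_modifications=2
        )
        # 4 singles + C(4,2) pairs
        assert sum(1 for _ in enumerate_candidates(problem)) == 10

    def test_ou_space_size(self, gou_problem):
        count = sum(1 for _ in enumerate_candidates(gou_problem))
        assert count == 4 * 4 + 6 * 16  # singles + pairs with 4 levels each


class TestProblemValidation:
    def test_objective_count_bounds(self, toy1):
        with pytest.raises(ConfigurationError):
            Problem(toy1, [])
        five = [BPCY("R_biomass", "EX_P")] * 5
        with pytest.raises(ConfigurationError):
            Problem(toy1, five)

    def test_ko_strategy_forces_zero_grid(self, toy1):
        problem = GKOProblem(toy1, [BPCY("R_biomass", "EX_P")])
        assert problem.level_grid == (0.0,)

    def test_default_gene_targets_only_cover_gpr_genes(self, toy1):
        problem = GKOProblem(toy1, [BPCY("R_biomass", "EX_P")])
        assert set(problem.targets) == {"g1", "g2", "g3", "g4"}

    def test_default_reaction_targets_exclude_exchanges_and_biomass(self, toy1):
        problem = Problem(
            toy1, [BPCY("R_biomass", "EX_P")], target_space="reactions"
        )
        assert set(problem.targets) == {"R1", "R2", "R3"}

    def test_non_targets_are_subtracted(self, toy1):
        problem = GKOProblem(
            toy1, [BPCY("R_biomass", "EX_P")], non_targets={"g1"}
        )
        assert "g1" not in problem.targets
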