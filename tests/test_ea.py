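"""Evolutionary engine: operators, dominance, sorting, archives, runs."""

import itertools
import random

import pytest

from strainbench.ea import (
    EAConfig,
    Individual,
    SolutionArchive,
    brute_force_front,
    crossover,
    dominates,
    mutate,
    nondominated_sort_and_crowding,
    run,
)
from strainbench.errors import ConfigurationError
from strainbench.problems import (
    BPCY,
    WYIELD,
    Candidate,
    Fitness,
    GKOProblem,
    GOUProblem,
    ObjectiveSpec,
)


@pytest.fixture
def gou_problem(toy1):
    return GOUProblem(
        toy1,
        [WYIELD("R_biomass", "EX_P"), ObjectiveSpec(kind="growth", method="FBA")],
        level_grid=[0, 0.25, 0.5, 2],
        max_modifications=2,
    )


@pytest.fixture
def wyield_ko_problem(toy1):
    return GKOProblem(toy1, [WYIELD("R_biomass", "EX_P")], max_modifications=2)


RATES = (0.3, 0.3, 0.2, 0.2)


class TestMutate:
    def test_never_exceeds_max_modifications(self, gou_problem):
        rng = random.Random(0)
        cand = Candidate.of(("g1", 0.5), ("g2", 0.5))
        for _ in range(200):
            cand = mutate(cand, gou_problem, RATES, rng)
            assert 1 <= len(cand) <= gou_problem.max_modifications
            targets = [t for t, _ in cand.modifications]
            assert len(targets) == len(set(targets))

    def test_single_modification_never_removed(self, gou_problem):
        rng = random.Random(1)
        for _ in range(100):
            out = mutate(Candidate.of(("g1", 0.5)), gou_problem, RATES, rng)
            assert len(out) >= 1

    def test_fixed_seed_reproduces_sequence(self, gou_problem):
        def sequence(seed):
            rng = random.Random(seed)
            cand = Candidate.of(("g1", 0.5))
            return [
                (cand := mutate(cand, gou_problem, RATES, rng)).sorted_mods()
                for _ in range(30)
            ]

        assert sequence(7) == sequence(7)

    def test_ko_problem_never_changes_levels(self, wyield_ko_problem):
        rng = random.Random(2)
        cand = Candidate.of(("g1", 0.0))
        for _ in range(100):
            cand = mutate(cand, wyield_ko_problem, RATES, rng)
            assert all(level == 0.0 for _, level in cand.modifications)


class TestCrossover:
    def test_identical_parents_breed_true(self, gou_problem):
        rng = random.Random(3)
        parent = Candidate.of(("g1", 0.5), ("g2", 2.0))
        a, b = crossover(parent, parent, gou_problem, rng)
        assert a == parent and b == parent

    def test_disjoint_singletons_partition_or_share(self, gou_problem):
        rng = random.Random(4)
        pa, pb = Candidate.of(("g1", 0.5)), Candidate.of(("g2", 2.0))
        union = pa.modifications | pb.modifications
        for _ in range(50):
            a, b = crossover(pa, pb, gou_problem, rng)
            for child in (a, b):
                assert 1 <= len(child) <= 2
                assert child.modifications <= union

    def test_children_respect_max_modifications(self, toy1):
        problem = GOUProblem(
            toy1, [WYIELD("R_biomass", "EX_P")], level_grid=[0, 0.5], max_modifications=2
        )
        rng = random.Random(5)
        pa = Candidate.of(("g1", 0.5), ("g2", 0.5))
        pb = Candidate.of(("g3", 0.5), ("g4", 0.5))
        for _ in range(50):
            for child in crossover(pa, pb, problem, rng):
                assert 1 <= len(child) <= 2

    def test_fixed_seed_is_deterministic(self, gou_problem):
        pa = Candidate.of(("g1", 0.5), ("g3", 0.0))
        pb = Candidate.of(("g2", 2.0))
        first = crossover(pa, pb, gou_problem, random.Random(9))
        second = crossover(pa, pb, gou_problem, random.Random(9))
        assert first == second


class TestDominance:
    MAX2 = [True, True]

    def test_strict_dominance(self):
        assert dominates(Fitness((2, 2)), Fitness((1, 2)), self.MAX2)

    def test_incomparable_points(self):
        assert not dominates(Fitness((2, 1)), Fitness((1, 2)), self.MAX2)
        assert not dominates(Fitness((1, 2)), Fitness((2, 1)), self.MAX2)

    def test_feasible_beats_infeasible(self):
        bad = Fitness((float("-inf"), float("-inf")), feasible=False)
        assert dominates(Fitness((0, 0)), bad, self.MAX2)
        assert not dominates(bad, Fitness((0, 0)), self.MAX2)

    def test_direction_aware(self):
        assert dominates(Fitness((1, 1)), Fitness((1, 2)), [True, False])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dominates(Fitness((1,)), Fitness((1, 2)), self.MAX2)


def _population(fitnesses):
    return [Individual(Candidate.of((f"t{i}", 0.0)), Fitness(tuple(f)))
            for i, f in enumerate(fitnesses)]


class TestSorting:
    def test_worked_front_assignment(self):
        pop = _population([(1, 4), (4, 1), (2, 2), (1, 1)])
        nondominated_sort_and_crowding(pop, [True, True])
        assert [ind.rank for ind in pop] == [0, 0, 0, 1]

    def test_identical_fitnesses_form_one_front(self):
        pop = _population([(1, 1)] * 4)
        fronts = nondominated_sort_and_crowding(pop, [True, True])
        assert len(fronts) == 1
        crowds = sorted(ind.crowding for ind in pop)
        assert crowds[-1] == float("inf")

    def test_single_individual(self):
        pop = _population([(3, 3)])
        nondominated_sort_and_crowding(pop, [True, True])
        assert pop[0].rank == 0 and pop[0].crowding == float("inf")

    def test_agrees_with_brute_force_on_random_populations(self):
        rng = random.Random(123)
        for trial in range(100):
            m = rng.choice([2, 3])
            n = rng.randint(2, 50)
            directions = [rng.random() < 0.5 for _ in range(m)]
            pop = _population(
                [tuple(rng.randint(0, 5) for _ in range(m)) for _ in range(n)]
            )
            nondominated_sort_and_crowding(pop, directions)
            # brute force: rank 0 iff no other individual dominates it
            for ind in pop:
                dominated = any(
                    dominates(other.fitness, ind.fitness, directions)
                    for other in pop
                    if other is not ind
                )
                assert (ind.rank == 0) == (not dominated)


class TestArchive:
    def test_members_are_mutually_nondominated(self):
        rng = random.Random(5)
        archive = SolutionArchive([True, True], capacity=50)
        for i in range(200):
            fitness = Fitness((rng.randint(0, 8), rng.randint(0, 8)))
            ind = Individual(Candidate.of((f"t{i}", 0.0)), fitness)
            archive.update([ind], [i])
        members = archive.members()
        for a, b in itertools.permutations(members, 2):
            assert not dominates(a.fitness, b.fitness, [True, True])

    def test_infeasible_never_enters(self):
        archive = SolutionArchive([True], capacity=10)
        bad = Individual(Candidate.of(("t", 0.0)), Fitness((float("-inf"),), feasible=False))
        archive.update([bad], ["k"])
        assert len(archive) == 0

    def test_deduplication_by_key(self):
        archive = SolutionArchive([True], capacity=10)
        ind = Individual(Candidate.of(("t", 0.0)), Fitness((1.0,)))
        archive.update([ind, ind], ["same", "same"])
        assert len(archive) == 1


class TestRuns:
    def test_nsga2_reaches_enumerated_front(self, gou_problem):
        config = EAConfig(seed=11, algorithm="NSGAII", population_size=20, generations=20)
        archive = run(gou_problem, config)
        truth = brute_force_front(gou_problem)
        assert archive.fitness_set() == truth.fitness_set()

    def test_ga_finds_single_objective_optimum(self, wyield_ko_problem):
        config = EAConfig(seed=3, algorithm="GA", population_size=16, generations=15)
        archive = run(wyield_ko_problem, config)
        truth = brute_force_front(wyield_ko_problem)
        best_true = max(v[0] for v in truth.fitness_set())
        assert max(v[0] for v in archive.fitness_set()) == pytest.approx(best_true, abs=1e-6)

    def test_sa_finds_single_objective_optimum(self, wyield_ko_problem):
        config = EAConfig(seed=5, algorithm="SA", population_size=16, generations=15)
        archive = run(wyield_ko_problem, config)
        truth = brute_force_front(wyield_ko_problem)
        best_true = max(v[0] for v in truth.fitness_set())
        assert max(v[0] for v in archive.fitness_set()) == pytest.approx(best_true, abs=1e-6)

    def test_sa_at_zero_temperature_is_hill_climbing(self, wyield_ko_problem):
        log: list = []
        config = EAConfig(
            seed=8, algorithm="SA", population_size=8, generations=10,
            sa_schedule=(1e-12, 0.5, 5),
        )
        run(wyield_ko_problem, config, generation_log=log)
        bests = [row[1] for row in log]
        assert bests == sorted(bests)

    def test_zero_generations_returns_initial_archive(self, wyield_ko_problem):
        config = EAConfig(seed=2, algorithm="NSGAII", population_size=8, generations=0)
        archive = run(wyield_ko_problem, config)
        assert len(archive) >= 1

    def test_constant_objective_does_not_crash(self, toy1):
        problem = GKOProblem(
            toy1, [ObjectiveSpec(kind="modification_count", direction="min")],
            max_modifications=2,
        )
        config = EAConfig(seed=4, algorithm="NSGAII", population_size=8, generations=3)
        archive = run(problem, config)
        assert len(archive) >= 1

    def test_same_seed_reproduces_archive_exactly(self, gou_problem):
        config = EAConfig(seed=21, algorithm="NSGAII", population_size=12, generations=8)
        a = run(gou_problem, config)
        b = run(gou_problem, config)
        assert [(i.candidate.sorted_mods(), i.fitness) for i in a.members()] == [
            (i.candidate.sorted_mods(), i.fitness) for i in b.members()
        ]

    def test_archive_nondominated_after_every_generation(self, gou_problem):
        checked = []

        def check(gen, population, archive):
            members = archive.members()
            for a, b in itertools.permutations(members, 2):
                assert not dominates(a.fitness, b.fitness, archive.directions)
            checked.append(gen)

        config = EAConfig(seed=13, algorithm="NSGAII", population_size=10, generations=6)
        run(gou_problem, config, on_generation=check)
        assert len(checked) == 7  # initial population + 6 generations

    def test_unsupported_algorithm_named(self):
        with pytest.raises(ConfigurationError, match="SPEA2.*NSGAII|not implemented"):
            EAConfig(seed=1, algorithm="SPEA2")
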