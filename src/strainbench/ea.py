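"""Evolutionary optimization over candidate modification sets.

Three algorithms share one variable-length set representation (a
:class:`~strainbench.problems.Candidate` is a set of (target, level) pairs):

* **GA** — single-objective genetic algorithm: binary tournament selection,
  uniform set crossover, one-move mutation, elitism of one.
* **SA** — simulated annealing: a single-candidate chain with Metropolis
  acceptance exp(delta/T) and geometric cooling.
* **NSGA-II** — (mu + lambda) multi-objective search with fast non-dominated
  sorting and crowding-distance selection.

Every algorithm maintains a :class:`SolutionArchive` of mutually
non-dominated candidates (deduplicated by decoded constraints) and returns
it. All randomness flows from a single ``random.Random`` stream seeded from
the configuration — runs with the same seed are bit-reproducible.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .errors import ConfigurationError
from .problems import Candidate, Fitness, Problem, decode, evaluate

__all__ = [
    "EAConfig",
    "Individual",
    "SolutionArchive",
    "mutate",
    "crossover",
    "dominates",
    "nondominated_sort_and_crowding",
    "run",
    "brute_force_front",
    "EA",
]

_ALGORITHMS = ("GA", "SA", "NSGAII")


@dataclass
class EAConfig:
    seed: int
    algorithm: str = "NSGAII"
    population_size: int = 20
    generations: int = 20
    #: probabilities for (add, remove, change-target, change-level) moves,
    #: renormalized over the moves applicable to each candidate.
    mutation_rates: tuple[float, float, float, float] = (0.3, 0.3, 0.2, 0.2)
    crossover_rate: float = 0.9
    #: (T0, geometric cooling factor, steps per temperature) for SA.
    sa_schedule: tuple[float, float, int] = (1.0, 0.9, 10)
    archive_size: int = 100
    #: optional weights for a scalarized GA/SA objective; None = first objective.
    weights: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if self.algorithm not in _ALGORITHMS:
            raise ConfigurationError(
                f"algorithm '{self.algorithm}' is not implemented; "
                f"supported: {', '.join(_ALGORITHMS)}"
            )
        for p in self.mutation_rates:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("mutation rates must lie in [0, 1]")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ConfigurationError("crossover rate must lie in [0, 1]")
        if self.algorithm == "NSGAII" and self.population_size < 4:
            raise ConfigurationError("NSGA-II needs a population of at least 4")
        if self.generations < 0:
            raise ConfigurationError("generations must be >= 0")


@dataclass
class Individual:
    candidate: Candidate
    fitness: Optional[Fitness] = None
    rank: Optional[int] = None
    crowding: Optional[float] = None


# ---------------------------------------------------------------------------
# Dominance and sorting
# ---------------------------------------------------------------------------

def dominates(f1: Fitness, f2: Fitness, directions: Sequence[bool]) -> bool:
    """Pareto dominance respecting per-objective direction (True = maximize).
    A feasible fitness always dominates an infeasible one."""
    if len(f1.values) != len(f2.values) or len(f1.values) != len(directions):
        raise ValueError("fitness/direction length mismatch")
    if f1.feasible and not f2.feasible:
        return True
    if not f1.feasible:
        return False
    better_somewhere = False
    for a, b, maximize in zip(f1.values, f2.values, directions):
        if not maximize:
            a, b = -a, -b
        if a < b:
            return False
        if a > b:
            better_somewhere = True
    return better_somewhere


def nondominated_sort_and_crowding(
    population: list[Individual], directions: Sequence[bool]
) -> list[list[Individual]]:
    """Fast non-dominated sorting plus per-front crowding distances.

    Assigns ``rank`` (0 = non-dominated) and ``crowding`` (boundary
    individuals +inf) in place and returns the list of fronts; the induced
    total order is (rank ascending, crowding descending).
    """
    n = len(population)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    counts = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(population[i].fitness, population[j].fitness, directions):
                dominated_by[i].append(j)
                counts[j] += 1
            elif dominates(population[j].fitness, population[i].fitness, directions):
                dominated_by[j].append(i)
                counts[i] += 1
    fronts: list[list[int]] = []
    current = [i for i in range(n) if counts[i] == 0]
    rank = 0
    while current:
        for i in current:
            population[i].rank = rank
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        fronts.append(current)
        current = sorted(nxt)
        rank += 1
    result: list[list[Individual]] = []
    for front_idx in fronts:
        front = [population[i] for i in front_idx]
        _crowding_distance(front, directions)
        result.append(front)
    return result


def _crowding_distance(front: list[Individual], directions: Sequence[bool]) -> None:
    for ind in front:
        ind.crowding = 0.0
    m = len(directions)
    if len(front) <= 2:
        for ind in front:
            ind.crowding = math.inf
        return
    for k in range(m):
        front.sort(key=lambda ind: ind.fitness.values[k])
        front[0].crowding = math.inf
        front[-1].crowding = math.inf
        span = front[-1].fitness.values[k] - front[0].fitness.values[k]
        if span <= 0 or not math.isfinite(span):
            continue
        for i in range(1, len(front) - 1):
            if math.isfinite(front[i].crowding):
                front[i].crowding += (
                    front[i + 1].fitness.values[k] - front[i - 1].fitness.values[k]
                ) / span


def _order_key(ind: Individual) -> tuple:
    crowd = ind.crowding if ind.crowding is not None else 0.0
    return (ind.rank, -crowd)


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _random_modification(problem: Problem, rng: random.Random, exclude=frozenset()):
    available = [t for t in problem.targets if t not in exclude]
    if not available:
        return None
    target = rng.choice(available)
    level = rng.choice(problem.level_grid)
    return (target, level)


def random_candidate(problem: Problem, rng: random.Random) -> Candidate:
    """Uniform size on [1, max_modifications], targets without replacement."""
    max_size = min(problem.max_modifications, len(problem.targets))
    size = rng.randint(1, max_size)
    targets = rng.sample(sorted(problem.targets), size)
    return Candidate(
        frozenset((t, rng.choice(problem.level_grid)) for t in targets)
    )


def mutate(
    candidate: Candidate,
    problem: Problem,
    rates: tuple[float, float, float, float],
    rng: random.Random,
) -> Candidate:
    """Apply at most one move — add, remove, change-target, change-level —
    with probabilities renormalized over the applicable moves. The result is
    always valid for the problem (no-op when nothing applies)."""
    mods = list(candidate.sorted_mods())
    targets_used = {t for t, _ in mods}
    unused = [t for t in problem.targets if t not in targets_used]
    applicable: list[tuple[str, float]] = []
    add_p, rem_p, chg_t_p, chg_l_p = rates
    if len(mods) < problem.max_modifications and unused:
        applicable.append(("add", add_p))
    if len(mods) > 1:
        applicable.append(("remove", rem_p))
    if unused:
        applicable.append(("change-target", chg_t_p))
    if problem.strategy == "OU" and len(problem.level_grid) > 1:
        applicable.append(("change-level", chg_l_p))
    total = sum(p for _, p in applicable)
    if not applicable or total <= 0:
        return candidate
    draw = rng.random() * total
    acc = 0.0
    move = applicable[-1][0]
    for name, p in applicable:
        acc += p
        if draw < acc:
            move = name
            break
    if move == "add":
        new = _random_modification(problem, rng, targets_used)
        mods.append(new)
    elif move == "remove":
        mods.pop(rng.randrange(len(mods)))
    elif move == "change-target":
        i = rng.randrange(len(mods))
        _, level = mods[i]
        mods[i] = (rng.choice(unused), level)
    else:  # change-level
        i = rng.randrange(len(mods))
        target, old = mods[i]
        choices = [g for g in problem.level_grid if g != old] or list(problem.level_grid)
        mods[i] = (target, rng.choice(choices))
    return Candidate(frozenset(mods))


def crossover(
    parent_a: Candidate,
    parent_b: Candidate,
    problem: Problem,
    rng: random.Random,
) -> tuple[Candidate, Candidate]:
    """Uniform set crossover: each modification of the parents' union goes to
    child A or B with probability 1/2; duplicate targets within a child keep
    one level at random; children are truncated uniformly at random to
    max_modifications and padded to size >= 1 from the union."""
    shared = parent_a.modifications & parent_b.modifications
    union = sorted(parent_a.modifications | parent_b.modifications)
    sides: tuple[list, list] = ([], [])
    for mod in union:
        if mod in shared:
            sides[0].append(mod)
            sides[1].append(mod)
        else:
            sides[0 if rng.random() < 0.5 else 1].append(mod)

    def finish(side: list) -> Candidate:
        by_target: dict[str, list[float]] = {}
        for t, g in side:
            by_target.setdefault(t, []).append(g)
        mods = [
            (t, levels[0] if len(levels) == 1 else rng.choice(levels))
            for t, levels in sorted(by_target.items())
        ]
        while len(mods) > problem.max_modifications:
            mods.pop(rng.randrange(len(mods)))
        if not mods:
            mods.append(union[rng.randrange(len(union))])
        return Candidate(frozenset(mods))

    return finish(sides[0]), finish(sides[1])


# ---------------------------------------------------------------------------
# Archive
# ---------------------------------------------------------------------------

class SolutionArchive:
    """Bounded set of mutually non-dominated, evaluated individuals,
    deduplicated by decoded constraints (crowding-based truncation)."""

    def __init__(self, directions: Sequence[bool], capacity: int = 100):
        self.directions = list(directions)
        self.capacity = capacity
        self._items: dict = {}

    def update(self, individuals, keys) -> None:
        for ind, key in zip(individuals, keys):
            if ind.fitness is None or not ind.fitness.feasible:
                continue
            if key in self._items:
                continue
            if any(
                dominates(other.fitness, ind.fitness, self.directions)
                for other in self._items.values()
            ):
                continue
            self._items = {
                k: o
                for k, o in self._items.items()
                if not dominates(ind.fitness, o.fitness, self.directions)
            }
            self._items[key] = Individual(ind.candidate, ind.fitness)
        if len(self._items) > self.capacity:
            self._truncate()

    def _truncate(self) -> None:
        members = self.members()
        _crowding_distance(members, self.directions)
        members.sort(key=lambda ind: (-(ind.crowding or 0.0), ind.candidate.label()))
        keep = {id(ind) for ind in members[: self.capacity]}
        self._items = {
            k: o for k, o in self._items.items() if id(o) in keep
        }

    def members(self) -> list[Individual]:
        return sorted(self._items.values(), key=lambda ind: ind.candidate.label())

    def __len__(self) -> int:
        return len(self._items)

    def fitness_set(self) -> set[tuple[float, ...]]:
        return {ind.fitness.values for ind in self._items.values()}


# ---------------------------------------------------------------------------
# Runners
# ---------------------------------------------------------------------------

def _directions(problem: Problem) -> list[bool]:
    return [o.maximize for o in problem.objectives]


def _decode_key(problem: Problem, candidate: Candidate):
    return tuple(sorted(decode(problem, candidate).items()))


def _evaluated(problem: Problem, candidate: Candidate) -> Individual:
    return Individual(candidate=candidate, fitness=evaluate(problem, candidate))


def _scalar(fitness: Fitness, directions, weights) -> float:
    if not fitness.feasible:
        return -math.inf
    if weights is None:
        v = fitness.values[0]
        return v if directions[0] else -v
    return sum(
        w * (v if maximize else -v)
        for w, v, maximize in zip(weights, fitness.values, directions)
    )


def run(
    problem: Problem,
    config: EAConfig,
    on_generation: Optional[Callable] = None,
    generation_log: Optional[list] = None,
) -> SolutionArchive:
    """Run the configured algorithm and return the solution archive.

    ``on_generation(generation, population, archive)`` is invoked after each
    generation; ``generation_log`` (if given) collects per-generation rows
    (generation, best-per-objective..., mean-per-objective..., archive size).
    """
    rng = random.Random(config.seed)
    directions = _directions(problem)
    archive = SolutionArchive(directions, config.archive_size)
    if config.algorithm == "SA":
        return _run_sa(problem, config, rng, archive, on_generation, generation_log)
    population = [
        _evaluated(problem, random_candidate(problem, rng))
        for _ in range(config.population_size)
    ]
    archive.update(population, [_decode_key(problem, i.candidate) for i in population])
    _log_generation(0, population, archive, directions, generation_log, on_generation)
    for gen in range(1, config.generations + 1):
        if config.algorithm == "NSGAII":
            population = _nsga2_step(problem, config, rng, population, directions)
        else:
            population = _ga_step(problem, config, rng, population, directions)
        archive.update(
            population, [_decode_key(problem, i.candidate) for i in population]
        )
        _log_generation(gen, population, archive, directions, generation_log, on_generation)
    return archive


def _log_generation(gen, population, archive, directions, log, callback):
    if log is not None:
        row = [gen]
        m = len(directions)
        for k in range(m):
            vals = [
                ind.fitness.values[k]
                for ind in population
                if ind.fitness.feasible
            ]
            if vals:
                best = max(vals) if directions[k] else min(vals)
                mean = sum(vals) / len(vals)
            else:
                best = mean = math.nan
            row.extend([best, mean])
        row.append(len(archive))
        log.append(tuple(row))
    if callback is not None:
        callback(gen, population, archive)


def _tournament(population, rng: random.Random) -> Individual:
    a, b = rng.randrange(len(population)), rng.randrange(len(population))
    ia, ib = population[a], population[b]
    return ia if _order_key(ia) <= _order_key(ib) else ib


def _offspring(problem, config, rng, select) -> list[Individual]:
    children: list[Candidate] = []
    while len(children) < config.population_size:
        p1, p2 = select(), select()
        if rng.random() < config.crossover_rate:
            c1, c2 = crossover(p1.candidate, p2.candidate, problem, rng)
        else:
            c1, c2 = p1.candidate, p2.candidate
        children.append(mutate(c1, problem, config.mutation_rates, rng))
        if len(children) < config.population_size:
            children.append(mutate(c2, problem, config.mutation_rates, rng))
    return [_evaluated(problem, c) for c in children]


def _nsga2_step(problem, config, rng, population, directions) -> list[Individual]:
    nondominated_sort_and_crowding(population, directions)
    offspring = _offspring(
        problem, config, rng, lambda: _tournament(population, rng)
    )
    combined = population + offspring
    fronts = nondominated_sort_and_crowding(combined, directions)
    survivors: list[Individual] = []
    for front in fronts:
        if len(survivors) + len(front) <= config.population_size:
            survivors.extend(front)
        else:
            front.sort(key=_order_key)
            survivors.extend(front[: config.population_size - len(survivors)])
            break
    return survivors


def _ga_step(problem, config, rng, population, directions) -> list[Individual]:
    weights = config.weights

    def scalar(ind: Individual) -> float:
        return _scalar(ind.fitness, directions, weights)

    ordered = sorted(population, key=lambda i: (-scalar(i), i.candidate.label()))
    elite = ordered[0]

    def select() -> Individual:
        a = population[rng.randrange(len(population))]
        b = population[rng.randrange(len(population))]
        return a if scalar(a) >= scalar(b) else b

    offspring = _offspring(problem, config, rng, select)
    return [elite] + offspring[: config.population_size - 1]


def _run_sa(problem, config, rng, archive, on_generation, generation_log):
    t0, cooling, steps_per_temp = config.sa_schedule
    directions = _directions(problem)
    weights = config.weights
    current = _evaluated(problem, random_candidate(problem, rng))
    archive.update([current], [_decode_key(problem, current.candidate)])
    temperature = t0
    total_steps = config.generations * config.population_size
    for step in range(total_steps):
        neighbor = _evaluated(
            problem, mutate(current.candidate, problem, config.mutation_rates, rng)
        )
        archive.update([neighbor], [_decode_key(problem, neighbor.candidate)])
        e_cur = _scalar(current.fitness, directions, weights)
        e_new = _scalar(neighbor.fitness, directions, weights)
        if e_new >= e_cur:
            current = neighbor
        elif math.isfinite(e_new) and temperature > 0:
            delta = e_new - e_cur
            if math.isfinite(delta) and rng.random() < math.exp(delta / temperature):
                current = neighbor
        if (step + 1) % max(1, steps_per_temp) == 0:
            temperature *= cooling
        if (step + 1) % config.population_size == 0:
            _log_generation(
                (step + 1) // config.population_size,
                [current], archive, directions, generation_log, on_generation,
            )
    return archive


# ---------------------------------------------------------------------------
# Exhaustive oracle and the minimal workflow wrapper
# ---------------------------------------------------------------------------

def brute_force_front(problem: Problem, limit: int = 100000) -> SolutionArchive:
    """Evaluate every candidate of an enumerable problem and return the true
    non-dominated front (the `enumerate` command's engine)."""
    from .problems import enumerate_candidates

    directions = _directions(problem)
    archive = SolutionArchive(directions, capacity=limit)
    count = 0
    for candidate in enumerate_candidates(problem):
        count += 1
        if count > limit:
            raise ConfigurationError(
                f"candidate space exceeds the enumeration limit ({limit})"
            )
        ind = _evaluated(problem, candidate)
        archive.update([ind], [_decode_key(problem, candidate)])
    return archive


class EA:
    """Thin façade over :func:`run` mirroring the minimal four-step workflow:
    load a model, choose objectives, instantiate the problem, run."""

    def __init__(self, problem: Problem, config: Optional[EAConfig] = None, **kw):
        if config is None:
            kw.setdefault("seed", 1)
            config = EAConfig(**kw)
        self.problem = problem
        self.config = config
        self.generation_log: list = []

    def run(self) -> SolutionArchive:
        return run(self.problem, self.config, generation_log=self.generation_log)
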