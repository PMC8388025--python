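"""Problem definition layer: modification targets, candidate decoding, and
the BPCY / WYIELD objective functions.

A :class:`Problem` fixes the search space of a strain-design task: which
targets may be modified (reactions, genes, enzymes, or regulatory
variables), the strategy (KO = deletion only, OU = over-/under-expression on
a discrete level grid), the environmental conditions, and the ordered list
of objectives. A :class:`Candidate` is a small set of (target, level) pairs;
:func:`decode` translates it into reaction bound overrides for the
simulators, and :func:`evaluate` turns it into a :class:`Fitness` vector.

Decoding routes per target space:

* reactions — the level gamma scales the wild-type flux into new bounds
  (:func:`strainbench.gpr.reaction_fold_to_bounds`).
* genes — gene levels propagate through each GPR (Boolean for KO, min/max
  algebra for OU) to a reaction-level fold, then to bounds.
* enzymes — gamma scales the reaction's permitted enzyme usage against the
  wild-type usage (:func:`strainbench.enzymes.enzyme_modification_bounds`).
* regulatory — modified regulators are frozen in the Boolean network, the
  steady state is computed, metabolic genes that end up off become level-0,
  direct gene modifications are applied on top (regulation first, then
  expression levels), and the result follows the gene route. With strategy
  KO this is the OptORF vocabulary (deletions of metabolic genes and TFs);
  with OU it is the OptRAM vocabulary (up-/down-regulation and deletions).

Wild-type reference fluxes (for OU folds and for lMOMA/ROOM references) are
the parsimonious-FBA distribution under the problem's environment, computed
once and cached. Evaluations are cached by decoded constraint map (bounded
LRU), since evolutionary runs revisit candidates.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from . import gpr as gpr_mod
from .enzymes import EnzymeParams, attach_protein_pool, enzyme_modification_bounds
from .errors import ConfigurationError, DecodeError, ValidationError
from .model import (
    EnvironmentalConditions,
    FluxDistribution,
    MetabolicModel,
    ModelView,
    apply_conditions,
)
from .regulatory import RegulatoryNetwork, initial_state, regulatory_steady_state
from .simulation import TOLERANCE, SimulationResult, fba, fva, simulate

__all__ = [
    "DEFAULT_LEVEL_GRID",
    "ObjectiveSpec",
    "BPCY",
    "WYIELD",
    "Candidate",
    "Fitness",
    "Problem",
    "RKOProblem",
    "ROUProblem",
    "GKOProblem",
    "GOUProblem",
    "OptORFProblem",
    "OptRAMProblem",
    "wild_type_reference",
    "decode",
    "evaluate",
    "bpcy",
    "wyield",
    "enumerate_candidates",
]

logger = logging.getLogger(__name__)

#: Symmetric powers of two around wild type (0 = deletion).
DEFAULT_LEVEL_GRID: tuple[float, ...] = (
    0.0, 1 / 32, 1 / 16, 1 / 8, 1 / 4, 1 / 2, 2.0, 4.0, 8.0, 16.0, 32.0
)

_OBJECTIVE_KINDS = ("BPCY", "WYIELD", "target_flux", "growth", "modification_count")


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective: what to compute, with which phenotype method."""

    kind: str
    biomass_id: Optional[str] = None
    product_id: Optional[str] = None
    substrate_id: Optional[str] = None
    method: str = "pFBA"
    direction: str = "max"
    alpha: float = 0.5
    objective_fraction: float = 1.0

    def __post_init__(self):
        if self.kind not in _OBJECTIVE_KINDS:
            raise ConfigurationError(
                f"unknown objective kind '{self.kind}'; available: {_OBJECTIVE_KINDS}"
            )
        if self.direction not in ("max", "min"):
            raise ConfigurationError("objective direction must be 'max' or 'min'")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError("WYIELD alpha must lie in [0, 1]")

    @property
    def maximize(self) -> bool:
        return self.direction == "max"


def BPCY(
    biomass_id: str,
    product_id: str,
    substrate_id: Optional[str] = None,
    method: str = "pFBA",
) -> ObjectiveSpec:
    """Biomass-product coupled yield: v_biomass * v_product (divided by
    |v_substrate| when a substrate is configured), to be maximized."""
    return ObjectiveSpec(
        kind="BPCY",
        biomass_id=biomass_id,
        product_id=product_id,
        substrate_id=substrate_id,
        method=method,
    )


def WYIELD(
    biomass_id: str,
    product_id: str,
    alpha: float = 0.5,
    objective_fraction: float = 1.0,
) -> ObjectiveSpec:
    """Weighted yield: alpha * v_max + (1 - alpha) * v_min of the product
    flux at (a fraction of) the mutant's predicted growth, to be maximized."""
    return ObjectiveSpec(
        kind="WYIELD",
        biomass_id=biomass_id,
        product_id=product_id,
        alpha=alpha,
        objective_fraction=objective_fraction,
    )


@dataclass(frozen=True)
class Candidate:
    """A set of (target id, expression level) modifications, unique per target."""

    modifications: frozenset[tuple[str, float]]

    @classmethod
    def of(cls, *mods: tuple[str, float]) -> "Candidate":
        return cls(frozenset(mods))

    def sorted_mods(self) -> tuple[tuple[str, float], ...]:
        return tuple(sorted(self.modifications))

    def targets(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.modifications)

    def __len__(self) -> int:
        return len(self.modifications)

    def label(self) -> str:
        return ";".join(f"{t}:{g:g}" for t, g in self.sorted_mods())


@dataclass(frozen=True)
class Fitness:
    """Objective values aligned with the problem's objective list."""

    values: tuple[float, ...]
    feasible: bool = True


_TARGET_SPACES = ("reactions", "genes", "enzymes", "regulatory")


class Problem:
    """A computational strain-optimization problem definition."""

    def __init__(
        self,
        model: MetabolicModel,
        objectives: Sequence[ObjectiveSpec],
        target_space: str = "genes",
        strategy: str = "KO",
        targets: Optional[Sequence[str]] = None,
        max_modifications: int = 2,
        level_grid: Optional[Sequence[float]] = None,
        env: Optional[EnvironmentalConditions] = None,
        non_targets: Iterable[str] = (),
        network: Optional[RegulatoryNetwork] = None,
        enzymes: Optional[EnzymeParams] = None,
        signals: Optional[dict] = None,
        and_op=min,
        or_op=max,
        cache_size: int = 10000,
    ):
        if target_space not in _TARGET_SPACES:
            raise ConfigurationError(
                f"unknown target space '{target_space}'; available: {_TARGET_SPACES}"
            )
        if strategy not in ("KO", "OU"):
            raise ConfigurationError("strategy must be 'KO' or 'OU'")
        if not 1 <= len(objectives) <= 4:
            raise ConfigurationError("a problem takes between 1 and 4 objectives")
        if max_modifications < 1:
            raise ConfigurationError("max_modifications must be >= 1")
        if target_space == "regulatory" and network is None:
            raise ConfigurationError("regulatory problems need a regulatory network")
        if target_space == "enzymes" and enzymes is None:
            raise ConfigurationError("enzyme problems need enzyme parameters")
        self.model = model
        self.objectives = list(objectives)
        self.target_space = target_space
        self.strategy = strategy
        self.max_modifications = max_modifications
        if strategy == "KO":
            self.level_grid: tuple[float, ...] = (0.0,)
        else:
            grid = tuple(level_grid) if level_grid is not None else DEFAULT_LEVEL_GRID
            if any(g < 0 for g in grid):
                raise ConfigurationError("expression levels must be non-negative")
            self.level_grid = grid
        self.env = env or EnvironmentalConditions()
        self.non_targets = set(non_targets)
        self.network = network
        self.enzymes = enzymes
        self.signals = dict(signals or {})
        self.and_op = and_op
        self.or_op = or_op
        self.targets: list[str] = list(targets) if targets is not None else self._default_targets()
        self._check_targets()
        self.targets = [t for t in self.targets if t not in self.non_targets]
        if not self.targets:
            raise ConfigurationError("problem has an empty target list")
        self._base_view: Optional[ModelView] = None
        self._reference: Optional[FluxDistribution] = None
        self._cache: OrderedDict = OrderedDict()
        self._cache_size = cache_size

    # -- target space ------------------------------------------------------
    def _default_targets(self) -> list[str]:
        model = self.model
        if self.target_space == "reactions":
            skip = set(model.exchange_ids()) | {model.objective_id}
            return [r.id for r in model.reactions if r.id not in skip]
        if self.target_space == "genes":
            used: set[str] = set()
            for r in model.reactions:
                if r.gpr is not None:
                    used |= r.gpr.genes()
            return sorted(used)
        if self.target_space == "enzymes":
            return list(self.enzymes.reaction_ids)
        # regulatory: TFs plus metabolic-gene rule targets
        net = self.network
        tfs = sorted(net.regulators - net.signals - set(self.model.genes))
        gene_targets = sorted(net.metabolic_gene_links(self.model.genes))
        return tfs + gene_targets

    def _check_targets(self) -> None:
        model = self.model
        for t in self.targets:
            if self.target_space == "reactions" and not model.has_reaction(t):
                raise ValidationError(f"target reaction '{t}' not in model")
            if self.target_space == "genes" and t not in model.genes:
                raise ValidationError(f"target gene '{t}' not in model")
            if self.target_space == "enzymes" and t not in self.enzymes.entries:
                raise ValidationError(f"target '{t}' carries no enzyme parameters")
            if self.target_space == "regulatory":
                known = self.network.ids() | model.genes
                if t not in known:
                    raise ValidationError(f"regulatory target '{t}' unknown")

    # -- cached base state -------------------------------------------------
    def base_view(self) -> ModelView:
        """The model under the problem's environment (plus protein pool)."""
        if self._base_view is None:
            view = apply_conditions(self.model, self.env)
            if self.enzymes is not None:
                view = attach_protein_pool(view, self.enzymes)
            self._base_view = view
        return self._base_view

    def validate_candidate(self, candidate: Candidate) -> None:
        if not 1 <= len(candidate) <= self.max_modifications:
            raise DecodeError(
                f"candidate has {len(candidate)} modifications; allowed "
                f"1..{self.max_modifications}"
            )
        target_set = set(self.targets)
        seen: set[str] = set()
        for t, g in candidate.modifications:
            if t not in target_set:
                raise DecodeError(f"unknown target '{t}' for this problem")
            if t in seen:
                raise DecodeError(f"duplicate target '{t}' in candidate")
            seen.add(t)


def wild_type_reference(problem: Problem) -> FluxDistribution:
    """Wild-type pFBA flux distribution under the problem's environment,
    computed once and cached on the problem."""
    if problem._reference is None:
        result = simulate(problem.base_view(), "pFBA")
        if not result.ok:
            raise ConfigurationError(
                f"wild type is not solvable under the given conditions "
                f"(status {result.status})"
            )
        if result.objective_value <= TOLERANCE:
            raise ConfigurationError(
                "wild type has zero growth under the given conditions"
            )
        problem._reference = result.fluxes
    return problem._reference


# ---------------------------------------------------------------------------
# Candidate decoding
# ---------------------------------------------------------------------------

def _gene_levels_to_bounds(
    problem: Problem, levels: dict[str, float], boolean: bool
) -> dict[str, tuple[float, float]]:
    """Propagate gene levels through GPRs to reaction bound overrides."""
    view = problem.base_view()
    reference = wild_type_reference(problem)
    touched = set(levels)
    overrides: dict[str, tuple[float, float]] = {}
    for r in problem.model.reactions:
        if r.gpr is None or not (r.gpr.genes() & touched):
            continue
        if boolean:
            deleted = {g for g, lvl in levels.items() if lvl == 0.0}
            gamma_r = 1.0 if gpr_mod.eval_boolean(r.gpr, deleted) else 0.0
        else:
            gamma_r = gpr_mod.eval_algebraic(
                r.gpr, levels, problem.and_op, problem.or_op
            )
        if gamma_r == 1.0:
            continue
        lb, ub = view.bounds(r.id)
        w = reference.get(r.id, 0.0)
        if gamma_r > 1.0 and w == 0.0:
            logger.debug(
                "over-expression of unused reaction %s (w=0) is a no-op", r.id
            )
        overrides[r.id] = gpr_mod.reaction_fold_to_bounds(gamma_r, w, lb, ub)
    return overrides


def decode(problem: Problem, candidate: Candidate) -> dict[str, tuple[float, float]]:
    """Translate a candidate into reaction bound overrides (deterministic)."""
    problem.validate_candidate(candidate)
    mods = dict(candidate.sorted_mods())
    view = problem.base_view()
    reference = None

    if problem.target_space == "reactions":
        reference = wild_type_reference(problem)
        overrides = {}
        for rid, gamma in sorted(mods.items()):
            lb, ub = view.bounds(rid)
            new = gpr_mod.reaction_fold_to_bounds(gamma, reference.get(rid, 0.0), lb, ub)
            if new != (lb, ub):
                overrides[rid] = new
        return overrides

    if problem.target_space == "genes":
        return _gene_levels_to_bounds(problem, mods, boolean=problem.strategy == "KO")

    if problem.target_space == "enzymes":
        reference = wild_type_reference(problem)
        overrides = {}
        for rid, gamma in sorted(mods.items()):
            usage = problem.enzymes.cost(rid) * reference.get(rid, 0.0)
            new = enzyme_modification_bounds(rid, gamma, problem.enzymes, usage)
            if new is None:
                continue
            lb, ub = view.bounds(rid)
            overrides[rid] = (new[0], min(new[1], ub))
        return overrides

    # regulatory: regulation first, then expression levels
    net = problem.network
    frozen: dict[str, bool] = {}
    direct_genes: dict[str, float] = {}
    for ident, gamma in sorted(mods.items()):
        if ident in problem.model.genes:
            direct_genes[ident] = gamma
        else:
            # A Boolean regulator admits no fractional level: off unless
            # over-expressed (gamma > 1 forces it on).
            frozen[ident] = gamma > 1.0
    state, _ = regulatory_steady_state(
        net, initial_state(net, problem.signals), frozen
    )
    levels: dict[str, float] = {
        g: 0.0
        for g in net.metabolic_gene_links(problem.model.genes)
        if not state[g]
    }
    levels.update(direct_genes)
    if not levels:
        return {}
    return _gene_levels_to_bounds(problem, levels, boolean=problem.strategy == "KO")


# ---------------------------------------------------------------------------
# Objective functions
# ---------------------------------------------------------------------------

def bpcy(
    result: SimulationResult,
    biomass_id: str,
    product_id: str,
    substrate_id: Optional[str] = None,
) -> float:
    """Biomass-product coupled yield from one simulation result.

    (v_biomass * v_product) / |v_substrate| when a substrate is given;
    v_biomass * v_product otherwise. Returns 0 for non-growing mutants and
    (logged) for zero substrate uptake.
    """
    if not result.ok or result.fluxes is None:
        return 0.0
    growth = result.fluxes.get(biomass_id, 0.0)
    if growth <= 0.0:
        return 0.0
    product = result.fluxes.get(product_id, 0.0)
    if substrate_id is None:
        return growth * product + 0.0  # normalize -0.0
    uptake = abs(result.fluxes.get(substrate_id, 0.0))
    if uptake <= TOLERANCE:
        logger.debug("BPCY: zero substrate uptake through %s", substrate_id)
        return 0.0
    return growth * product / uptake + 0.0


def wyield(
    model_view,
    biomass_id: str,
    product_id: str,
    alpha: float = 0.5,
    objective_fraction: float = 1.0,
) -> tuple[float, bool]:
    """Weighted yield of the product at the mutant's predicted growth.

    Fixes biomass >= objective_fraction * (mutant FBA optimum), runs FVA on
    the product, and returns (alpha * v_max + (1 - alpha) * v_min, ok).
    Infeasible mutants yield (0.0, False).
    """
    growth = fba(model_view, biomass_id)
    if not growth.ok:
        return 0.0, False
    ranges = fva(
        model_view, [product_id],
        objective_fraction=objective_fraction, objective_id=biomass_id,
    )
    if product_id not in ranges:
        return 0.0, False
    v_min, v_max = ranges[product_id]
    return alpha * v_max + (1.0 - alpha) * v_min, True


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _sentinel(objectives: Sequence[ObjectiveSpec]) -> tuple[float, ...]:
    return tuple(-math.inf if o.maximize else math.inf for o in objectives)


def _run_objective(
    problem: Problem, view: ModelView, spec: ObjectiveSpec, n_mods: int
) -> tuple[float, bool]:
    if spec.kind == "modification_count":
        return float(n_mods), True
    if spec.kind == "WYIELD":
        return wyield(
            view, spec.biomass_id or problem.model.objective_id,
            spec.product_id, spec.alpha, spec.objective_fraction,
        )
    options = {}
    if spec.method.lower() in ("lmoma", "room"):
        options["reference"] = wild_type_reference(problem)
    result = simulate(view, spec.method, **options)
    if not result.ok:
        return 0.0, False
    if spec.kind == "BPCY":
        return (
            bpcy(result, spec.biomass_id or problem.model.objective_id,
                 spec.product_id, spec.substrate_id),
            True,
        )
    if spec.kind == "target_flux":
        return result.fluxes.get(spec.product_id, 0.0), True
    # growth
    return result.fluxes.get(spec.biomass_id or problem.model.objective_id, 0.0), True


def evaluate(problem: Problem, candidate: Candidate) -> Fitness:
    """Decode once, run every objective's phenotype simulation, and assemble
    the fitness vector. Simulation failures never raise during optimization:
    they yield an infeasible Fitness with worst-case sentinel values."""
    try:
        overrides = decode(problem, candidate)
    except DecodeError:
        raise
    except Exception:  # pragma: no cover - defensive against odd candidates
        logger.exception("decode failed for %s", candidate.label())
        return Fitness(values=_sentinel(problem.objectives), feasible=False)
    # The decoded constraint map determines every phenotype simulation; only
    # a modification_count objective sees the candidate's size itself.
    counts = any(o.kind == "modification_count" for o in problem.objectives)
    key = (len(candidate) if counts else 0, tuple(sorted(overrides.items())))
    cached = problem._cache.get(key)
    if cached is not None:
        problem._cache.move_to_end(key)
        return cached
    view = problem.base_view().with_bounds(overrides)
    values: list[float] = []
    feasible = True
    for spec in problem.objectives:
        value, ok = _run_objective(problem, view, spec, len(candidate))
        values.append(value)
        feasible = feasible and ok
    fitness = (
        Fitness(values=tuple(values), feasible=True)
        if feasible
        else Fitness(values=_sentinel(problem.objectives), feasible=False)
    )
    problem._cache[key] = fitness
    if len(problem._cache) > problem._cache_size:
        problem._cache.popitem(last=False)
    return fitness


# ---------------------------------------------------------------------------
# Candidate-space enumeration (brute force, small spaces)
# ---------------------------------------------------------------------------

def enumerate_candidates(problem: Problem) -> Iterator[Candidate]:
    """Yield every valid candidate of the problem (sizes 1..max, all level
    assignments); intended for exhaustively enumerable toy spaces."""
    for size in range(1, problem.max_modifications + 1):
        for targets in itertools.combinations(problem.targets, size):
            for levels in itertools.product(problem.level_grid, repeat=size):
                yield Candidate(frozenset(zip(targets, levels)))


# ---------------------------------------------------------------------------
# Convenience problem constructors (the field's usual naming)
# ---------------------------------------------------------------------------

def RKOProblem(model, objectives, **kw) -> Problem:
    """Reaction-deletion problem."""
    return Problem(model, objectives, target_space="reactions", strategy="KO", **kw)


def ROUProblem(model, objectives, **kw) -> Problem:
    """Reaction over-/under-expression problem."""
    return Problem(model, objectives, target_space="reactions", strategy="OU", **kw)


def GKOProblem(model, objectives, **kw) -> Problem:
    """Gene-deletion problem."""
    return Problem(model, objectives, target_space="genes", strategy="KO", **kw)


def GOUProblem(model, objectives, **kw) -> Problem:
    """Gene over-/under-expression problem."""
    return Problem(model, objectives, target_space="genes", strategy="OU", **kw)


def OptORFProblem(model, objectives, network, **kw) -> Problem:
    """Deletions over metabolic genes and transcription factors."""
    return Problem(
        model, objectives, target_space="regulatory", strategy="KO",
        network=network, **kw,
    )


def OptRAMProblem(model, objectives, network, **kw) -> Problem:
    """Up-/down-regulation and deletions over regulatory and metabolic targets."""
    return Problem(
        model, objectives, target_space="regulatory", strategy="OU",
        network=network, **kw,
    )
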