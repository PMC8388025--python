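"""Metabolic model data structures, readers/writers, and condition handling.

The central object is :class:`MetabolicModel`: an ordered set of metabolites
and reactions, a gene set, GPR rules parsed into expression trees, and an
objective (biomass) reaction. Flux bounds are the single source of truth for
directionality; there is no separate reversibility flag.

Simulators never consume a model directly but a :class:`ModelView` — a
copy-on-write overlay produced by :func:`apply_conditions` that merges, in
increasing precedence, model bounds < environmental conditions (growth
medium) < per-candidate constraints. The base model is never mutated, which
lets an evolutionary algorithm evaluate thousands of candidate views against
one shared model. A view can also carry extra linear constraints (used for
the shared protein-pool budget).

Supported formats: SBML Level 3 + FBC v2 (read, via cobra/libsbml) and a
plain-JSON dialect (read/write) documented in :func:`save_json`. Infinite
bounds clamp to ``+-DEFAULT_BOUND`` (1000 flux units, the standard
constraint-based-modelling convention) so every LP stays bounded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

from .errors import (
    ConstraintConflictError,
    ModelFormatError,
    NoObjectiveError,
    ValidationError,
)
from .gpr import GPRExpression, parse_gpr

__all__ = [
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "EnvironmentalConditions",
    "FluxDistribution",
    "ExtraConstraint",
    "ModelView",
    "as_view",
    "apply_conditions",
    "stoichiometric_matrix",
    "load_model",
    "load_json",
    "save_json",
    "read_medium_tsv",
]

#: Bounds magnitude used in place of infinity (flux units, mmol/gDW/h by convention).
DEFAULT_BOUND = 1000.0


def _clamp(value: float) -> float:
    if value == math.inf or value > DEFAULT_BOUND:
        return DEFAULT_BOUND
    if value == -math.inf or value < -DEFAULT_BOUND:
        return -DEFAULT_BOUND
    return float(value)


@dataclass
class Metabolite:
    id: str
    compartment: str = "c"
    name: Optional[str] = None


@dataclass
class Reaction:
    """A reaction: signed stoichiometry (negative = consumed), flux bounds,
    and an optional GPR rule."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: Optional[GPRExpression] = None

    @property
    def is_exchange(self) -> bool:
        """Exchange/drain reactions touch exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)


class MetabolicModel:
    """An ordered, validated constraint-based metabolic model."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        genes: Iterable[str] = (),
        objective_id: Optional[str] = None,
        annotations: Optional[dict] = None,
    ):
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.genes: set[str] = set(genes)
        self.objective_id = objective_id
        self.annotations: dict = dict(annotations or {})
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if len(self._rxn_index) != len(self.reactions):
            raise ValidationError("duplicate reaction ids")
        if len(self._met_index) != len(self.metabolites):
            raise ValidationError("duplicate metabolite ids")
        for m in self.metabolites:
            if not m.id:
                raise ValidationError("empty metabolite id")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ValidationError(
                    f"reaction '{r.id}' has lower bound above upper bound"
                )
            if not r.stoichiometry:
                raise ValidationError(f"reaction '{r.id}' has empty stoichiometry")
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise ValidationError(
                        f"reaction '{r.id}' references unknown metabolite '{mid}'"
                    )
            if r.gpr is not None:
                missing = r.gpr.genes() - self.genes
                if missing:
                    raise ValidationError(
                        f"reaction '{r.id}' GPR references unknown genes {sorted(missing)}"
                    )
        if self.objective_id is not None and self.objective_id not in self._rxn_index:
            raise ValidationError(
                f"objective reaction '{self.objective_id}' not in model"
            )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MetabolicModel({len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes, "
            f"objective={self.objective_id!r})"
        )


@dataclass
class EnvironmentalConditions:
    """Growth medium expressed as reaction bound overrides."""

    bounds_override: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for rid, (lb, ub) in self.bounds_override.items():
            if lb > ub:
                raise ConstraintConflictError(rid, lb, ub)


class FluxDistribution(Mapping):
    """A flux vector keyed by reaction id (read-only mapping)."""

    def __init__(self, values: Mapping[str, float]):
        self._values = dict(values)

    def __getitem__(self, rid: str) -> float:
        return self._values[rid]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def get(self, rid: str, default: float = 0.0) -> float:
        return self._values.get(rid, default)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_id\tflux\n")
            for rid, v in self._values.items():
                fh.write(f"{rid}\t{v:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "FluxDistribution":
        values: dict[str, float] = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                rid, v = line.rstrip("\n").split("\t")
                values[rid] = float(v)
        return cls(values)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FluxDistribution({self._values!r})"


@dataclass(frozen=True)
class ExtraConstraint:
    """An additional linear constraint sum(coef_j * v_j) <sense> rhs."""

    coefficients: tuple[tuple[str, float], ...]
    sense: str  # "<=", ">=", "=="
    rhs: float
    name: str = ""

    @classmethod
    def of(cls, coefficients: Mapping[str, float], sense: str, rhs: float, name: str = ""):
        return cls(tuple(sorted(coefficients.items())), sense, float(rhs), name)


class ModelView:
    """Non-destructive bounds/constraint overlay on a base model.

    Precedence when stacking overlays: later (per-candidate) overrides win
    over earlier (environmental) ones, which win over the model's bounds.
    """

    def __init__(
        self,
        model: MetabolicModel,
        bound_overrides: Optional[Mapping[str, tuple[float, float]]] = None,
        extra_constraints: Sequence[ExtraConstraint] = (),
    ):
        self.model = model
        self._overrides: dict[str, tuple[float, float]] = dict(bound_overrides or {})
        self.extra_constraints: tuple[ExtraConstraint, ...] = tuple(extra_constraints)
        for rid, (lb, ub) in self._overrides.items():
            if not model.has_reaction(rid):
                raise ValidationError(f"bound override for unknown reaction '{rid}'")
            if lb > ub:
                raise ConstraintConflictError(rid, lb, ub)

    # -- bounds ------------------------------------------------------------
    def bounds(self, rid: str) -> tuple[float, float]:
        if rid in self._overrides:
            return self._overrides[rid]
        r = self.model.reaction(rid)
        return (r.lower_bound, r.upper_bound)

    @property
    def reaction_ids(self) -> list[str]:
        return self.model.reaction_ids

    @property
    def objective_id(self) -> Optional[str]:
        return self.model.objective_id

    def bound_overrides(self) -> dict[str, tuple[float, float]]:
        return dict(self._overrides)

    # -- derived views -----------------------------------------------------
    def with_bounds(self, overrides: Mapping[str, tuple[float, float]]) -> "ModelView":
        merged = dict(self._overrides)
        merged.update(overrides)
        return ModelView(self.model, merged, self.extra_constraints)

    def with_constraint(self, constraint: ExtraConstraint) -> "ModelView":
        return ModelView(
            self.model, self._overrides, self.extra_constraints + (constraint,)
        )

    def has_conflict(self) -> Optional[str]:
        """Return the id of a reaction whose effective bounds conflict, if any."""
        for rid in self.model.reaction_ids:
            lb, ub = self.bounds(rid)
            if lb > ub:
                return rid
        return None


def as_view(model_or_view) -> ModelView:
    if isinstance(model_or_view, ModelView):
        return model_or_view
    return ModelView(model_or_view)


def apply_conditions(
    model: MetabolicModel | ModelView,
    env: Optional[EnvironmentalConditions] = None,
    extra: Optional[Mapping[str, tuple[float, float]]] = None,
) -> ModelView:
    """Merge environmental conditions and per-candidate bounds into a view.

    Precedence: ``extra`` > ``env`` > model bounds. The source model is never
    mutated. Raises :class:`ConstraintConflictError` if a merged pair has
    lb > ub.
    """
    view = as_view(model)
    merged: dict[str, tuple[float, float]] = {}
    if env is not None:
        merged.update(env.bounds_override)
    if extra:
        merged.update(extra)
    for rid, (lb, ub) in merged.items():
        if not view.model.has_reaction(rid):
            raise ValidationError(f"bound override for unknown reaction '{rid}'")
        if lb > ub:
            raise ConstraintConflictError(rid, lb, ub)
    return view.with_bounds(merged)


def stoichiometric_matrix(model: MetabolicModel | ModelView) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites x reactions), row/column
    order matching the model's ordering."""
    if isinstance(model, ModelView):
        model = model.model
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            S[model._met_index[mid], j] = coef
    return S


# ---------------------------------------------------------------------------
# I/O — JSON dialect
# ---------------------------------------------------------------------------

def load_json(path) -> MetabolicModel:
    """Load the plain-JSON dialect (see :func:`save_json` for the schema)."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"cannot read JSON model '{path}': {exc}") from exc
    try:
        metabolites = [
            Metabolite(id=m["id"], compartment=m.get("compartment", "c"), name=m.get("name"))
            for m in doc["metabolites"]
        ]
        reactions = []
        for r in doc["reactions"]:
            gpr = None
            if r.get("gpr"):
                try:
                    gpr = parse_gpr(r["gpr"])
                except Exception as exc:
                    raise ModelFormatError(
                        f"bad GPR on reaction '{r.get('id')}': {exc}"
                    ) from exc
            reactions.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=_clamp(float(r.get("lb", 0.0))),
                    upper_bound=_clamp(float(r.get("ub", DEFAULT_BOUND))),
                    gpr=gpr,
                )
            )
        genes = set(doc.get("genes", []))
        objective = doc.get("objective")
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed JSON model '{path}': missing {exc}") from exc
    if objective is None:
        raise NoObjectiveError(f"model '{path}' declares no objective reaction")
    return MetabolicModel(metabolites, reactions, genes, objective)


def save_json(model: MetabolicModel, path) -> None:
    """Write the JSON dialect::

        {"metabolites": [{"id", "compartment"}],
         "reactions": [{"id", "stoichiometry": {met: coef}, "lb", "ub",
                        "gpr": string-or-null}],
         "genes": [ids], "objective": reaction-id}
    """
    doc = {
        "metabolites": [
            {"id": m.id, "compartment": m.compartment} for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr.original_string if r.gpr is not None else None,
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
        "objective": model.objective_id,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)


# ---------------------------------------------------------------------------
# I/O — SBML (Level 3 + FBC), parsed through cobra
# ---------------------------------------------------------------------------

def _load_sbml(path) -> MetabolicModel:
    import cobra
    from cobra.util.solver import linear_reaction_coefficients

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ModelFormatError(f"cannot parse SBML '{path}': {exc}") from exc

    metabolites = [
        Metabolite(id=m.id, compartment=m.compartment or "c", name=m.name or None)
        for m in cmodel.metabolites
    ]
    reactions = []
    for r in cmodel.reactions:
        gpr = None
        rule = r.gene_reaction_rule
        if rule and rule.strip():
            try:
                gpr = parse_gpr(rule)
            except Exception as exc:
                raise ModelFormatError(
                    f"bad GPR on reaction '{r.id}': {exc}"
                ) from exc
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=_clamp(r.lower_bound),
                upper_bound=_clamp(r.upper_bound),
                gpr=gpr,
            )
        )
    genes = {g.id for g in cmodel.genes}
    coeffs = linear_reaction_coefficients(cmodel)
    if not coeffs:
        raise NoObjectiveError(f"SBML model '{path}' declares no FBC objective")
    objective = next(iter(coeffs)).id
    return MetabolicModel(metabolites, reactions, genes, objective)


def load_model(path, format: str = None) -> MetabolicModel:
    """Load a model from SBML (L3+FBC) or the JSON dialect.

    ``format`` is ``"sbml"`` or ``"json"``; when omitted it is inferred from
    the file extension (.xml/.sbml -> SBML, .json -> JSON).
    """
    fmt = (format or "").lower()
    if not fmt:
        s = str(path).lower()
        fmt = "json" if s.endswith(".json") else "sbml"
    if fmt == "json":
        return load_json(path)
    if fmt == "sbml":
        return _load_sbml(path)
    raise ModelFormatError(f"unknown model format '{format}' (use sbml or json)")


def read_medium_tsv(path) -> EnvironmentalConditions:
    """Read a growth-medium TSV with columns reaction_id, lb, ub."""
    overrides: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["reaction_id", "lb", "ub"]:
            raise ModelFormatError(
                f"medium file '{path}': expected header reaction_id\\tlb\\tub"
            )
        for line in fh:
            if not line.strip():
                continue
            rid, lb, ub = line.rstrip("\n").split("\t")[:3]
            overrides[rid] = (_clamp(float(lb)), _clamp(float(ub)))
    return EnvironmentalConditions(overrides)
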