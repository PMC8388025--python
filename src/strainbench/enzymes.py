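"""Enzymatic constraints: a shared protein-pool budget over catalysed fluxes.

The single-pool formulation adds one linear constraint

    sum_j (MW_j / kcat_j) * v_j  <=  P_pool

over the parameterized (enzyme-catalysed) reactions, where MW_j is the enzyme
molecular weight (kDa), kcat_j the turnover number in the flux direction
(1/h) and P_pool the total protein budget (g/gDW). This captures the same
semantics as pool-constrained models that introduce enzyme pseudo-species,
without splitting the model; all simulators honour the constraint because it
travels on the :class:`~strainbench.model.ModelView`.

Parameterized reactions must be irreversible in the view (lb >= 0): a signed
flux would earn negative enzyme usage. Reversible reactions are split first
with :func:`split_reversible` (explicitly — no implicit model surgery).

Enzyme-level modifications scale a reaction's permitted enzyme usage
relative to its wild-type usage; see :func:`enzyme_modification_bounds`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import ValidationError
from .model import ExtraConstraint, MetabolicModel, ModelView, Reaction, as_view

__all__ = [
    "EnzymeParams",
    "attach_protein_pool",
    "enzyme_modification_bounds",
    "split_reversible",
    "read_enzyme_tsv",
]


@dataclass
class EnzymeParams:
    """Per-reaction kinetic parameters and the shared pool size.

    ``entries`` maps reaction id -> (kcat [1/h], MW [kDa]); ``pool`` is
    P_pool in g/gDW. The specific cost of a reaction is MW/kcat.
    """

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    pool: float = 1.0

    def __post_init__(self):
        if self.pool < 0:
            raise ValidationError("protein pool must be non-negative")
        for rid, (kcat, mw) in self.entries.items():
            if kcat <= 0 or mw <= 0:
                raise ValidationError(
                    f"enzyme parameters for '{rid}' must be positive (kcat={kcat}, mw={mw})"
                )

    def cost(self, rid: str) -> float:
        kcat, mw = self.entries[rid]
        return mw / kcat

    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.entries)


def attach_protein_pool(model_view, params: EnzymeParams) -> ModelView:
    """Return a view carrying the pool constraint sum (MW/kcat) v <= P_pool.

    Every parameterized reaction must be irreversible in the view
    (lower bound >= 0) and must carry a GPR (it is enzyme-catalysed).
    """
    view = as_view(model_view)
    coefs: dict[str, float] = {}
    for rid in params.reaction_ids:
        if not view.model.has_reaction(rid):
            raise ValidationError(f"enzyme parameters for unknown reaction '{rid}'")
        if view.model.reaction(rid).gpr is None:
            raise ValidationError(
                f"reaction '{rid}' carries enzyme parameters but no GPR"
            )
        lb, _ = view.bounds(rid)
        if lb < 0:
            raise ValidationError(
                f"reaction '{rid}' is reversible (lb={lb}); split it before "
                f"attaching the protein pool"
            )
        coefs[rid] = params.cost(rid)
    return view.with_constraint(
        ExtraConstraint.of(coefs, "<=", params.pool, name="protein_pool")
    )


def enzyme_modification_bounds(
    rid: str,
    gamma: float,
    params: EnzymeParams,
    reference_usage: float,
) -> Optional[tuple[float, float]]:
    """Translate an enzyme-expression fold into reaction flux bounds.

    ``reference_usage`` is the wild-type enzyme usage (MW/kcat) * w_r of the
    reaction. The usage cap (MW/kcat) * v <= gamma * reference_usage is
    returned as the equivalent flux bound pair (single-reaction constraint):

    * gamma = 0: (0, 0) — the enzyme is absent.
    * gamma = 1: None — no-op, the pool alone binds.
    * otherwise: (0, gamma * reference_usage / cost); for gamma > 1 this is a
      relaxed cap — the global pool still binds.
    """
    if gamma < 0:
        raise ValueError(f"negative enzyme expression fold {gamma}")
    if rid not in params.entries:
        raise ValidationError(f"reaction '{rid}' carries no enzyme parameters")
    if gamma == 1.0:
        return None
    if gamma == 0.0:
        return (0.0, 0.0)
    return (0.0, gamma * reference_usage / params.cost(rid))


def split_reversible(model: MetabolicModel, reaction_ids) -> MetabolicModel:
    """Return a new model with the listed reversible reactions split into
    irreversible forward/backward halves (``<id>_fwd``/``<id>_rev``); the
    halves share the original GPR (and hence any enzyme cost)."""
    reaction_ids = set(reaction_ids)
    reactions: list[Reaction] = []
    for r in model.reactions:
        if r.id in reaction_ids and r.lower_bound < 0:
            reactions.append(
                Reaction(f"{r.id}_fwd", dict(r.stoichiometry), 0.0,
                         max(0.0, r.upper_bound), r.gpr)
            )
            reactions.append(
                Reaction(
                    f"{r.id}_rev",
                    {m: -c for m, c in r.stoichiometry.items()},
                    0.0,
                    -r.lower_bound,
                    r.gpr,
                )
            )
        else:
            reactions.append(r)
    return MetabolicModel(
        model.metabolites, reactions, model.genes, model.objective_id, model.annotations
    )


def read_enzyme_tsv(path, pool: float) -> EnzymeParams:
    """Read an enzyme parameter TSV with columns reaction_id, kcat_per_h,
    mw_kda; the pool size comes from the run configuration."""
    entries: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"reaction_id", "kcat_per_h", "mw_kda"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(
                f"enzyme file '{path}': expected columns reaction_id, kcat_per_h, mw_kda"
            )
        for row in reader:
            entries[row["reaction_id"]] = (
                float(row["kcat_per_h"]),
                float(row["mw_kda"]),
            )
    return EnzymeParams(entries=entries, pool=pool)
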