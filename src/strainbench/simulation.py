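"""Phenotype-prediction methods over a model view.

All methods solve variations of the steady-state flux cone

    S v = 0,   lb <= v <= ub

where the bounds come from the view (model < medium < candidate overrides)
and any extra linear constraints on the view (e.g. the protein-pool budget)
are honoured by every method.

* :func:`fba`    — maximize (or minimize) the objective flux.
* :func:`pfba`   — parsimonious FBA: fix the objective at (a fraction of) its
  optimum, then minimize total absolute flux via split variables.
* :func:`fva`    — per-reaction min/max at a fraction of the optimum.
* :func:`lmoma`  — linear minimization of metabolic adjustment: minimize the
  L1 distance to a reference flux distribution under mutant bounds.
* :func:`room`   — regulatory on/off minimization: MILP minimizing the number
  of fluxes that leave a tolerance window around the reference.

Infeasible or unbounded problems are reported through
``SimulationResult.status``; no solver condition raises.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import CapabilityError
from .model import FluxDistribution, ModelView, as_view
from .solver import LinearProblem, Status, has_capability

__all__ = ["SimulationResult", "fba", "pfba", "fva", "lmoma", "room", "simulate"]

logger = logging.getLogger(__name__)

#: Feasibility / equality tolerance used across the package.
TOLERANCE = 1e-6

#: ROOM defaults — canonical values from the ROOM literature.
ROOM_DELTA = 0.03
ROOM_EPSILON = 0.001


@dataclass
class SimulationResult:
    status: str
    objective_value: Optional[float]
    fluxes: Optional[FluxDistribution]
    method: str
    extras: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == Status.OPTIMAL


def _failed(method: str, status: str) -> SimulationResult:
    return SimulationResult(status=status, objective_value=None, fluxes=None, method=method)


def _add_flux_vars(lp: LinearProblem, view: ModelView) -> None:
    for rid in view.reaction_ids:
        lb, ub = view.bounds(rid)
        lp.add_var(rid, lb, ub)


def _add_steady_state(lp: LinearProblem, view: ModelView, var=lambda rid: rid) -> None:
    model = view.model
    by_met: dict[str, dict[str, float]] = {m.id: {} for m in model.metabolites}
    for r in model.reactions:
        for mid, coef in r.stoichiometry.items():
            by_met[mid][r.id] = coef
    for mid, coefs in by_met.items():
        if coefs:
            lp.add_constraint({var(rid): c for rid, c in coefs.items()}, "==", 0.0)
    for con in view.extra_constraints:
        lp.add_constraint({var(rid): c for rid, c in con.coefficients}, con.sense, con.rhs)


def _split_flux_vars(lp: LinearProblem, view: ModelView) -> None:
    """Encode v = v+ - v- with v+, v- >= 0 honouring the view bounds."""
    for rid in view.reaction_ids:
        lb, ub = view.bounds(rid)
        lp.add_var(f"{rid}+", 0.0, max(0.0, ub))
        lp.add_var(f"{rid}-", 0.0, max(0.0, -lb))
        # net flux within [lb, ub]
        lp.add_constraint({f"{rid}+": 1.0, f"{rid}-": -1.0}, ">=", lb)
        lp.add_constraint({f"{rid}+": 1.0, f"{rid}-": -1.0}, "<=", ub)


def fba(
    model_view, objective_id: Optional[str] = None, maximize: bool = True
) -> SimulationResult:
    """Flux balance analysis: optimize the objective flux over the cone."""
    view = as_view(model_view)
    objective_id = objective_id or view.objective_id
    conflict = view.has_conflict()
    if conflict is not None:
        return _failed("FBA", Status.INFEASIBLE)
    lp = LinearProblem()
    _add_flux_vars(lp, view)
    _add_steady_state(lp, view)
    lp.set_objective({objective_id: 1.0}, maximize=maximize)
    sol = lp.solve()
    if sol.status != Status.OPTIMAL:
        return _failed("FBA", sol.status)
    fluxes = FluxDistribution({rid: sol.values[rid] for rid in view.reaction_ids})
    return SimulationResult(Status.OPTIMAL, sol.objective, fluxes, "FBA")


def pfba(
    model_view, objective_id: Optional[str] = None, fraction: float = 1.0
) -> SimulationResult:
    """Parsimonious FBA.

    Stage 1 computes the FBA optimum v*; stage 2 fixes the objective flux to
    ``fraction * v*`` (default 1.0) and minimizes total absolute flux using
    split variables v = v+ - v-. Returns the stage-2 fluxes with
    ``objective_value`` equal to the stage-1 optimum; the minimal total flux
    is reported in ``extras["total_flux"]``.
    """
    view = as_view(model_view)
    objective_id = objective_id or view.objective_id
    stage1 = fba(view, objective_id)
    if not stage1.ok:
        return _failed("pFBA", stage1.status)
    lp = LinearProblem()
    _split_flux_vars(lp, view)

    def net(rid: str) -> dict[str, float]:
        return {f"{rid}+": 1.0, f"{rid}-": -1.0}

    model = view.model
    by_met: dict[str, dict[str, float]] = {m.id: {} for m in model.metabolites}
    for r in model.reactions:
        for mid, coef in r.stoichiometry.items():
            by_met[mid][r.id] = coef
    for mid, coefs in by_met.items():
        if coefs:
            combined: dict[str, float] = {}
            for rid, c in coefs.items():
                combined[f"{rid}+"] = c
                combined[f"{rid}-"] = -c
            lp.add_constraint(combined, "==", 0.0)
    for con in view.extra_constraints:
        combined = {}
        for rid, c in con.coefficients:
            combined[f"{rid}+"] = c
            combined[f"{rid}-"] = -c
        lp.add_constraint(combined, con.sense, con.rhs)
    lp.add_constraint(net(objective_id), "==", fraction * stage1.objective_value)
    total = {}
    for rid in view.reaction_ids:
        total[f"{rid}+"] = 1.0
        total[f"{rid}-"] = 1.0
    lp.set_objective(total, maximize=False)
    sol = lp.solve()
    if sol.status != Status.OPTIMAL:
        return _failed("pFBA", sol.status)
    fluxes = FluxDistribution(
        {rid: sol.values[f"{rid}+"] - sol.values[f"{rid}-"] for rid in view.reaction_ids}
    )
    return SimulationResult(
        Status.OPTIMAL, stage1.objective_value, fluxes, "pFBA",
        extras={"total_flux": sol.objective},
    )


def fva(
    model_view,
    reaction_ids=None,
    objective_fraction: float = 1.0,
    objective_id: Optional[str] = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis.

    Constrains the objective flux to at least ``objective_fraction`` times the
    FBA optimum, then minimizes and maximizes each listed reaction
    (2 * len(reaction_ids) LPs). Reactions whose sub-problem fails are left
    out of the returned map (logged).
    """
    view = as_view(model_view)
    objective_id = objective_id or view.objective_id
    reaction_ids = list(reaction_ids) if reaction_ids is not None else view.reaction_ids
    base = fba(view, objective_id)
    if not base.ok:
        return {}
    ranges: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids:
        lo_hi = []
        failed = False
        for maximize in (False, True):
            lp = LinearProblem()
            _add_flux_vars(lp, view)
            _add_steady_state(lp, view)
            lp.add_constraint(
                {objective_id: 1.0}, ">=", objective_fraction * base.objective_value
            )
            lp.set_objective({rid: 1.0}, maximize=maximize)
            sol = lp.solve()
            if sol.status != Status.OPTIMAL:
                logger.warning("FVA sub-problem for %s (%s) ended %s", rid,
                               "max" if maximize else "min", sol.status)
                failed = True
                break
            lo_hi.append(sol.objective)
        if not failed:
            ranges[rid] = (lo_hi[0], lo_hi[1])
    return ranges


def lmoma(model_view, reference: Optional[Mapping[str, float]] = None) -> SimulationResult:
    """Linear MOMA: minimize sum |v_i - w_i| under the mutant bounds.

    ``reference`` maps reaction id -> wild-type flux w_i (missing entries are
    treated as 0; an empty reference therefore minimizes total flux).
    ``objective_value`` is the flux through the model's objective (biomass)
    reaction in the minimal-adjustment solution; the attained L1 deviation is
    reported in ``extras["deviation"]``.
    """
    view = as_view(model_view)
    reference = dict(reference or {})
    conflict = view.has_conflict()
    if conflict is not None:
        return _failed("lMOMA", Status.INFEASIBLE)
    lp = LinearProblem()
    _add_flux_vars(lp, view)
    _add_steady_state(lp, view)
    dev_terms: dict[str, float] = {}
    for rid in view.reaction_ids:
        w = float(reference.get(rid, 0.0))
        dp = lp.add_var(f"dev+_{rid}", 0.0, math.inf)
        dn = lp.add_var(f"dev-_{rid}", 0.0, math.inf)
        # v - d+ + d- == w  =>  d+ >= v - w, d- >= w - v at optimum
        lp.add_constraint({rid: 1.0, dp: -1.0, dn: 1.0}, "==", w)
        dev_terms[dp] = 1.0
        dev_terms[dn] = 1.0
    lp.set_objective(dev_terms, maximize=False)
    sol = lp.solve()
    if sol.status != Status.OPTIMAL:
        return _failed("lMOMA", sol.status)
    fluxes = FluxDistribution({rid: sol.values[rid] for rid in view.reaction_ids})
    biomass = fluxes.get(view.objective_id, 0.0) if view.objective_id else 0.0
    return SimulationResult(
        Status.OPTIMAL, biomass, fluxes, "lMOMA", extras={"deviation": sol.objective}
    )


def room(
    model_view,
    reference: Optional[Mapping[str, float]] = None,
    delta: float = ROOM_DELTA,
    epsilon: float = ROOM_EPSILON,
) -> SimulationResult:
    """Regulatory on/off minimization of metabolic flux (MILP).

    Minimizes the number of reactions whose flux leaves the window
    ``[w_i - delta*|w_i| - epsilon, w_i + delta*|w_i| + epsilon]`` around the
    reference, with one binary y_i per reaction:

        v_i - y_i (ub_i - w_u_i) <= w_u_i
        v_i - y_i (lb_i - w_l_i) >= w_l_i

    ``objective_value`` is the biomass flux of the solution; the number of
    significantly changed fluxes is in ``extras["significant_changes"]``.
    """
    if not has_capability("milp"):  # pragma: no cover - defensive
        raise CapabilityError("ROOM needs a MILP backend; use lMOMA instead")
    if delta < 0 or epsilon < 0:
        raise ValueError("delta and epsilon must be non-negative")
    view = as_view(model_view)
    reference = dict(reference or {})
    conflict = view.has_conflict()
    if conflict is not None:
        return _failed("ROOM", Status.INFEASIBLE)
    lp = LinearProblem()
    _add_flux_vars(lp, view)
    _add_steady_state(lp, view)
    y_vars = []
    for rid in view.reaction_ids:
        w = float(reference.get(rid, 0.0))
        lb, ub = view.bounds(rid)
        wu = w + delta * abs(w) + epsilon
        wl = w - delta * abs(w) - epsilon
        y = lp.add_var(f"y_{rid}", 0.0, 1.0, integer=True)
        y_vars.append(y)
        # y = 0 forces v into the window; y = 1 relaxes to the full bounds.
        if ub > wu:
            lp.add_constraint({rid: 1.0, y: -(ub - wu)}, "<=", wu)
        if lb < wl:
            lp.add_constraint({rid: 1.0, y: -(lb - wl)}, ">=", wl)
    lp.set_objective({y: 1.0 for y in y_vars}, maximize=False)
    sol = lp.solve()
    if sol.status != Status.OPTIMAL:
        return _failed("ROOM", sol.status)
    fluxes = FluxDistribution({rid: sol.values[rid] for rid in view.reaction_ids})
    biomass = fluxes.get(view.objective_id, 0.0) if view.objective_id else 0.0
    changes = int(round(sum(sol.values[y] for y in y_vars)))
    return SimulationResult(
        Status.OPTIMAL, biomass, fluxes, "ROOM",
        extras={"significant_changes": changes},
    )


_METHODS = ("FBA", "pFBA", "lMOMA", "ROOM", "MOMA")


def simulate(model_view, method: str, **options) -> SimulationResult:
    """Dispatch to a phenotype method by name (case-insensitive).

    Consistent option names across methods: ``objective_id``, ``fraction``
    (pFBA), ``reference`` (lMOMA/ROOM; auto-computed as the view's wild-type
    pFBA when omitted, logged), ``delta``/``epsilon`` (ROOM).
    """
    key = method.strip().lower()
    view = as_view(model_view)
    if key == "fba":
        return fba(view, options.get("objective_id"), options.get("maximize", True))
    if key == "pfba":
        return pfba(view, options.get("objective_id"), options.get("fraction", 1.0))
    if key in ("lmoma", "room"):
        reference = options.get("reference")
        if reference is None:
            logger.info("no reference supplied for %s; using wild-type pFBA", method)
            wt = pfba(view, options.get("objective_id"))
            if not wt.ok:
                return _failed(method, wt.status)
            reference = wt.fluxes
        if key == "lmoma":
            return lmoma(view, reference)
        return room(
            view, reference,
            options.get("delta", ROOM_DELTA), options.get("epsilon", ROOM_EPSILON),
        )
    if key == "moma":
        raise CapabilityError(
            "MOMA requires a quadratic-capable solver backend, which is not "
            "configured; use lMOMA as the linear surrogate"
        )
    raise ValueError(f"unknown simulation method '{method}'; available: {_METHODS}")
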