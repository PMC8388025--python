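"""Boolean transcriptional regulation and its integration with metabolism.

A :class:`RegulatoryNetwork` is a set of Boolean rules ``target = expr`` over
transcription factors (TFs), metabolic genes, and environment signals
(identifiers prefixed ``env_``). Two integration routes are provided:

* :func:`rfba` — compute the network's synchronous steady state, switch off
  every reaction whose GPR is false under the off-genes, then run one FBA.
  This is the single-step variant used as a mutant-evaluation routine inside
  optimization loops, not the time-stepped dynamic rFBA.
* :func:`srfba` — one joint MILP: a binary per regulatory variable with the
  Boolean rules linearized, gene binaries coupled to reaction bounds through
  the linearized GPR, biomass maximized over fluxes and binaries together.

Update semantics are synchronous; when the trajectory enters a cycle the
state is collapsed by element-wise AND over the cycle (a gene counts as on
only if it is on throughout), reported with ``converged = False``. The srFBA
MILP leaves cyclic binaries free (optimistic) — on acyclic networks the two
routes coincide.

Rule file format: one rule per line, ``target = <boolean expr>`` with
operators and/or/not, constants true/false, and ``env_``-prefixed signals;
blank lines and ``#`` comments ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError
from .gpr import (
    And,
    Const,
    GeneRef,
    GPRExpression,
    Not,
    Or,
    parse_bool_expr,
)
from .model import ModelView, as_view
from .simulation import SimulationResult, Status, _add_flux_vars, _add_steady_state, _failed, fba
from .solver import LinearProblem

__all__ = [
    "RegulatoryRule",
    "RegulatoryNetwork",
    "RegulatoryState",
    "initial_state",
    "synchronous_update",
    "regulatory_steady_state",
    "rfba",
    "srfba",
    "read_rule_file",
]

SIGNAL_PREFIX = "env_"


@dataclass(frozen=True)
class RegulatoryRule:
    target: str
    expression: GPRExpression


class RegulatoryNetwork:
    """Boolean rules plus the classification of their identifiers."""

    def __init__(self, rules: Sequence[RegulatoryRule]):
        self.rules: dict[str, RegulatoryRule] = {}
        for rule in rules:
            if rule.target in self.rules:
                raise ValidationError(f"duplicate regulatory target '{rule.target}'")
            if rule.target.startswith(SIGNAL_PREFIX):
                raise ValidationError(
                    f"environment signal '{rule.target}' cannot be a rule target"
                )
            self.rules[rule.target] = rule
        leaves: set[str] = set()
        for rule in rules:
            leaves |= rule.expression.genes()
        self.signals: set[str] = {x for x in leaves if x.startswith(SIGNAL_PREFIX)}
        # Regulators: every non-signal identifier that appears on a
        # right-hand side, plus rule targets that regulate others.
        self.regulators: set[str] = (leaves - self.signals) | {
            t for t in self.rules if self._regulates(t)
        }

    def _regulates(self, ident: str) -> bool:
        return any(
            ident in rule.expression.genes() for rule in self.rules.values()
        )

    @property
    def targets(self) -> set[str]:
        return set(self.rules)

    def ids(self) -> set[str]:
        return self.targets | self.regulators | self.signals

    def metabolic_gene_links(self, model_genes: Iterable[str]) -> set[str]:
        """Rule targets that are genes of the attached metabolic model."""
        return self.targets & set(model_genes)

    def __len__(self) -> int:
        return len(self.rules)


#: A complete Boolean state over a network's targets, regulators and signals.
RegulatoryState = dict


def initial_state(
    net: RegulatoryNetwork,
    signals: Optional[Mapping[str, bool]] = None,
    default: bool = True,
) -> RegulatoryState:
    """Build a complete state: signals from ``signals`` (missing ones off),
    every other identifier set to ``default`` (genes start expressed)."""
    state: RegulatoryState = {}
    for ident in net.ids():
        if ident in net.signals:
            state[ident] = bool(signals.get(ident, False)) if signals else False
        else:
            state[ident] = default
    return state


def _eval_state(expr: GPRExpression, state: Mapping[str, bool]) -> bool:
    def ev(node) -> bool:
        if isinstance(node, GeneRef):
            return bool(state.get(node.gene, True))
        if isinstance(node, Const):
            return node.value
        if isinstance(node, Not):
            return not ev(node.child)
        if isinstance(node, And):
            return all(ev(c) for c in node.children)
        if isinstance(node, Or):
            return any(ev(c) for c in node.children)
        raise TypeError(f"unexpected node {node!r}")

    return ev(expr.root)


def _normalize_frozen(frozen) -> dict[str, bool]:
    """Frozen ids may be a set (pinned false, i.e. deleted) or a mapping."""
    if frozen is None:
        return {}
    if isinstance(frozen, Mapping):
        return {k: bool(v) for k, v in frozen.items()}
    return {k: False for k in frozen}


def synchronous_update(
    net: RegulatoryNetwork, state: RegulatoryState, frozen=None
) -> RegulatoryState:
    """One synchronous step: every non-frozen target re-evaluated from the
    previous state simultaneously; signals and frozen ids are never updated."""
    pinned = _normalize_frozen(frozen)
    nxt = dict(state)
    nxt.update(pinned)
    for target, rule in net.rules.items():
        if target in pinned:
            continue
        nxt[target] = _eval_state(rule.expression, state)
    return nxt


def regulatory_steady_state(
    net: RegulatoryNetwork,
    initial: RegulatoryState,
    frozen=None,
    max_iter: int = 64,
) -> tuple[RegulatoryState, bool]:
    """Iterate synchronous updates to a fixed point or a cycle.

    On a cycle the returned state is the element-wise AND over the cycle's
    states (conservative: on only if on throughout) and ``converged`` is
    False. ``max_iter`` bounds the walk; exhausting it is treated as a cycle
    over the visited suffix.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    pinned = _normalize_frozen(frozen)
    state = dict(initial)
    state.update(pinned)
    seen: dict[tuple, int] = {}
    history: list[RegulatoryState] = [state]
    key = tuple(sorted(state.items()))
    seen[key] = 0
    for _ in range(max_iter):
        state = synchronous_update(net, state, pinned)
        key = tuple(sorted(state.items()))
        if key in seen:
            start = seen[key]
            cycle = history[start:]
            if len(cycle) == 1:
                return dict(state), True
            collapsed = {
                ident: all(s[ident] for s in cycle) for ident in state
            }
            collapsed.update(pinned)
            return collapsed, False
        seen[key] = len(history)
        history.append(state)
    collapsed = {ident: all(s[ident] for s in history) for ident in state}
    collapsed.update(pinned)
    return collapsed, False


def rfba(
    model_view,
    net: RegulatoryNetwork,
    initial: Optional[RegulatoryState] = None,
    frozen=None,
    signals: Optional[Mapping[str, bool]] = None,
) -> SimulationResult:
    """Regulatory FBA: steady state of the Boolean network, GPR-disabled
    reactions zeroed, then one FBA."""
    from .gpr import eval_boolean

    view = as_view(model_view)
    if initial is None:
        initial = initial_state(net, signals)
    state, converged = regulatory_steady_state(net, initial, frozen)
    off_genes = {
        g for g in net.metabolic_gene_links(view.model.genes) if not state[g]
    }
    # Deleted (frozen-false) metabolic genes count as off as well.
    off_genes |= {
        g for g, v in _normalize_frozen(frozen).items()
        if not v and g in view.model.genes
    }
    overrides: dict[str, tuple[float, float]] = {}
    for r in view.model.reactions:
        if r.gpr is not None and not eval_boolean(r.gpr, off_genes):
            overrides[r.id] = (0.0, 0.0)
    result = fba(view.with_bounds(overrides))
    result.method = "rFBA"
    result.extras["regulatory_state"] = state
    result.extras["converged"] = converged
    result.extras["off_genes"] = sorted(off_genes)
    return result


# ---------------------------------------------------------------------------
# srFBA — joint MILP
# ---------------------------------------------------------------------------

class _BoolLinearizer:
    """Create binaries and standard AND/OR/NOT linearizations inside a
    LinearProblem. Identifier binaries are shared; internal nodes get fresh
    auxiliaries."""

    def __init__(self, lp: LinearProblem):
        self.lp = lp
        self._aux = 0

    def ident(self, name: str) -> str:
        var = f"b_{name}"
        if not self.lp.has_var(var):
            self.lp.add_var(var, 0.0, 1.0, integer=True)
        return var

    def fix(self, name: str, value: bool) -> str:
        var = self.ident(name)
        self.lp.set_var_bounds(var, float(value), float(value))
        return var

    def _fresh(self) -> str:
        self._aux += 1
        return self.lp.add_var(f"aux_{self._aux}", 0.0, 1.0, integer=True)

    def linearize(self, node) -> str:
        if isinstance(node, GeneRef):
            return self.ident(node.gene)
        if isinstance(node, Const):
            var = self._fresh()
            self.lp.set_var_bounds(var, float(node.value), float(node.value))
            return var
        if isinstance(node, Not):
            child = self.linearize(node.child)
            var = self._fresh()
            self.lp.add_constraint({var: 1.0, child: 1.0}, "==", 1.0)
            return var
        children = [self.linearize(c) for c in node.children]
        var = self._fresh()
        k = len(children)
        if isinstance(node, And):
            for c in children:
                self.lp.add_constraint({var: 1.0, c: -1.0}, "<=", 0.0)
            self.lp.add_constraint(
                {var: 1.0, **{c: -1.0 for c in children}}, ">=", -(k - 1)
            )
        else:  # Or
            for c in children:
                self.lp.add_constraint({var: 1.0, c: -1.0}, ">=", 0.0)
            self.lp.add_constraint(
                {var: 1.0, **{c: -1.0 for c in children}}, "<=", 0.0
            )
        return var

    def equate(self, name: str, node) -> None:
        lhs = self.ident(name)
        rhs = self.linearize(node)
        self.lp.add_constraint({lhs: 1.0, rhs: -1.0}, "==", 0.0)


def srfba(
    model_view,
    net: RegulatoryNetwork,
    frozen=None,
    signals: Optional[Mapping[str, bool]] = None,
) -> SimulationResult:
    """Steady-state regulatory FBA as a single MILP.

    One binary per regulatory identifier, rules linearized as equalities,
    gene binaries coupled to reaction fluxes via
    ``lb_i * b_GPR(i) <= v_i <= ub_i * b_GPR(i)``, biomass maximized over the
    joint flux/binary space. Signals are fixed from ``signals`` (missing
    signals off); frozen ids are fixed to their pinned value; genes outside
    the network are fixed on. Cyclic dependencies leave their binaries free,
    so on acyclic networks srFBA matches :func:`rfba`.
    """
    view = as_view(model_view)
    conflict = view.has_conflict()
    if conflict is not None:
        return _failed("srFBA", Status.INFEASIBLE)
    pinned = _normalize_frozen(frozen)
    lp = LinearProblem()
    _add_flux_vars(lp, view)
    _add_steady_state(lp, view)
    lin = _BoolLinearizer(lp)

    for sig in net.signals:
        lin.fix(sig, bool(signals.get(sig, False)) if signals else False)
    for ident, value in pinned.items():
        lin.fix(ident, value)
    for target, rule in net.rules.items():
        if target in pinned:
            continue
        lin.equate(target, rule.expression.root)

    controlled = net.ids() | set(pinned)
    for r in view.model.reactions:
        if r.gpr is None:
            continue
        # Genes never touched by regulation or freezing stay on.
        for g in r.gpr.genes():
            if g not in controlled:
                lin.fix(g, True)
        b_r = lin.linearize(r.gpr.root)
        lb, ub = view.bounds(r.id)
        lp.add_constraint({r.id: 1.0, b_r: -ub}, "<=", 0.0)
        lp.add_constraint({r.id: 1.0, b_r: -lb}, ">=", 0.0)

    objective_id = view.objective_id
    lp.set_objective({objective_id: 1.0}, maximize=True)
    sol = lp.solve()
    if sol.status != Status.OPTIMAL:
        return _failed("srFBA", sol.status)
    from .model import FluxDistribution

    fluxes = FluxDistribution({rid: sol.values[rid] for rid in view.reaction_ids})
    state = {
        ident: sol.values[f"b_{ident}"] > 0.5
        for ident in net.ids()
        if lp.has_var(f"b_{ident}")
    }
    return SimulationResult(
        Status.OPTIMAL, sol.objective, fluxes, "srFBA",
        extras={"regulatory_state": state},
    )


def read_rule_file(path) -> RegulatoryNetwork:
    """Parse a plain-text rule file: ``target = <boolean expr>`` per line."""
    rules: list[RegulatoryRule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(
                    f"rule file '{path}' line {lineno}: expected 'target = expr'"
                )
            target, expr = line.split("=", 1)
            rules.append(
                RegulatoryRule(target=target.strip(), expression=parse_bool_expr(expr))
            )
    return RegulatoryNetwork(rules)
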