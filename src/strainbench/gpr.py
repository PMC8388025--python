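"""Gene-protein-reaction (GPR) rules and Boolean expressions.

A GPR rule is a Boolean expression over gene identifiers linking genotype to
the reaction it catalyses, e.g. ``"g3 or (g1 and g4)"`` for a reaction carried
either by the enzyme of ``g3`` or by the ``g1``/``g4`` complex. The same tree
is evaluated two ways:

* **Boolean** — for deletion analysis: a deleted gene is false and a false
  rule disables the reaction.
* **Algebraic** — for over-/under-expression: gene identifiers are replaced by
  expression folds relative to wild type (1 = unchanged, 0 = deleted) and the
  AND/OR operators by ``min``/``max`` reductions (complex capacity is limited
  by its scarcest subunit; isozymes contribute their best). The reductions
  are injectable: passing ``or_op=sum`` treats isozymes as additive capacity.

The grammar (EBNF, also documented in the README)::

    expr    = term , { ("or" | "|") , term } ;
    term    = factor , { ("and" | "&") , factor } ;
    factor  = [ "not" | "!" ] , atom ;          (* "not" only with allow_not *)
    atom    = identifier | "true" | "false" | "(" , expr , ")" ;

Operator names are case-insensitive; ``and`` binds tighter than ``or``.
``not`` and the constants are accepted only when parsing regulatory rules
(``allow_not=True``); plain GPRs use and/or alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import reduce as _reduce
from typing import Callable, Iterable, Mapping, Sequence

from .errors import GPRParseError

__all__ = [
    "GeneRef",
    "And",
    "Or",
    "Not",
    "Const",
    "GPRExpression",
    "parse_gpr",
    "parse_bool_expr",
    "unparse",
    "eval_boolean",
    "eval_algebraic",
    "reaction_fold_to_bounds",
    "or_sum",
]


# ---------------------------------------------------------------------------
# Expression tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRef:
    gene: str


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


@dataclass(frozen=True)
class Not:
    child: object


@dataclass(frozen=True)
class Const:
    value: bool


Node = object  # GeneRef | And | Or | Not | Const


@dataclass(frozen=True)
class GPRExpression:
    """A parsed rule: expression tree plus the original string."""

    root: Node
    original_string: str

    def genes(self) -> frozenset[str]:
        return frozenset(_collect_genes(self.root))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.original_string


def _collect_genes(node: Node) -> Iterable[str]:
    if isinstance(node, GeneRef):
        yield node.gene
    elif isinstance(node, (And, Or)):
        for c in node.children:
            yield from _collect_genes(c)
    elif isinstance(node, Not):
        yield from _collect_genes(node.child)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(\()|(\))|(&{1,2}|\|{1,2}|!)|([^\s()&|!]+))")

_AND_WORDS = {"and", "&", "&&"}
_OR_WORDS = {"or", "|", "||"}
_NOT_WORDS = {"not", "!"}
_TRUE_WORDS = {"true", "on", "1"}
_FALSE_WORDS = {"false", "off", "0"}


def _tokenize(rule: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None or m.end() == pos:
            break
        lparen, rparen, op, word = m.groups()
        tok = lparen or rparen or op or word
        tok_start = m.end() - len(tok)
        tokens.append((tok, tok_start))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, int]], source: str, allow_not: bool):
        self.tokens = tokens
        self.source = source
        self.allow_not = allow_not
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, len(self.source))

    def _next(self):
        tok = self._peek()
        self.i += 1
        return tok

    def parse(self) -> Node:
        if not self.tokens:
            raise GPRParseError("empty rule")
        node = self.expr()
        tok, pos = self._peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token '{tok}'", pos)
        return node

    def expr(self) -> Node:
        parts = [self.term()]
        while self._peek()[0] is not None and self._peek()[0].lower() in _OR_WORDS:
            self._next()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def term(self) -> Node:
        parts = [self.factor()]
        while self._peek()[0] is not None and self._peek()[0].lower() in _AND_WORDS:
            self._next()
            parts.append(self.factor())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def factor(self) -> Node:
        tok, pos = self._peek()
        if tok is not None and tok.lower() in _NOT_WORDS:
            if not self.allow_not:
                raise GPRParseError("'not' is not allowed in GPR rules", pos)
            self._next()
            return Not(self.factor())
        return self.atom()

    def atom(self) -> Node:
        tok, pos = self._next()
        if tok is None:
            raise GPRParseError("dangling operator: expected gene or '('", pos)
        if tok == "(":
            node = self.expr()
            nxt, npos = self._next()
            if nxt != ")":
                raise GPRParseError("unbalanced parentheses", pos)
            return node
        if tok == ")":
            raise GPRParseError("unbalanced parentheses", pos)
        low = tok.lower()
        if low in _AND_WORDS | _OR_WORDS:
            raise GPRParseError(f"dangling operator '{tok}'", pos)
        if self.allow_not and low in _TRUE_WORDS:
            return Const(True)
        if self.allow_not and low in _FALSE_WORDS:
            return Const(False)
        return GeneRef(tok)


def parse_gpr(rule: str) -> GPRExpression:
    """Parse a GPR rule string into an expression tree.

    Operators ``and``/``AND``/``&`` and ``or``/``OR``/``|`` with parentheses;
    ``and`` binds tighter than ``or``. Raises :class:`GPRParseError` (with
    character position) on unbalanced parentheses, dangling operators, or an
    empty rule.
    """
    root = _Parser(_tokenize(rule), rule, allow_not=False).parse()
    return GPRExpression(root=root, original_string=rule)


def parse_bool_expr(rule: str) -> GPRExpression:
    """Parse a regulatory Boolean expression: like a GPR, plus ``not`` and
    the constants ``true``/``false``."""
    root = _Parser(_tokenize(rule), rule, allow_not=True).parse()
    return GPRExpression(root=root, original_string=rule)


def unparse(expr: GPRExpression | Node) -> str:
    """Render a tree back to a canonical rule string (fully parenthesised
    below the top level, lower-case operators)."""
    node = expr.root if isinstance(expr, GPRExpression) else expr

    def render(n: Node, parent: str) -> str:
        if isinstance(n, GeneRef):
            return n.gene
        if isinstance(n, Const):
            return "true" if n.value else "false"
        if isinstance(n, Not):
            return f"not {render(n.child, 'not')}"
        op = "and" if isinstance(n, And) else "or"
        s = f" {op} ".join(render(c, op) for c in n.children)
        return f"({s})" if parent != "top" else s

    return render(node, "top")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def eval_boolean(expr: GPRExpression | Node, deleted: Iterable[str] = ()) -> bool:
    """Evaluate a rule with the genes in ``deleted`` set false and all other
    leaves true. A false result means the catalysing reaction is disabled."""
    deleted = frozenset(deleted)
    node = expr.root if isinstance(expr, GPRExpression) else expr

    def ev(n: Node) -> bool:
        if isinstance(n, GeneRef):
            return n.gene not in deleted
        if isinstance(n, Const):
            return n.value
        if isinstance(n, Not):
            return not ev(n.child)
        if isinstance(n, And):
            return all(ev(c) for c in n.children)
        return any(ev(c) for c in n.children)

    return ev(node)


def or_sum(values: Sequence[float]) -> float:
    """Additive OR reduction: isozymes pool their capacity."""
    return float(sum(values))


def eval_algebraic(
    expr: GPRExpression | Node,
    levels: Mapping[str, float],
    and_op: Callable[[Sequence[float]], float] = min,
    or_op: Callable[[Sequence[float]], float] = max,
) -> float:
    """Evaluate a rule with gene identifiers replaced by expression folds.

    ``levels`` maps gene id -> fold gamma_g >= 0 (1 = wild type, 0 = deleted);
    genes absent from the map default to 1. AND/OR nodes reduce their
    children with ``and_op``/``or_op`` (defaults min/max), bottom-up, yielding
    the reaction-level fold gamma_r.
    """
    node = expr.root if isinstance(expr, GPRExpression) else expr

    def ev(n: Node) -> float:
        if isinstance(n, GeneRef):
            level = float(levels.get(n.gene, 1.0))
            if level < 0:
                raise ValueError(f"negative expression level for gene '{n.gene}'")
            return level
        if isinstance(n, Const):
            return 1.0 if n.value else 0.0
        if isinstance(n, Not):
            raise ValueError("algebraic evaluation is undefined for 'not'")
        vals = [ev(c) for c in n.children]
        return float(and_op(vals) if isinstance(n, And) else or_op(vals))

    return ev(node)


def reaction_fold_to_bounds(
    gamma_r: float, reference_flux: float, lb: float, ub: float
) -> tuple[float, float]:
    """Translate a reaction-level expression fold into new flux bounds.

    ``reference_flux`` w_r is the wild-type flux (from pFBA). The encoding:

    * gamma = 1: bounds unchanged.
    * gamma = 0: knockout, (0, 0).
    * gamma < 1 (under-expression): flux capped at gamma*w_r, keeping the
      wild-type direction — (0, gamma*w) for w > 0, (gamma*w, 0) for w < 0,
      (0, 0) when w = 0.
    * gamma > 1 (over-expression): force flux at least gamma*w_r in the
      wild-type direction, clamped into the original bounds; when w = 0 the
      bounds are left unchanged (there is no direction to push an unused
      reaction; decoders log this no-op).
    """
    if gamma_r < 0:
        raise ValueError(f"negative reaction fold {gamma_r}")
    if gamma_r == 1.0:
        return (lb, ub)
    if gamma_r == 0.0:
        return (0.0, 0.0)
    w = reference_flux
    if gamma_r < 1.0:
        if w > 0:
            return (0.0, gamma_r * w)
        if w < 0:
            return (gamma_r * w, 0.0)
        return (0.0, 0.0)
    # gamma > 1
    if w > 0:
        return (min(gamma_r * w, ub), ub)
    if w < 0:
        return (lb, max(gamma_r * w, lb))
    return (lb, ub)
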