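"""Prefix-notation constraint language for common data elements.

Constraint rules on CDEs are written as parenthesized prefix-notation
forms, e.g. ``(Required CDE40 CDE41)`` or
``(IF (= CDE31.unit_of_measure 'm') (/ CDE30 CDE31 CDE31) (* (/ CDE30 CDE31 CDE31) 10000))``.

The language has four operator classes:

* arithmetic  ``+ - * /``        — n-ary (>=2), left-folding
* relational  ``= < > <= >= !=`` — chained pairwise (``!=`` binary only)
* logical     ``and or not``     — three-valued, short-circuiting
* forms       ``IF Required Ordered`` — special forms

Evaluation uses Kleene three-valued logic: any comparison with a NULL
operand yields *indeterminate*, which propagates through ``and``/``or``/
``not`` and through the ``IF`` condition.  This matters clinically: a
skip-logic condition over an unanswered question must neither fire nor
pass silently.
"""

from __future__ import annotations

import datetime as _dt
import enum
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

__all__ = [
    "RuleKind",
    "ValueTag",
    "Value",
    "NULL",
    "TRUE",
    "FALSE",
    "INDETERMINATE",
    "Literal",
    "CdeRef",
    "Apply",
    "Expression",
    "EvalContext",
    "RuleSyntaxError",
    "RuleEvalError",
    "UnboundRefError",
    "OPERATORS",
    "parse_rule",
    "unparse",
    "evaluate",
    "collect_refs",
    "classify_rule",
    "dependent_target",
]


class RuleKind(str, enum.Enum):
    """Constraint kinds a rule expression can encode."""

    OPERATED = "Operated"
    REQUIRED = "Required"
    DEPENDENT = "Dependent"
    ORDERED = "Ordered"
    DICTIONARY = "Dictionary"


# ---------------------------------------------------------------------------
# Runtime values
# ---------------------------------------------------------------------------


class ValueTag(str, enum.Enum):
    NUMBER = "number"
    TEXT = "text"
    BOOLEAN = "boolean"
    DATE = "date"
    TIME = "time"
    DATETIME = "datetime"
    NULL = "null"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Value:
    """A typed runtime value; ``unit`` only ever accompanies numbers."""

    tag: ValueTag
    payload: object = None
    unit: Optional[str] = None

    def is_null(self) -> bool:
        return self.tag is ValueTag.NULL

    def is_indeterminate(self) -> bool:
        return self.tag is ValueTag.INDETERMINATE

    def is_missing(self) -> bool:
        return self.tag in (ValueTag.NULL, ValueTag.INDETERMINATE)

    @staticmethod
    def number(x: float, unit: Optional[str] = None) -> "Value":
        return Value(ValueTag.NUMBER, float(x), unit)

    @staticmethod
    def text(s: str) -> "Value":
        return Value(ValueTag.TEXT, s)

    @staticmethod
    def boolean(b: bool) -> "Value":
        return TRUE if b else FALSE

    @staticmethod
    def date(d: _dt.date) -> "Value":
        return Value(ValueTag.DATE, d)

    @staticmethod
    def time(t: _dt.time) -> "Value":
        return Value(ValueTag.TIME, t)

    @staticmethod
    def datetime(t: _dt.datetime) -> "Value":
        return Value(ValueTag.DATETIME, t)


NULL = Value(ValueTag.NULL)
TRUE = Value(ValueTag.BOOLEAN, True)
FALSE = Value(ValueTag.BOOLEAN, False)
INDETERMINATE = Value(ValueTag.INDETERMINATE)


# ---------------------------------------------------------------------------
# Expression tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Literal:
    value: Value


@dataclass(frozen=True)
class CdeRef:
    """Reference to a CDE by id, optionally to its ``unit_of_measure``."""

    cde_id: str
    attribute: Optional[str] = None


@dataclass(frozen=True)
class Apply:
    operator: str
    args: tuple = field(default_factory=tuple)


Expression = Union[Literal, CdeRef, Apply]


class RuleSyntaxError(ValueError):
    """Raised for lexical, structural, or arity errors in a rule text."""


class RuleEvalError(RuntimeError):
    """Raised for runtime evaluation failures (type mismatch, /0, ...)."""


class UnboundRefError(RuleEvalError):
    """A referenced CDE id has no binding in strict mode."""


# ---------------------------------------------------------------------------
# Operator table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Operator:
    symbol: str
    klass: str  # arithmetic | relational | logical | form
    min_arity: int
    max_arity: Optional[int]  # None = unbounded


OPERATORS = {
    op.symbol: op
    for op in [
        Operator("+", "arithmetic", 2, None),
        Operator("-", "arithmetic", 2, None),
        Operator("*", "arithmetic", 2, None),
        Operator("/", "arithmetic", 2, None),
        Operator("=", "relational", 2, None),
        Operator("<", "relational", 2, None),
        Operator(">", "relational", 2, None),
        Operator("<=", "relational", 2, None),
        Operator(">=", "relational", 2, None),
        Operator("!=", "relational", 2, 2),
        Operator("and", "logical", 2, None),
        Operator("or", "logical", 2, None),
        Operator("not", "logical", 1, 1),
        Operator("IF", "form", 3, 3),
        Operator("Required", "form", 1, None),
        Operator("Ordered", "form", 2, None),
    ]
}

IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_:.\-]*\Z")
ATTR_SUFFIX = ".unit_of_measure"

_TOKEN_RE = re.compile(
    r"""
      (?P<ws>[\s,]+)
    | (?P<lparen>\()
    | (?P<rparen>\))
    | (?P<string>'[^']*')
    | (?P<number>-?\d+(?:\.\d+)?(?![A-Za-z0-9_:.\-]))
    | (?P<bang>!\s*=)
    | (?P<symbol>[^\s(),']+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> Iterator[tuple]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise RuleSyntaxError(f"bad character at offset {pos}: {text[pos]!r}")
        pos = m.end()
        kind = m.lastgroup
        if kind == "ws":
            continue
        tok = m.group()
        if kind == "bang":
            tok = "!="
        yield kind, tok


def parse_rule(text: str) -> Expression:
    """Parse a single parenthesized prefix-notation form.

    Commas are whitespace; string literals use single quotes; ``!=`` may be
    printed with an interior space (``! =``).  Arity violations are raised
    at parse time.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        raise RuleSyntaxError("empty rule text")
    expr, rest = _parse_expr(tokens)
    if rest:
        raise RuleSyntaxError(f"trailing tokens after expression: {rest[0][1]!r}")
    if not isinstance(expr, Apply):
        raise RuleSyntaxError("a rule must be a parenthesized form")
    return expr


def _parse_expr(tokens: list) -> tuple:
    kind, tok = tokens[0]
    rest = tokens[1:]
    if kind == "lparen":
        if not rest:
            raise RuleSyntaxError("unbalanced parentheses: missing operator")
        head_kind, head = rest[0]
        if head_kind not in ("symbol", "bang") or head not in OPERATORS:
            raise RuleSyntaxError(f"unknown operator: {head!r}")
        rest = rest[1:]
        args = []
        while True:
            if not rest:
                raise RuleSyntaxError("unbalanced parentheses: missing ')'")
            if rest[0][0] == "rparen":
                rest = rest[1:]
                break
            arg, rest = _parse_expr(rest)
            args.append(arg)
        return _make_apply(head, tuple(args)), rest
    if kind == "rparen":
        raise RuleSyntaxError("unexpected ')'")
    return _parse_atom(kind, tok), rest


def _parse_atom(kind: str, tok: str) -> Expression:
    if kind == "string":
        return Literal(Value.text(tok[1:-1]))
    if kind == "number":
        return Literal(Value.number(float(tok)))
    if kind == "symbol":
        if tok == "NULL":
            return Literal(NULL)
        if tok in OPERATORS:
            raise RuleSyntaxError(f"operator {tok!r} used as an atom")
        ident = tok
        attribute = None
        if ident.endswith(ATTR_SUFFIX):
            ident, attribute = ident[: -len(ATTR_SUFFIX)], "unit_of_measure"
        if not IDENT_RE.match(ident):
            raise RuleSyntaxError(f"malformed identifier: {tok!r}")
        return CdeRef(ident, attribute)
    raise RuleSyntaxError(f"unexpected token {tok!r}")


def _make_apply(operator: str, args: tuple) -> Apply:
    op = OPERATORS[operator]
    n = len(args)
    if n < op.min_arity or (op.max_arity is not None and n > op.max_arity):
        raise RuleSyntaxError(
            f"operator {operator!r} takes "
            f"{op.min_arity}{'+' if op.max_arity is None else f'..{op.max_arity}'}"
            f" arguments, got {n}"
        )
    if operator in ("Required", "Ordered"):
        for a in args:
            if not isinstance(a, CdeRef) or a.attribute is not None:
                raise RuleSyntaxError(f"{operator} arguments must be plain CDE references")
    return Apply(operator, args)


def unparse(expr: Expression) -> str:
    """Canonical single-space text; ``parse_rule(unparse(e))`` equals ``e``."""
    if isinstance(expr, Literal):
        v = expr.value
        if v.tag is ValueTag.NULL:
            return "NULL"
        if v.tag is ValueTag.TEXT:
            return f"'{v.payload}'"
        if v.tag is ValueTag.NUMBER:
            f = float(v.payload)
            return str(int(f)) if f.is_integer() else repr(f)
        raise RuleSyntaxError(f"literal of tag {v.tag} has no surface syntax")
    if isinstance(expr, CdeRef):
        return expr.cde_id + (ATTR_SUFFIX if expr.attribute else "")
    return "(" + " ".join([expr.operator] + [unparse(a) for a in expr.args]) + ")"


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalContext:
    """Bindings of CDE ids (and their units) to runtime values.

    In *strict* mode every referenced id must be bound (NULL counts as
    bound); *lenient* mode maps unbound references to NULL and records a
    warning.
    """

    bindings: dict = field(default_factory=dict)
    attributes: dict = field(default_factory=dict)  # (id, "unit_of_measure") -> str
    mode: str = "strict"
    warnings: list = field(default_factory=list)

    def bind(self, cde_id: str, value: Value) -> None:
        self.bindings[cde_id] = value
        if value.tag is ValueTag.NUMBER and value.unit is not None:
            self.attributes.setdefault((cde_id, "unit_of_measure"), value.unit)

    def bind_unit(self, cde_id: str, unit: str) -> None:
        self.attributes[(cde_id, "unit_of_measure")] = unit

    def lookup(self, ref: CdeRef) -> Value:
        if ref.attribute is not None:
            key = (ref.cde_id, ref.attribute)
            if key in self.attributes:
                return Value.text(self.attributes[key])
            if self.mode == "strict":
                raise UnboundRefError(f"no {ref.attribute} bound for {ref.cde_id}")
            self.warnings.append(f"unbound attribute {ref.cde_id}.{ref.attribute} -> NULL")
            return NULL
        if ref.cde_id in self.bindings:
            return self.bindings[ref.cde_id]
        if self.mode == "strict":
            raise UnboundRefError(f"unbound CDE reference: {ref.cde_id}")
        self.warnings.append(f"unbound reference {ref.cde_id} -> NULL")
        return NULL


_CHRONO_TAGS = (ValueTag.DATE, ValueTag.TIME, ValueTag.DATETIME)


def evaluate(expr: Expression, ctx: EvalContext) -> Value:
    """Evaluate an expression against a context (three-valued semantics)."""
    if isinstance(expr, Literal):
        return expr.value
    if isinstance(expr, CdeRef):
        return ctx.lookup(expr)
    op = OPERATORS[expr.operator]
    if op.klass == "arithmetic":
        return _eval_arith(expr, ctx)
    if op.klass == "relational":
        return _eval_relational(expr, ctx)
    if op.klass == "logical":
        return _eval_logical(expr, ctx)
    if expr.operator == "IF":
        cond = evaluate(expr.args[0], ctx)
        truth = _truth(cond)
        if truth is None:
            return INDETERMINATE
        return evaluate(expr.args[1] if truth else expr.args[2], ctx)
    raise RuleEvalError(f"form {expr.operator!r} is not value-evaluable")


def _truth(v: Value):
    if v.tag is ValueTag.BOOLEAN:
        return bool(v.payload)
    if v.is_missing():
        return None
    raise RuleEvalError(f"condition is not boolean: {v.tag.value}")


def _eval_arith(expr: Apply, ctx: EvalContext) -> Value:
    vals = [evaluate(a, ctx) for a in expr.args]
    if any(v.is_missing() for v in vals):
        return INDETERMINATE
    nums = []
    for v in vals:
        if v.tag is not ValueTag.NUMBER:
            raise RuleEvalError(
                f"arithmetic {expr.operator!r} applied to {v.tag.value} operand"
            )
        nums.append(float(v.payload))
    acc = nums[0]
    for x in nums[1:]:
        if expr.operator == "+":
            acc = acc + x
        elif expr.operator == "-":
            acc = acc - x
        elif expr.operator == "*":
            acc = acc * x
        else:
            if x == 0:
                raise RuleEvalError("division by zero")
            acc = acc / x
    return Value.number(acc)


def _compare(op: str, a: Value, b: Value) -> Value:
    if a.is_missing() or b.is_missing():
        return INDETERMINATE
    if op in ("=", "!="):
        if a.tag is ValueTag.NUMBER and b.tag is ValueTag.NUMBER:
            eq = float(a.payload) == float(b.payload)
        elif a.tag is not b.tag:
            eq = False
        else:
            eq = a.payload == b.payload
        return Value.boolean(eq if op == "=" else not eq)
    # ordering
    if a.tag is ValueTag.NUMBER and b.tag is ValueTag.NUMBER:
        x, y = float(a.payload), float(b.payload)
    elif a.tag is b.tag and a.tag in _CHRONO_TAGS:
        x, y = a.payload, b.payload
    elif a.tag is b.tag and a.tag is ValueTag.TEXT:
        raise RuleEvalError("ordering comparison applied to text operands")
    else:
        raise RuleEvalError(
            f"cannot order {a.tag.value} against {b.tag.value}"
        )
    if op == "<":
        return Value.boolean(x < y)
    if op == ">":
        return Value.boolean(x > y)
    if op == "<=":
        return Value.boolean(x <= y)
    return Value.boolean(x >= y)


def _eval_relational(expr: Apply, ctx: EvalContext) -> Value:
    vals = [evaluate(a, ctx) for a in expr.args]
    result = TRUE
    for a, b in zip(vals, vals[1:]):
        r = _compare(expr.operator, a, b)
        if r is FALSE:
            return FALSE
        if r.is_indeterminate():
            result = INDETERMINATE
    return result


def _eval_logical(expr: Apply, ctx: EvalContext) -> Value:
    if expr.operator == "not":
        v = _truth(evaluate(expr.args[0], ctx))
        return INDETERMINATE if v is None else Value.boolean(not v)
    saw_indeterminate = False
    for a in expr.args:
        t = _truth(evaluate(a, ctx))
        if t is None:
            saw_indeterminate = True
        elif expr.operator == "and" and not t:
            return FALSE
        elif expr.operator == "or" and t:
            return TRUE
    if saw_indeterminate:
        return INDETERMINATE
    return TRUE if expr.operator == "and" else FALSE


# ---------------------------------------------------------------------------
# Static analysis
# ---------------------------------------------------------------------------


def collect_refs(expr: Expression) -> list:
    """All CDE references, depth-first left-to-right, duplicates kept.

    Returns ``(cde_id, attribute)`` pairs; ``attribute`` is None for plain
    value references and ``"unit_of_measure"`` for attribute access.
    """
    out: list = []
    _collect(expr, out)
    return out


def _collect(expr: Expression, out: list) -> None:
    if isinstance(expr, CdeRef):
        out.append((expr.cde_id, expr.attribute))
    elif isinstance(expr, Apply):
        for a in expr.args:
            _collect(a, out)


def _is_boolean_headed(expr: Expression) -> bool:
    return isinstance(expr, Apply) and OPERATORS[expr.operator].klass in (
        "relational",
        "logical",
    )


def dependent_target(expr: Expression) -> Optional[str]:
    """The governed CDE id if ``expr`` is a dependent form, else None.

    A dependent rule has the exact shape ``(IF <boolean-expr> <ref> NULL)``:
    when the condition holds the referenced CDE is forced to null.
    """
    if (
        isinstance(expr, Apply)
        and expr.operator == "IF"
        and _is_boolean_headed(expr.args[0])
        and isinstance(expr.args[1], CdeRef)
        and expr.args[1].attribute is None
        and isinstance(expr.args[2], Literal)
        and expr.args[2].value.is_null()
    ):
        return expr.args[1].cde_id
    return None


def classify_rule(expr: Expression) -> RuleKind:
    """Classify an expression into its constraint kind.

    Required and Ordered are recognized by their head symbol; the dependent
    shape ``(IF <boolean-expr> <ref> NULL)`` is Dependent; everything else
    is Operated (boolean-valued forms act as assertions, numeric-valued
    ones as derivations).
    """
    if isinstance(expr, Apply):
        if expr.operator == "Required":
            return RuleKind.REQUIRED
        if expr.operator == "Ordered":
            return RuleKind.ORDERED
        if dependent_target(expr) is not None:
            return RuleKind.DEPENDENT
    return RuleKind.OPERATED
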