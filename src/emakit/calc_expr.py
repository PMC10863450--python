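"""Calculated-variables expression language.

Study designers attach named expressions ("calculated variables") to an
intervention to derive feedback values and timing conditions at runtime:
arithmetic over item variables plus five cohort aggregation functions.

Grammar (standard arithmetic)::

    expr   := term  (("+" | "-") term)*
    term   := unary (("*" | "/") unary)*
    unary  := "-" unary | power
    power  := atom ("^" unary)?          # right-associative
    atom   := NUMBER | IDENT | IDENT "(" args ")" | "(" expr ")"

so ``*``/``/`` bind tighter than ``+``/``-``, ``^`` tighter still and
right-associative (``2^3^2 == 2^(3^2)``), and unary minus binds looser than
``^`` (``-2^2 == -(2^2)``).

Aggregation functions (cohort scope):

``SUM_ANS(N)``
    sum of all recorded responses to variable ``N``.
``NUM_PS(N)``
    number of participants assigned to the intervention holding ``N``
    (assignment is context, not answers: with 3 assigned it returns 3 even
    if fewer answered).
``NUM_P_ANS(N)``
    number of distinct participants who answered ``N``.
``MODE_ANS(N)``
    most frequent response value; if the maximal frequency is shared by two
    or more distinct values ("no mode"), the mean of all answers.
``COUNT_ANS(VAR, VAL)``
    number of responses to ``VAR`` equal to ``VAL``.

A plain variable reference resolves to the scoped participant's most recent
answer. A reference with no recorded answer is *undefined*, and
undefinedness propagates: any undefined sub-expression makes the whole
expression undefined (:data:`UNDEFINED`), so dependent scheduling rules
simply do not fire. Division by zero is an evaluation error, never NaN.
Non-numeric answers are excluded from all aggregations; the exclusion count
is tallied on the context.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Union


class ExprSyntaxError(ValueError):
    """Source text does not parse; carries the character position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


class EvaluationError(ValueError):
    """Hard evaluation failure: division by zero, unknown variable scope."""


class _Undefined:
    _instance: Optional["_Undefined"] = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


#: Sentinel result of an expression whose inputs are missing.
UNDEFINED = _Undefined()

Result = Union[float, _Undefined]


# --- AST ---------------------------------------------------------------------

@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Neg:
    child: "ExprNode"


@dataclass(frozen=True)
class BinOp:
    op: str  # one of + - * / ^
    left: "ExprNode"
    right: "ExprNode"


@dataclass(frozen=True)
class Call:
    func: str
    args: tuple["ExprNode", ...]


ExprNode = Union[Num, Var, Neg, BinOp, Call]

FUNCTION_ARITY = {
    "SUM_ANS": 1,
    "NUM_PS": 1,
    "NUM_P_ANS": 1,
    "MODE_ANS": 1,
    "COUNT_ANS": 2,
}


# --- tokenizer / recursive-descent parser ------------------------------------

_OPS = set("+-*/^(),")


def _tokenize(source: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(source)
    while i < n:
        c = source[i]
        if c.isspace():
            i += 1
        elif c in _OPS:
            tokens.append(("op", c, i))
            i += 1
        elif c.isdigit() or (c == "." and i + 1 < n and source[i + 1].isdigit()):
            j = i
            while j < n and (source[j].isdigit() or source[j] == "."):
                j += 1
            text = source[i:j]
            if text.count(".") > 1:
                raise ExprSyntaxError(f"malformed number {text!r}", i)
            tokens.append(("num", text, i))
            i = j
        elif c.isalpha() or c == "_":
            j = i
            while j < n and (source[j].isalnum() or source[j] == "_"):
                j += 1
            tokens.append(("ident", source[i:j], i))
            i = j
        else:
            raise ExprSyntaxError(f"unexpected character {c!r}", i)
    tokens.append(("end", "", n))
    return tokens


class _Parser:
    def __init__(self, source: str):
        self.source = source
        self.tokens = _tokenize(source)
        self.pos = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.pos]

    def take(self) -> tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect_op(self, op: str) -> None:
        kind, text, at = self.peek()
        if kind != "op" or text != op:
            raise ExprSyntaxError(f"expected {op!r}, found {text or 'end'!r}", at)
        self.take()

    def parse(self) -> ExprNode:
        node = self.expr()
        kind, text, at = self.peek()
        if kind != "end":
            raise ExprSyntaxError(f"unexpected trailing {text!r}", at)
        return node

    def expr(self) -> ExprNode:
        node = self.term()
        while self.peek()[:2] in (("op", "+"), ("op", "-")):
            op = self.take()[1]
            node = BinOp(op, node, self.term())
        return node

    def term(self) -> ExprNode:
        node = self.unary()
        while self.peek()[:2] in (("op", "*"), ("op", "/")):
            op = self.take()[1]
            node = BinOp(op, node, self.unary())
        return node

    def unary(self) -> ExprNode:
        if self.peek()[:2] == ("op", "-"):
            self.take()
            return Neg(self.unary())
        return self.power()

    def power(self) -> ExprNode:
        base = self.atom()
        if self.peek()[:2] == ("op", "^"):
            self.take()
            # right-associative; exponent may carry a unary minus
            return BinOp("^", base, self.unary())
        return base

    def atom(self) -> ExprNode:
        kind, text, at = self.take()
        if kind == "num":
            return Num(float(text))
        if kind == "ident":
            if self.peek()[:2] == ("op", "("):
                return self.call(text, at)
            return Var(text)
        if kind == "op" and text == "(":
            node = self.expr()
            self.expect_op(")")
            return node
        raise ExprSyntaxError(f"unexpected {text or 'end'!r}", at)

    def call(self, name: str, at: int) -> ExprNode:
        if name not in FUNCTION_ARITY:
            raise ExprSyntaxError(f"unknown function {name!r}", at)
        self.expect_op("(")
        args: list[ExprNode] = []
        if self.peek()[:2] != ("op", ")"):
            args.append(self.expr())
            while self.peek()[:2] == ("op", ","):
                self.take()
                args.append(self.expr())
        self.expect_op(")")
        arity = FUNCTION_ARITY[name]
        if len(args) != arity:
            raise ExprSyntaxError(
                f"{name} takes {arity} argument(s), got {len(args)}", at)
        if not isinstance(args[0], Var):
            raise ExprSyntaxError(
                f"first argument of {name} must be a variable name", at)
        if name == "COUNT_ANS" and not isinstance(args[1], (Num, Var)):
            raise ExprSyntaxError(
                "second argument of COUNT_ANS must be a literal or variable", at)
        return Call(name, tuple(args))


def parse(source: str) -> ExprNode:
    """Parse expression source text into an AST."""
    if not source or not source.strip():
        raise ExprSyntaxError("empty expression", 0)
    return _Parser(source).parse()


def referenced_variables(ast: ExprNode) -> set[tuple[str, bool]]:
    """All variable names in the AST, flagged True when aggregated over."""
    out: set[tuple[str, bool]] = set()

    def walk(node: ExprNode, inside_call: bool) -> None:
        if isinstance(node, Var):
            out.add((node.name, inside_call))
        elif isinstance(node, Neg):
            walk(node.child, inside_call)
        elif isinstance(node, BinOp):
            walk(node.left, inside_call)
            walk(node.right, inside_call)
        elif isinstance(node, Call):
            for arg in node.args:
                walk(arg, True)

    walk(ast, False)
    return out


# --- evaluation context ------------------------------------------------------

Answer = tuple[str, int, object]  # (participant_id, time minutes, value)


@dataclass
class EvaluationContext:
    """Answer histories plus cohort assignment, the data aggregations read.

    ``assigned_participants`` is the intervention's assignment count — it is
    context, not derived from answers, so NUM_PS reports 3 assigned even
    when only 2 answered. ``scope`` selects the participant whose latest
    answer a bare variable reference resolves to; aggregation functions
    always read the whole cohort regardless of scope.
    """

    assigned_participants: int = 0
    answers: dict[str, list[Answer]] = field(default_factory=dict)
    scope: Optional[str] = None  # participant id, or None for cohort scope
    derived: dict[str, ExprNode] = field(default_factory=dict)
    excluded_non_numeric: int = 0

    def record(self, participant_id: str, time: int, variable: str,
               value: object) -> None:
        self.answers.setdefault(variable, []).append(
            (participant_id, time, value))

    def numeric_answers(self, variable: str) -> list[tuple[str, int, float]]:
        """Cohort answers to a variable, non-numeric values excluded."""
        out = []
        for pid, t, v in self.answers.get(variable, []):
            x = _as_number(v)
            if x is None:
                self.excluded_non_numeric += 1
            else:
                out.append((pid, t, x))
        return out

    def for_participant(self, participant_id: str) -> "EvaluationContext":
        return EvaluationContext(
            assigned_participants=self.assigned_participants,
            answers=self.answers, scope=participant_id, derived=self.derived)


def _as_number(value: object) -> Optional[float]:
    if isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        return float(value) if math.isfinite(value) else None
    if isinstance(value, str):
        try:
            x = float(value)
        except ValueError:
            return None
        return x if math.isfinite(x) else None
    return None


def _values_equal(a: float, b: float) -> bool:
    # exact on integers; tolerant on non-integer answers
    if float(a).is_integer() and float(b).is_integer():
        return a == b
    return math.isclose(a, b, rel_tol=1e-9, abs_tol=0.0)


# --- evaluator ---------------------------------------------------------------

def evaluate(ast: ExprNode, ctx: EvaluationContext,
             _resolving: Optional[frozenset] = None) -> Result:
    """Evaluate an AST against a context; pure given (AST, context)."""
    if isinstance(ast, Num):
        return ast.value
    if isinstance(ast, Var):
        return _resolve_var(ast.name, ctx, _resolving or frozenset())
    if isinstance(ast, Neg):
        v = evaluate(ast.child, ctx, _resolving)
        return UNDEFINED if v is UNDEFINED else -v
    if isinstance(ast, BinOp):
        # undefined short-circuits left to right: once an operand is
        # undefined the whole expression is, and the remainder (which might
        # e.g. divide by zero) is never evaluated
        left = evaluate(ast.left, ctx, _resolving)
        if left is UNDEFINED:
            return UNDEFINED
        right = evaluate(ast.right, ctx, _resolving)
        if right is UNDEFINED:
            return UNDEFINED
        return _apply_op(ast.op, left, right)
    if isinstance(ast, Call):
        return _apply_function(ast, ctx)
    raise TypeError(f"not an expression node: {ast!r}")


def _apply_op(op: str, left: float, right: float) -> float:
    if op == "+":
        return left + right
    if op == "-":
        return left - right
    if op == "*":
        return left * right
    if op == "/":
        if right == 0:
            raise EvaluationError("division by zero")
        return left / right
    if op == "^":
        try:
            result = left ** right
        except (OverflowError, ZeroDivisionError) as exc:
            raise EvaluationError(f"exponentiation failed: {exc}")
        if isinstance(result, complex):
            raise EvaluationError(
                "fractional power of a negative base is undefined over the reals")
        return result
    raise EvaluationError(f"unknown operator {op!r}")


def _resolve_var(name: str, ctx: EvaluationContext,
                 resolving: frozenset) -> Result:
    if name in ctx.answers:
        if ctx.scope is None:
            raise EvaluationError(
                f"bare reference to {name!r} needs participant scope; "
                "aggregate with SUM_ANS/MODE_ANS/... in cohort scope")
        mine = [(t, i, v) for i, (pid, t, v) in enumerate(ctx.answers[name])
                if pid == ctx.scope]
        if not mine:
            return UNDEFINED
        # most recent answer; insertion order breaks same-minute ties
        _, _, value = max(mine)
        x = _as_number(value)
        if x is None:
            ctx.excluded_non_numeric += 1
            return UNDEFINED
        return x
    if name in ctx.derived:
        if name in resolving:
            raise EvaluationError(f"cyclic calculated variable {name!r}")
        return evaluate(ctx.derived[name], ctx, resolving | {name})
    return UNDEFINED


def _apply_function(call: Call, ctx: EvaluationContext) -> Result:
    var = call.args[0]
    assert isinstance(var, Var)
    values = ctx.numeric_answers(var.name)

    if call.func == "NUM_PS":
        return float(ctx.assigned_participants)
    if call.func == "NUM_P_ANS":
        return float(len({pid for pid, _, _ in values}))
    if call.func == "SUM_ANS":
        return float(sum(v for _, _, v in values))
    if call.func == "MODE_ANS":
        return _mode_or_mean([v for _, _, v in values])
    if call.func == "COUNT_ANS":
        target = evaluate(call.args[1], ctx)
        if target is UNDEFINED:
            return UNDEFINED
        return float(sum(1 for _, _, v in values if _values_equal(v, target)))
    raise EvaluationError(f"unknown function {call.func!r}")


def _mode_or_mean(values: list[float]) -> Result:
    if not values:
        return UNDEFINED
    counts = Counter(values)
    top = max(counts.values())
    modal = [v for v, c in counts.items() if c == top]
    if len(modal) == 1:
        return modal[0]
    return float(sum(values) / len(values))


def evaluate_source(source: str, ctx: EvaluationContext) -> Result:
    """Convenience: parse then evaluate."""
    return evaluate(parse(source), ctx)


def three_day_average(variable: str, ctx: EvaluationContext,
                      participant_id: Optional[str] = None) -> Result:
    """Per-participant mean of answers to a daily-repeated variable.

    The canonical use: the same 1–10 mood item asked in three daily
    modules, summarized as one average. Missed days are simply absent, so
    the mean runs over the answers that exist; no answers at all is
    undefined. Computed as the library expression ``SUM_ANS(v)`` over the
    participant's own answers, divided by their answer count.
    """
    pid = participant_id if participant_id is not None else ctx.scope
    if pid is None:
        raise EvaluationError("three_day_average needs a participant scope")
    mine = EvaluationContext(assigned_participants=1, scope=pid)
    for p, t, v in ctx.answers.get(variable, []):
        if p == pid:
            mine.record(p, t, variable, v)
    n = len(mine.numeric_answers(variable))
    if n == 0:
        return UNDEFINED
    total = evaluate_source(f"SUM_ANS({variable})", mine)
    return total / n
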