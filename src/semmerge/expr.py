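"""Infix math expressions for the model dialect.

The grammar is Python-expression compatible and parsed with the stdlib
``ast`` module: numeric literals, variable symbols, unary minus, the binary
operators ``+ - * / ^`` (``**`` also accepted for power), calls to a fixed
function set, and ``piecewise(cond1, val1, ..., default)`` whose conditions
are single comparisons (``< <= > >= ==``) of sub-expressions.

The function set is ``exp, ln, log10, sqrt, abs, min, max`` plus
``pulse(t, period, onset, duration)``, a periodic rectangular pulse helper
(1 inside the window ``onset <= t mod period < onset + duration``, else 0)
used to encode stimulus trains without integrator events.
"""

from __future__ import annotations

import ast as _pyast
import math
from dataclasses import dataclass
from typing import Iterator, Mapping

from .errors import ExpressionError

# function name -> arity (None = variadic, >= 2)
FUNCTIONS: dict[str, int | None] = {
    "exp": 1,
    "ln": 1,
    "log10": 1,
    "sqrt": 1,
    "abs": 1,
    "min": None,
    "max": None,
    "pulse": 4,
}

_COMPARE_OPS = ("<", "<=", ">", ">=", "==")
_BINARY_OPS = ("+", "-", "*", "/", "^")


class Expr:
    """Base class for expression AST nodes (immutable)."""

    __slots__ = ()


@dataclass(frozen=True)
class Num(Expr):
    value: float


@dataclass(frozen=True)
class Sym(Expr):
    name: str


@dataclass(frozen=True)
class Neg(Expr):
    arg: Expr


@dataclass(frozen=True)
class BinOp(Expr):
    op: str  # one of + - * / ^
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Call(Expr):
    fn: str
    args: tuple[Expr, ...]


@dataclass(frozen=True)
class Cond(Expr):
    """A single comparison, only legal as a piecewise condition."""

    op: str  # one of < <= > >= ==
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Piecewise(Expr):
    pieces: tuple[tuple[Cond, Expr], ...]  # at least one (condition, value)
    default: Expr

    def __post_init__(self) -> None:
        if not self.pieces:
            raise ExpressionError("piecewise needs at least one (condition, value) pair")


def pulse(t: float, period: float, onset: float, duration: float) -> float:
    """Rectangular pulse train: 1 when onset <= (t mod period) < onset+duration."""
    phase = t - math.floor(t / period) * period
    return 1.0 if onset <= phase < onset + duration else 0.0


# ---------------------------------------------------------------------------
# parsing

_BIN_MAP = {
    _pyast.Add: "+",
    _pyast.Sub: "-",
    _pyast.Mult: "*",
    _pyast.Div: "/",
    _pyast.Pow: "^",
    _pyast.BitXor: "^",
}
_CMP_MAP = {
    _pyast.Lt: "<",
    _pyast.LtE: "<=",
    _pyast.Gt: ">",
    _pyast.GtE: ">=",
    _pyast.Eq: "==",
}


def parse(text: str) -> Expr:
    """Parse an infix expression string into an :class:`Expr` tree."""
    if not isinstance(text, str) or not text.strip():
        raise ExpressionError("empty expression")
    try:
        tree = _pyast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {text!r}: {exc.msg}") from None
    return _convert(tree.body, text)


def _convert(node: _pyast.AST, src: str) -> Expr:
    if isinstance(node, _pyast.Constant):
        if isinstance(node.value, bool) or not isinstance(node.value, (int, float)):
            raise ExpressionError(f"unsupported literal {node.value!r} in {src!r}")
        return Num(float(node.value))
    if isinstance(node, _pyast.Name):
        return Sym(node.id)
    if isinstance(node, _pyast.UnaryOp):
        if isinstance(node.op, _pyast.USub):
            operand = _convert(node.operand, src)
            # fold "-literal" so negative constants round-trip as Num
            if isinstance(operand, Num):
                return Num(-operand.value)
            return Neg(operand)
        if isinstance(node.op, _pyast.UAdd):
            return _convert(node.operand, src)
        raise ExpressionError(f"unsupported unary operator in {src!r}")
    if isinstance(node, _pyast.BinOp):
        op = _BIN_MAP.get(type(node.op))
        if op is None:
            raise ExpressionError(f"unsupported operator in {src!r}")
        return BinOp(op, _convert(node.left, src), _convert(node.right, src))
    if isinstance(node, _pyast.Call):
        if not isinstance(node.func, _pyast.Name) or node.keywords:
            raise ExpressionError(f"unsupported call form in {src!r}")
        name = node.func.id
        if name == "piecewise":
            return _convert_piecewise(node, src)
        if name not in FUNCTIONS:
            raise ExpressionError(f"unknown function {name!r} in {src!r}")
        args = tuple(_convert(a, src) for a in node.args)
        arity = FUNCTIONS[name]
        if arity is None:
            if len(args) < 2:
                raise ExpressionError(f"{name} needs at least 2 arguments in {src!r}")
        elif len(args) != arity:
            raise ExpressionError(f"{name} takes {arity} argument(s), got {len(args)} in {src!r}")
        return Call(name, args)
    if isinstance(node, _pyast.Compare):
        raise ExpressionError(f"comparison outside piecewise condition in {src!r}")
    raise ExpressionError(f"unsupported syntax in {src!r}")


def _convert_piecewise(node: _pyast.Call, src: str) -> Piecewise:
    args = node.args
    if len(args) < 3 or len(args) % 2 == 0:
        raise ExpressionError(
            f"piecewise needs an odd number of arguments >= 3 "
            f"(cond1, val1, ..., default) in {src!r}"
        )
    pieces = []
    for cond_node, val_node in zip(args[0:-1:2], args[1:-1:2]):
        if not isinstance(cond_node, _pyast.Compare):
            raise ExpressionError(f"piecewise condition must be a comparison in {src!r}")
        if len(cond_node.ops) != 1:
            raise ExpressionError(f"chained comparisons are not supported in {src!r}")
        op = _CMP_MAP.get(type(cond_node.ops[0]))
        if op is None:
            raise ExpressionError(f"unsupported comparison operator in {src!r}")
        cond = Cond(op, _convert(cond_node.left, src), _convert(cond_node.comparators[0], src))
        pieces.append((cond, _convert(val_node, src)))
    return Piecewise(tuple(pieces), _convert(args[-1], src))


# ---------------------------------------------------------------------------
# printing

def to_string(e: Expr) -> str:
    """Render to the infix dialect; parse(to_string(e)) == e."""
    if isinstance(e, Num):
        return repr(e.value)
    if isinstance(e, Sym):
        return e.name
    if isinstance(e, Neg):
        return f"-({to_string(e.arg)})"
    if isinstance(e, BinOp):
        return f"({to_string(e.left)} {e.op} {to_string(e.right)})"
    if isinstance(e, Cond):
        return f"{to_string(e.left)} {e.op} {to_string(e.right)}"
    if isinstance(e, Call):
        return f"{e.fn}({', '.join(to_string(a) for a in e.args)})"
    if isinstance(e, Piecewise):
        parts: list[str] = []
        for cond, val in e.pieces:
            parts.append(to_string(cond))
            parts.append(to_string(val))
        parts.append(to_string(e.default))
        return f"piecewise({', '.join(parts)})"
    raise ExpressionError(f"unknown node {e!r}")


# ---------------------------------------------------------------------------
# traversal and rewriting

def walk(e: Expr) -> Iterator[Expr]:
    yield e
    if isinstance(e, Neg):
        yield from walk(e.arg)
    elif isinstance(e, (BinOp, Cond)):
        yield from walk(e.left)
        yield from walk(e.right)
    elif isinstance(e, Call):
        for a in e.args:
            yield from walk(a)
    elif isinstance(e, Piecewise):
        for cond, val in e.pieces:
            yield from walk(cond)
            yield from walk(val)
        yield from walk(e.default)


def symbols(e: Expr) -> set[str]:
    """All variable names referenced in the expression."""
    return {n.name for n in walk(e) if isinstance(n, Sym)}


def substitute(e: Expr, mapping: Mapping[str, Expr]) -> Expr:
    """Replace each symbol found in ``mapping`` by the given expression."""
    if isinstance(e, Num):
        return e
    if isinstance(e, Sym):
        return mapping.get(e.name, e)
    if isinstance(e, Neg):
        return Neg(substitute(e.arg, mapping))
    if isinstance(e, BinOp):
        return BinOp(e.op, substitute(e.left, mapping), substitute(e.right, mapping))
    if isinstance(e, Cond):
        return Cond(e.op, substitute(e.left, mapping), substitute(e.right, mapping))
    if isinstance(e, Call):
        return Call(e.fn, tuple(substitute(a, mapping) for a in e.args))
    if isinstance(e, Piecewise):
        return Piecewise(
            tuple((substitute(c, mapping), substitute(v, mapping)) for c, v in e.pieces),
            substitute(e.default, mapping),
        )
    raise ExpressionError(f"unknown node {e!r}")


def rename_symbols(e: Expr, renames: Mapping[str, str]) -> Expr:
    return substitute(e, {old: Sym(new) for old, new in renames.items()})


# ---------------------------------------------------------------------------
# evaluation

_EVAL_FUNCS = {
    "exp": math.exp,
    "ln": math.log,
    "log10": math.log10,
    "sqrt": math.sqrt,
    "abs": abs,
    "min": min,
    "max": max,
    "pulse": pulse,
}

_CMP_FUNCS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
}


def evaluate(e: Expr, env: Mapping[str, float]) -> float:
    """Recursive evaluation against a name->value environment.

    Convenient for tests and one-off checks; the simulator compiles models
    to generated code instead.
    """
    if isinstance(e, Num):
        return e.value
    if isinstance(e, Sym):
        try:
            return env[e.name]
        except KeyError:
            raise ExpressionError(f"unbound symbol {e.name!r}") from None
    if isinstance(e, Neg):
        return -evaluate(e.arg, env)
    if isinstance(e, BinOp):
        a, b = evaluate(e.left, env), evaluate(e.right, env)
        if e.op == "+":
            return a + b
        if e.op == "-":
            return a - b
        if e.op == "*":
            return a * b
        if e.op == "/":
            return a / b
        return a ** b
    if isinstance(e, Call):
        return _EVAL_FUNCS[e.fn](*(evaluate(a, env) for a in e.args))
    if isinstance(e, Piecewise):
        for cond, val in e.pieces:
            if _CMP_FUNCS[cond.op](evaluate(cond.left, env), evaluate(cond.right, env)):
                return evaluate(val, env)
        return evaluate(e.default, env)
    raise ExpressionError(f"cannot evaluate {e!r}")


# ---------------------------------------------------------------------------
# code generation (used by the simulator)

_PY_FUNCS = {"ln": "log"}  # rendered-name overrides


def render_python(e: Expr, mangle) -> str:
    """Render as a Python expression; ``mangle(name)`` maps symbols to locals."""
    if isinstance(e, Num):
        return repr(e.value)
    if isinstance(e, Sym):
        return mangle(e.name)
    if isinstance(e, Neg):
        return f"(-{render_python(e.arg, mangle)})"
    if isinstance(e, BinOp):
        op = "**" if e.op == "^" else e.op
        return f"({render_python(e.left, mangle)} {op} {render_python(e.right, mangle)})"
    if isinstance(e, Cond):
        return f"({render_python(e.left, mangle)} {e.op} {render_python(e.right, mangle)})"
    if isinstance(e, Call):
        fn = _PY_FUNCS.get(e.fn, e.fn)
        return f"{fn}({', '.join(render_python(a, mangle) for a in e.args)})"
    if isinstance(e, Piecewise):
        out = render_python(e.default, mangle)
        for cond, val in reversed(e.pieces):
            out = f"({render_python(val, mangle)} if {render_python(cond, mangle)} else {out})"
        return out
    raise ExpressionError(f"cannot render {e!r}")


def as_expr(value) -> Expr:
    """Coerce a string (parsed) or Expr to an Expr."""
    if isinstance(value, Expr):
        return value
    if isinstance(value, (int, float)):
        return Num(float(value))
    if isinstance(value, str):
        return parse(value)
    raise ExpressionError(f"cannot interpret {value!r} as an expression")
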