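"""FHIRPath subset: parser, interpreted evaluation, and single-pass emission
of equivalent concise Python expression text.

The evaluator and the emitted code both route through the collection helpers
in :mod:`fmlc.runtime`, so the two paths share one semantics by construction.
Every result is a collection; empty propagates through operators; indexing is
0-based and out-of-range yields empty.  Decimal arithmetic is exact-decimal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

from . import runtime as rt
from ._lexer import Token, TokenStream, tokenize
from .errors import ParseError, UnsupportedFunctionError
from .schema_models import ModelSet

SUPPORTED_FUNCTIONS = {
    "where", "exists", "empty", "first", "last", "count", "select", "iif",
    "not", "contains", "startsWith", "substring", "toString", "toInteger",
    "now", "today",
}

_NILADIC = {"now", "today"}


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lit:
    kind: str  # string integer decimal boolean date datetime
    value: object  # decimals keep their lexical text


@dataclass(frozen=True)
class This:
    pass


@dataclass(frozen=True)
class VarRef:
    name: str


@dataclass(frozen=True)
class Path:
    base: object  # None == relative to focus
    name: str


@dataclass(frozen=True)
class Func:
    base: object  # None == called on focus
    name: str
    args: tuple = ()


@dataclass(frozen=True)
class Index:
    base: object
    index: object


@dataclass(frozen=True)
class UnaryOp:
    op: str
    operand: object


@dataclass(frozen=True)
class BinOp:
    op: str
    left: object
    right: object


@dataclass(frozen=True)
class TypeOp:
    op: str  # is | as
    operand: object
    type_name: str


@dataclass
class EvalContext:
    """Evaluation context: focus collection, variables, shared timestamp."""

    focus: list = field(default_factory=list)
    variables: dict = field(default_factory=dict)
    shared_now: str = ""
    shared_today: str = ""
    models: ModelSet | None = None

    def with_focus(self, focus: list) -> "EvalContext":
        return EvalContext(focus, self.variables, self.shared_now,
                           self.shared_today, self.models)


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

class FhirPathParser:
    """Recursive-descent parser over the shared token stream.

    Precedence (low to high): implies; or/xor; and; =/!=; comparisons;
    union ``|``; additive ``+ - &``; multiplicative ``* / div mod``;
    ``is``/``as``; unary ``-``; postfix (path, call, index); primary.
    """

    def __init__(self, ts: TokenStream):
        self.ts = ts

    def parse(self):
        return self._implies()

    def _implies(self):
        left = self._or()
        while self.ts.cur.is_ident("implies"):
            self.ts.advance()
            left = BinOp("implies", left, self._or())
        return left

    def _or(self):
        left = self._and()
        while self.ts.cur.is_ident("or", "xor"):
            op = self.ts.advance().value
            left = BinOp(op, left, self._and())
        return left

    def _and(self):
        left = self._equality()
        while self.ts.cur.is_ident("and"):
            self.ts.advance()
            left = BinOp("and", left, self._equality())
        return left

    def _equality(self):
        left = self._comparison()
        while self.ts.cur.is_sym("=", "!="):
            op = self.ts.advance().value
            left = BinOp(op, left, self._comparison())
        return left

    def _comparison(self):
        left = self._union()
        while self.ts.cur.is_sym("<", "<=", ">", ">="):
            op = self.ts.advance().value
            left = BinOp(op, left, self._union())
        return left

    def _union(self):
        left = self._additive()
        while self.ts.cur.is_sym("|"):
            self.ts.advance()
            left = BinOp("|", left, self._additive())
        return left

    def _additive(self):
        left = self._multiplicative()
        while self.ts.cur.is_sym("+", "-", "&"):
            op = self.ts.advance().value
            left = BinOp(op, left, self._multiplicative())
        return left

    def _multiplicative(self):
        left = self._type_expr()
        while self.ts.cur.is_sym("*", "/") or self.ts.cur.is_ident("div", "mod"):
            op = self.ts.advance().value
            left = BinOp(op, left, self._type_expr())
        return left

    def _type_expr(self):
        left = self._unary()
        while self.ts.cur.is_ident("is", "as"):
            op = self.ts.advance().value
            tname = self.ts.expect_ident().value
            left = TypeOp(op, left, tname)
        return left

    def _unary(self):
        if self.ts.cur.is_sym("-"):
            self.ts.advance()
            return UnaryOp("-", self._unary())
        if self.ts.cur.is_sym("+"):
            self.ts.advance()
            return self._unary()
        return self._postfix()

    def _postfix(self):
        node = self._primary()
        while True:
            if self.ts.cur.is_sym("."):
                self.ts.advance()
                t = self.ts.cur
                name = self._segment_name()
                if self.ts.cur.is_sym("("):
                    node = self._call(name, base=node, tok=t)
                else:
                    node = Path(node, name)
            elif self.ts.cur.is_sym("["):
                self.ts.advance()
                idx = self.parse()
                self.ts.expect_sym("]")
                node = Index(node, idx)
            else:
                return node

    def _segment_name(self) -> str:
        t = self.ts.cur
        if t.kind == "IDENT":
            return self.ts.advance().value
        if t.kind == "DQSTRING":  # quoted identifier
            return self.ts.advance().value
        raise self.ts.error(f"expected path segment, found {t.value or t.kind!r}")

    def _call(self, name: str, base, tok: Token) -> Func:
        if name not in SUPPORTED_FUNCTIONS:
            raise UnsupportedFunctionError(name, tok.line, tok.col)
        self.ts.expect_sym("(")
        args: list = []
        if not self.ts.cur.is_sym(")"):
            args.append(self.parse())
            while self.ts.cur.is_sym(","):
                self.ts.advance()
                args.append(self.parse())
        self.ts.expect_sym(")")
        if name in _NILADIC and (args or base is not None):
            raise ParseError(f"{name}() takes no arguments and no focus",
                             tok.line, tok.col)
        return Func(base, name, tuple(args))

    def _primary(self):
        t = self.ts.cur
        if t.is_sym("("):
            self.ts.advance()
            node = self.parse()
            self.ts.expect_sym(")")
            return node
        if t.kind == "STRING":
            self.ts.advance()
            return Lit("string", t.value)
        if t.kind == "NUMBER":
            self.ts.advance()
            if "." in t.value:
                return Lit("decimal", t.value)
            return Lit("integer", int(t.value))
        if t.kind == "DATE":
            self.ts.advance()
            return Lit("datetime" if "T" in t.value else "date", t.value)
        if t.is_sym("%"):
            self.ts.advance()
            return VarRef(self.ts.expect_ident().value)
        if t.is_sym("$"):
            self.ts.advance()
            self.ts.expect_ident("this")
            return This()
        if t.is_ident("true", "false"):
            self.ts.advance()
            return Lit("boolean", t.value == "true")
        if t.kind in ("IDENT", "DQSTRING"):
            name = self._segment_name()
            if self.ts.cur.is_sym("("):
                return self._call(name, base=None, tok=t)
            return Path(None, name)
        raise self.ts.error(f"expected expression, found {t.value or t.kind!r}")


def parse_fhirpath(expr_text: str):
    """Parse a FHIRPath expression into an AST.

    Unsupported functions are rejected here, at parse time.
    """
    ts = TokenStream(tokenize(expr_text))
    ast = FhirPathParser(ts).parse()
    if ts.cur.kind != "EOF":
        raise ts.error(f"unexpected trailing input {ts.cur.value!r}")
    return ast


# ---------------------------------------------------------------------------
# Interpreted evaluation
# ---------------------------------------------------------------------------

_BINOP_FN = {
    "=": rt.fp_eq, "!=": rt.fp_ne,
    "<": rt.fp_lt, "<=": rt.fp_le, ">": rt.fp_gt, ">=": rt.fp_ge,
    "+": rt.fp_add, "-": rt.fp_sub, "*": rt.fp_mul, "/": rt.fp_truediv,
    "div": rt.fp_intdiv, "mod": rt.fp_mod,
    "and": rt.fp_and, "or": rt.fp_or, "xor": rt.fp_xor,
    "implies": rt.fp_implies, "&": rt.fp_concat, "|": rt.fp_union,
}


def evaluate(ast, ctx: EvalContext) -> list:
    """Evaluate an AST over the context focus; always returns a collection."""
    if isinstance(ast, Lit):
        if ast.kind == "decimal":
            return [Decimal(ast.value)]
        return [ast.value]
    if isinstance(ast, This):
        return list(ctx.focus)
    if isinstance(ast, VarRef):
        return rt.as_coll(ctx.variables.get(ast.name))
    if isinstance(ast, Path):
        base = list(ctx.focus) if ast.base is None else evaluate(ast.base, ctx)
        return rt.get(base, ast.name)
    if isinstance(ast, Index):
        return rt.fp_index(evaluate(ast.base, ctx), evaluate(ast.index, ctx))
    if isinstance(ast, UnaryOp):
        return rt.fp_neg(evaluate(ast.operand, ctx))
    if isinstance(ast, BinOp):
        return _BINOP_FN[ast.op](evaluate(ast.left, ctx), evaluate(ast.right, ctx))
    if isinstance(ast, TypeOp):
        coll = evaluate(ast.operand, ctx)
        return rt.fp_is(coll, ast.type_name) if ast.op == "is" else rt.fp_as(
            coll, ast.type_name)
    if isinstance(ast, Func):
        return _eval_func(ast, ctx)
    raise TypeError(f"unknown AST node {ast!r}")


def _eval_func(ast: Func, ctx: EvalContext) -> list:
    name = ast.name
    if name == "now":
        return [ctx.shared_now]
    if name == "today":
        return [ctx.shared_today]
    base = list(ctx.focus) if ast.base is None else evaluate(ast.base, ctx)
    if name == "where":
        return rt.where(base, lambda it: rt.truthy(
            evaluate(ast.args[0], ctx.with_focus([it]))))
    if name == "exists":
        if ast.args:
            return [any(rt.truthy(evaluate(ast.args[0], ctx.with_focus([it])))
                        for it in base)]
        return [len(base) > 0]
    if name == "empty":
        return [len(base) == 0]
    if name == "first":
        return base[:1]
    if name == "last":
        return base[-1:]
    if name == "count":
        return [len(base)]
    if name == "select":
        return rt.select(base, lambda it: evaluate(
            ast.args[0], ctx.with_focus([it])))
    if name == "iif":
        cond = evaluate(ast.args[0], ctx.with_focus(base))
        if rt.truthy(cond):
            return evaluate(ast.args[1], ctx.with_focus(base))
        if len(ast.args) > 2:
            return evaluate(ast.args[2], ctx.with_focus(base))
        return []
    if name == "not":
        return rt.fp_not(base)
    if name == "contains":
        return rt.fp_contains(base, evaluate(ast.args[0], ctx))
    if name == "startsWith":
        return rt.fp_startswith(base, evaluate(ast.args[0], ctx))
    if name == "substring":
        return rt.fp_substring(
            base, evaluate(ast.args[0], ctx),
            evaluate(ast.args[1], ctx) if len(ast.args) > 1 else None)
    if name == "toString":
        return rt.fp_tostring(base)
    if name == "toInteger":
        return rt.fp_tointeger(base)
    raise UnsupportedFunctionError(name)


# ---------------------------------------------------------------------------
# Single-pass emission
# ---------------------------------------------------------------------------

_BINOP_NAME = {
    "=": "fp_eq", "!=": "fp_ne", "<": "fp_lt", "<=": "fp_le",
    ">": "fp_gt", ">=": "fp_ge", "+": "fp_add", "-": "fp_sub",
    "*": "fp_mul", "/": "fp_truediv", "div": "fp_intdiv", "mod": "fp_mod",
    "and": "fp_and", "or": "fp_or", "xor": "fp_xor",
    "implies": "fp_implies", "&": "fp_concat", "|": "fp_union",
}


def emit_expression(ast, static_type: str | None = None,
                    models: ModelSet | None = None, *,
                    focus: str = "_focus", varmap: dict | None = None) -> str:
    """Emit a Python expression equivalent to ``evaluate(ast, ...)``.

    Single traversal, no intermediate representation.  The emitted text
    references only the runtime helper namespace (``rt``), the execution
    context (``ctx``) and local variables; string literals are embedded
    directly.  ``static_type``, when known, enables model-informed
    simplification before emission; without it, navigation defers entirely to
    the runtime's dynamic dispatch.
    """
    ast = simplify(ast, static_type, models)
    return _emit(ast, focus, varmap or {}, 0)


def _lit_repr(lit: Lit) -> str:
    if lit.kind == "decimal":
        return f"rt.dec({lit.value!r})"
    if lit.kind in ("date", "datetime"):
        return repr(lit.value)
    return repr(lit.value)


def _emit(ast, focus: str, varmap: dict, depth: int) -> str:
    if isinstance(ast, Lit):
        return f"[{_lit_repr(ast)}]"
    if isinstance(ast, This):
        return focus
    if isinstance(ast, VarRef):
        py = varmap.get(ast.name, ast.name)
        return f"rt.as_coll({py})"
    if isinstance(ast, Path):
        base = focus if ast.base is None else _emit(ast.base, focus, varmap, depth)
        return f"rt.get({base}, {ast.name!r})"
    if isinstance(ast, Index):
        base = _emit(ast.base, focus, varmap, depth)
        if isinstance(ast.index, Lit) and ast.index.kind == "integer":
            n = ast.index.value
            return f"({base})[{n}:{n + 1}]" if n >= 0 else "[]"
        return f"rt.fp_index({base}, {_emit(ast.index, focus, varmap, depth)})"
    if isinstance(ast, UnaryOp):
        return f"rt.fp_neg({_emit(ast.operand, focus, varmap, depth)})"
    if isinstance(ast, BinOp):
        left = _emit(ast.left, focus, varmap, depth)
        right = _emit(ast.right, focus, varmap, depth)
        return f"rt.{_BINOP_NAME[ast.op]}({left}, {right})"
    if isinstance(ast, TypeOp):
        base = _emit(ast.operand, focus, varmap, depth)
        fn = "fp_is" if ast.op == "is" else "fp_as"
        return f"rt.{fn}({base}, {ast.type_name!r})"
    if isinstance(ast, Func):
        return _emit_func(ast, focus, varmap, depth)
    raise TypeError(f"unknown AST node {ast!r}")


def _emit_func(ast: Func, focus: str, varmap: dict, depth: int) -> str:
    name = ast.name
    if name == "now":
        return "[ctx.shared_now]"
    if name == "today":
        return "[ctx.shared_today]"
    base = focus if ast.base is None else _emit(ast.base, focus, varmap, depth)
    it = f"_it{depth}" if depth else "_it"
    if name == "where":
        body = _emit(ast.args[0], f"[{it}]", varmap, depth + 1)
        return f"rt.where({base}, lambda {it}: rt.truthy({body}))"
    if name == "exists":
        if ast.args:
            body = _emit(ast.args[0], f"[{it}]", varmap, depth + 1)
            return (f"[len(rt.where({base}, lambda {it}: rt.truthy({body}))) > 0]")
        return f"[len({base}) > 0]"
    if name == "empty":
        return f"[len({base}) == 0]"
    if name == "first":
        return f"({base})[:1]"
    if name == "last":
        return f"({base})[-1:]"
    if name == "count":
        return f"[len({base})]"
    if name == "select":
        body = _emit(ast.args[0], f"[{it}]", varmap, depth + 1)
        return f"rt.select({base}, lambda {it}: {body})"
    if name == "iif":
        cond = _emit(ast.args[0], base, varmap, depth)
        then = _emit(ast.args[1], base, varmap, depth)
        other = _emit(ast.args[2], base, varmap, depth) if len(ast.args) > 2 else "[]"
        return f"({then} if rt.truthy({cond}) else {other})"
    if name == "not":
        return f"rt.fp_not({base})"
    if name == "contains":
        return f"rt.fp_contains({base}, {_emit(ast.args[0], focus, varmap, depth)})"
    if name == "startsWith":
        return f"rt.fp_startswith({base}, {_emit(ast.args[0], focus, varmap, depth)})"
    if name == "substring":
        args = [_emit(a, focus, varmap, depth) for a in ast.args]
        return f"rt.fp_substring({base}, {', '.join(args)})"
    if name == "toString":
        return f"rt.fp_tostring({base})"
    if name == "toInteger":
        return f"rt.fp_tointeger({base})"
    raise UnsupportedFunctionError(name)


# ---------------------------------------------------------------------------
# Simplification
# ---------------------------------------------------------------------------

_FOLDABLE = {"+", "-", "*", "/", "div", "mod", "and", "or", "xor", "implies"}


def simplify(ast, static_type: str | None = None, models: ModelSet | None = None):
    """Semantics-preserving rewrites from a fixed catalogue.

    Constant folding of literal arithmetic/boolean operators;
    ``X.exists().not()`` -> ``X.empty()``; ``X.where(true)`` -> ``X``;
    ``X.first()`` -> ``X`` when the model proves max one item.  Idempotent.
    """
    if isinstance(ast, BinOp):
        left = simplify(ast.left, static_type, models)
        right = simplify(ast.right, static_type, models)
        node = BinOp(ast.op, left, right)
        if (ast.op in _FOLDABLE and isinstance(left, Lit) and isinstance(right, Lit)):
            folded = _try_fold(node)
            if folded is not None:
                return folded
        return node
    if isinstance(ast, UnaryOp):
        operand = simplify(ast.operand, static_type, models)
        if isinstance(operand, Lit) and operand.kind in ("integer", "decimal"):
            if operand.kind == "integer":
                return Lit("integer", -operand.value)
            return Lit("decimal", f"-{operand.value}" if not str(
                operand.value).startswith("-") else str(operand.value)[1:])
        return UnaryOp(ast.op, operand)
    if isinstance(ast, Index):
        return Index(simplify(ast.base, static_type, models),
                     simplify(ast.index, static_type, models))
    if isinstance(ast, TypeOp):
        return TypeOp(ast.op, simplify(ast.operand, static_type, models),
                      ast.type_name)
    if isinstance(ast, Path):
        if ast.base is None:
            return ast
        return Path(simplify(ast.base, static_type, models), ast.name)
    if isinstance(ast, Func):
        base = simplify(ast.base, static_type, models) if ast.base is not None else None
        args = tuple(simplify(a, static_type, models) for a in ast.args)
        node = Func(base, ast.name, args)
        # X.exists().not() -> X.empty()
        if (node.name == "not" and isinstance(base, Func)
                and base.name == "exists" and not base.args):
            return Func(base.base, "empty")
        # X.where(true) -> X
        if (node.name == "where" and args
                and args[0] == Lit("boolean", True)):
            return base if base is not None else This()
        # X.first() -> X when the model proves a singleton path
        if (node.name == "first" and not args and isinstance(base, Path)
                and _max_occurs_one(base, static_type, models)):
            return base
        return node
    return ast


def _max_occurs_one(path: Path, static_type: str | None,
                    models: ModelSet | None) -> bool:
    """True when the whole relative path chain has maxOccurs 1 at each step."""
    if static_type is None or models is None:
        return False
    chain: list[str] = []
    node = path
    while isinstance(node, Path):
        chain.append(node.name)
        node = node.base
    if node is not None and not isinstance(node, This):
        return False
    ctx_type: str | None = static_type
    for name in reversed(chain):
        if ctx_type is None or ctx_type.startswith("xs:"):
            return False
        try:
            e = models.element_map(ctx_type)[name]
        except Exception:
            return False
        if e.repeats:
            return False
        ctx_type = e.type_ref
    return True


def _try_fold(node: BinOp):
    left, right = node.left, node.right
    try:
        result = _BINOP_FN[node.op]([_lit_value(left)], [_lit_value(right)])
    except Exception:
        return None
    if len(result) != 1:
        return None
    v = result[0]
    if isinstance(v, bool):
        return Lit("boolean", v)
    if isinstance(v, int):
        return Lit("integer", v)
    if isinstance(v, Decimal):
        return Lit("decimal", str(v))
    if isinstance(v, str):
        kind = left.kind if left.kind in ("date", "datetime") else "string"
        return Lit(kind if kind != "string" else "string", v)
    return None


def _lit_value(lit: Lit):
    if lit.kind == "decimal":
        return Decimal(lit.value)
    return lit.value
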