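"""Reference interpreter: direct execution of a StructureMapAST.

This is the in-repo gold-standard engine the compiler is verified against.
It walks the AST rule by rule and shares the runtime module's assignment,
translation, timestamp and UUID helpers with compiled programs, so the two
engines differ only in dispatch, never in semantics.  Performance is a
non-goal here; the interpreter is the baseline the compiled path must beat.
"""
from __future__ import annotations

import difflib
import json
import re
from decimal import Decimal

from lxml import etree

from . import runtime as rt
from .errors import FmlcError, MapRuntimeError
from .fhirpath import EvalContext, evaluate
from .fml_frontend import MapGroup, MapRule, Param, RuleTarget, StructureMapAST
from .map_compiler import _Compiler, resolve_dependent_group
from .schema_models import InstanceNode, ModelSet

_LIST_SLICE = {"first": slice(0, 1), "last": slice(-1, None),
               "not_first": slice(1, None), "not_last": slice(None, -1)}


def _literal_value(p: Param):
    if p.kind == "string":
        return p.value
    if p.kind == "integer":
        return int(p.value)
    if p.kind == "decimal":
        return Decimal(str(p.value))
    if p.kind == "boolean":
        return bool(p.value)
    raise MapRuntimeError(f"parameter {p!r} is not a literal")


class _Interpreter:
    def __init__(self, ast: StructureMapAST, models: ModelSet,
                 ctx: rt.ExecutionContext):
        self.ast = ast
        self.models = models
        self.ctx = ctx
        # reuse the compiler's alias/type resolution so both engines agree
        self._resolver = _Compiler(ast, models)

    # -- groups -------------------------------------------------------------

    def run_group(self, group: MapGroup, args: list):
        if len(args) != len(group.inputs):
            raise MapRuntimeError(
                f"group {group.name!r}: {len(args)} arguments for "
                f"{len(group.inputs)} inputs")
        env = {name: value for (name, _t, _m), value in zip(group.inputs, args)}
        if group.extends:
            parent = next((g for g in self.ast.groups if g.name == group.extends),
                          None)
            if parent is None:
                raise MapRuntimeError(
                    f"group {group.name!r} extends unknown group {group.extends!r}")
            self.run_group(parent, args[:len(parent.inputs)])
        for rule in group.rules:
            self.exec_rule(rule, dict(env))

    # -- rules --------------------------------------------------------------

    def _eval_fp(self, expr, focus_item, env):
        ectx = EvalContext([focus_item], env, self.ctx.shared_now,
                           self.ctx.shared_today, self.models)
        return evaluate(expr.ast, ectx)

    def exec_rule(self, rule: MapRule, env: dict):
        s = rule.sources[0]
        if s.context not in env:
            raise MapRuntimeError(f"variable {s.context!r} not in scope")
        base = env[s.context]
        items = rt.iter_items(base, s.element) if s.element else [base]
        if s.default_value is not None and not items:
            items = [_literal_value(s.default_value)]
        if s.list_mode in _LIST_SLICE:
            items = items[_LIST_SLICE[s.list_mode]]
        elif s.list_mode == "only_one":
            items = rt.only_one(items, f"{s.context}.{s.element or ''}")
        for item in items:
            scope = dict(env)
            if s.variable is not None:
                scope[s.variable] = item
            if s.condition is not None and not rt.truthy(
                    self._eval_fp(s.condition, item, scope)):
                continue
            if s.check is not None:
                rt.check(rt.truthy(self._eval_fp(s.check, item, scope)),
                         s.check.text)
            for target in rule.targets:
                self.exec_target(target, scope, item)
            for nested in rule.nested_rules:
                self.exec_rule(nested, dict(scope))
            for gname, args in rule.dependent_calls:
                group = resolve_dependent_group((gname, tuple(args)), self.ast)
                values = []
                for a in args:
                    if a not in scope:
                        raise MapRuntimeError(
                            f"variable {a!r} not in scope in call to {gname!r}")
                    values.append(scope[a])
                self.run_group(group, values)

    # -- targets ------------------------------------------------------------

    def exec_target(self, target: RuleTarget, scope: dict, focus_item):
        t = target.transform
        ctx_node = None
        if target.context is not None:
            if target.context not in scope:
                raise MapRuntimeError(f"variable {target.context!r} not in scope")
            ctx_node = scope[target.context]
        if t is None:
            if ctx_node is None or target.element is None:
                raise MapRuntimeError("target without transform needs context.element")
            value = rt.get_or_create(ctx_node, target.element, self.ctx)
            if target.variable is not None:
                scope[target.variable] = value
            return
        value, is_coll = self._transform_value(t, target, scope, ctx_node)
        if ctx_node is None:
            if target.variable is None:
                raise MapRuntimeError(f"transform-only target {t!r} needs a variable")
            scope[target.variable] = value
            return
        if target.element is None:
            raise MapRuntimeError("target assignment needs an element")
        if is_coll:
            stored = rt.assign_all(ctx_node, target.element, value, self.ctx)
        else:
            stored = rt.assign(ctx_node, target.element, value, self.ctx)
        if target.variable is not None:
            scope[target.variable] = stored

    def _param_value(self, p: Param, scope: dict):
        if p.kind == "var":
            if p.value not in scope:
                raise MapRuntimeError(f"variable {p.value!r} not in scope")
            return scope[p.value]
        return _literal_value(p)

    def _transform_value(self, t: str, target: RuleTarget, scope: dict,
                         ctx_node):
        ps = target.parameters
        if t == "copy":
            return rt.copy_value(self._param_value(ps[0], scope)), False
        if t == "create":
            if ps:
                qname = self._resolver.resolve_input_type(ps[0].value, "target")
                return rt.create(self.models, qname), False
            if not isinstance(ctx_node, InstanceNode):
                raise MapRuntimeError("create: target context is not a node")
            return rt.create_for(self.models, ctx_node, target.element), False
        if t == "translate":
            code = self._param_value(ps[0], scope)
            url = ps[1].value.lstrip("#") if ps[1].kind == "string" else None
            if url is None:
                raise MapRuntimeError("translate: dynamic map URLs are not supported")
            resolved = next((u for u in self.ctx.conceptmaps
                             if u == url or u.endswith("/" + url)), url)
            return rt.translate_code(self.ctx, code, None, resolved,
                                     ps[2].value), False
        if t == "append":
            return rt.str_concat([self._param_value(p, scope) for p in ps]), False
        if t == "cast":
            return rt.cast_value(self._param_value(ps[0], scope), ps[1].value), False
        if t == "truncate":
            return rt.truncate(self._param_value(ps[0], scope),
                               int(ps[1].value)), False
        if t == "evaluate":
            if len(ps) == 2:
                focus = self._param_value(ps[0], scope)
            else:
                focus = None
            expr = ps[-1].value
            ectx = EvalContext([focus] if focus is not None else [], scope,
                               self.ctx.shared_now, self.ctx.shared_today,
                               self.models)
            return evaluate(expr.ast, ectx), True
        if t == "cc":
            return rt.make_cc(self.ctx,
                              *[self._param_value(p, scope) for p in ps]), False
        if t == "c":
            return rt.make_coding(self.ctx,
                                  *[self._param_value(p, scope) for p in ps]), False
        if t == "uuid":
            return rt.new_uuid(self.ctx), False
        raise MapRuntimeError(f"unsupported transform {t!r}")


def interpret_map(ast: StructureMapAST, source: InstanceNode, models: ModelSet,
                  conceptmaps=(), ctx: rt.ExecutionContext | None = None
                  ) -> InstanceNode:
    """Execute a mapping directly over an instance tree.

    Creates the target root from the entry (first) group's target input type,
    runs the group, and returns the target node.
    """
    if ctx is None:
        ctx = rt.ExecutionContext(models=models)
    if ctx.models is None:
        ctx.models = models
    for cm in list(ast.concept_maps) + list(conceptmaps):
        ctx.register_conceptmap(cm)
    itp = _Interpreter(ast, models, ctx)
    if not ast.groups:
        raise MapRuntimeError("map has no groups")
    entry = ast.groups[0]
    tgt_input = next(i for i in entry.inputs if i[2] == "target")
    tgt_type = itp._resolver.resolve_input_type(tgt_input[1], "target")
    if tgt_type is None:
        raise MapRuntimeError("entry group target input must carry a type")
    target = rt.create(models, tgt_type)
    args = []
    for name, _t, mode in entry.inputs:
        args.append(source if mode == "source" else target)
    itp.run_group(entry, args)
    return target


# ---------------------------------------------------------------------------
# Canonical diff
# ---------------------------------------------------------------------------

_UUID_RE = re.compile(
    r"[0-9a-fA-F]{8}-[0-9a-fA-F]{4}-4[0-9a-fA-F]{3}-"
    r"[89abAB][0-9a-fA-F]{3}-[0-9a-fA-F]{12}")


def _canonical_text(text: str, fmt: str) -> str:
    if fmt == "xml":
        parser = etree.XMLParser(remove_blank_text=True, remove_comments=True)
        try:
            root = etree.fromstring(
                text.encode() if isinstance(text, str) else text, parser)
        except etree.XMLSyntaxError as exc:
            raise FmlcError(f"XML parse failure: {exc}") from None
        return etree.tostring(root, pretty_print=True).decode()
    if fmt == "json":
        try:
            data = json.loads(text, parse_float=str)
        except json.JSONDecodeError as exc:
            raise FmlcError(f"JSON parse failure: {exc}") from None
        return json.dumps(data, indent=1, sort_keys=True, ensure_ascii=False)
    raise ValueError(f"unknown format {fmt!r}")


def diff_canonical(a: str, b: str, fmt: str) -> str:
    """Canonical diff of two documents; empty string iff equivalent.

    Both sides are canonicalized (whitespace-insignificant form) and v4-UUID
    tokens are normalized to a placeholder — the only permitted difference
    classes.  Anything else shows up in a unified diff naming the lines.
    """
    ca = _UUID_RE.sub("<uuid>", _canonical_text(a, fmt))
    cb = _UUID_RE.sub("<uuid>", _canonical_text(b, fmt))
    if ca == cb:
        return ""
    return "\n".join(difflib.unified_diff(
        ca.splitlines(), cb.splitlines(), "a", "b", lineterm=""))
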