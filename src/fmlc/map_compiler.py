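"""StructureMap-to-Python compiler.

Translates a :class:`~fmlc.fml_frontend.StructureMapAST` (plus models and
concept maps) into a standalone, human-traceable Python program.

Traceability contract: generated functions are named after their FML groups
(sanitization only), parameter and variable identifiers are preserved, and
rule names never appear in the output.  Type information resolved statically
from the models produces specialized assignment calls; where a type cannot be
determined at compile time the generated code falls back to the runtime's
dynamic dispatch.  Generated programs depend only on the runtime module and
the model schemas.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import AmbiguityError, CompileError
from .fhirpath import emit_expression
from .fml_frontend import (
    ConceptMapDef,
    MapGroup,
    MapRule,
    Param,
    RuleTarget,
    StructureMapAST,
)
from .schema_models import TEXT_ELEMENT, ModelSet

_CAST_KINDS = {"string", "integer", "decimal", "boolean", "date", "dateTime"}

_ARITY = {"copy": (1, 1), "create": (0, 1), "translate": (3, 3),
          "append": (1, 99), "cast": (2, 2), "truncate": (2, 2),
          "evaluate": (1, 2), "cc": (1, 2), "c": (2, 3), "uuid": (0, 0)}

_LIST_SLICE = {"first": "[:1]", "last": "[-1:]", "not_first": "[1:]",
               "not_last": "[:-1]"}


@dataclass
class GeneratedProgram:
    source_text: str
    symbol_table: dict[str, str]
    entry_point: str
    required_models: list[str]
    required_conceptmaps: list[str]


def sanitize_identifier(name: str) -> str:
    """Map an FML identifier to a Python identifier by sanitization only."""
    out = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if out and out[0].isdigit():
        out = "_" + out
    return out or "_"


@dataclass
class TypeEnv:
    """Lexically scoped variable -> (python name, static type or None)."""

    parent: "TypeEnv | None" = None
    vars: dict[str, tuple[str, str | None]] = field(default_factory=dict)
    _taken: set = field(default_factory=set)

    def child(self) -> "TypeEnv":
        env = TypeEnv(parent=self)
        env._taken = self._taken  # python scope is flat per function
        return env

    def lookup(self, name: str):
        env: TypeEnv | None = self
        while env is not None:
            if name in env.vars:
                return env.vars[name]
            env = env.parent
        return None

    def bind(self, name: str, static_type: str | None) -> str:
        base = sanitize_identifier(name)
        py = base
        k = 2
        while py in self._taken and (name not in self.vars or self.vars[name][0] != py):
            py = f"{base}_{k}"
            k += 1
        self._taken.add(py)
        self.vars[name] = (py, static_type)
        return py

    def varmap(self) -> dict[str, str]:
        out: dict[str, str] = {}
        env: TypeEnv | None = self
        chain = []
        while env is not None:
            chain.append(env)
            env = env.parent
        for env in reversed(chain):
            for name, (py, _t) in env.vars.items():
                out[name] = py
        return out


class _Compiler:
    def __init__(self, ast: StructureMapAST, models: ModelSet,
                 conceptmaps=(), emit_fml_comments: bool = False):
        self.ast = ast
        self.models = models
        self.conceptmaps = list(ast.concept_maps) + [
            cm for cm in conceptmaps if cm not in ast.concept_maps]
        self.emit_fml_comments = emit_fml_comments
        self.symbol_table: dict[str, str] = {}
        #: inlined ConceptMap tables: url -> (generated name, code table)
        self._cm_tables: dict[str, tuple[str, dict]] = {}
        self._need_cm_types = False
        self.groups_by_name = {g.name: g for g in ast.groups}
        #: model-URI alias -> qualified type, from `uses` declarations
        self.aliases: dict[str, str] = {}
        self.mode_families: dict[str, list[str]] = {"source": [], "target": []}
        for uri, alias, mode in ast.uses_declarations:
            qname = self._type_from_uri(uri)
            if alias:
                self.aliases[alias] = qname
            fam = qname.split(".")[0]
            if fam not in self.mode_families[mode]:
                self.mode_families[mode].append(fam)

    # -- type resolution ----------------------------------------------------

    def _type_from_uri(self, uri: str) -> str:
        local = uri.rstrip("/").rsplit("/", 1)[-1]
        hits = [t for t in self.models.types if t.split(".")[-1] == local]
        if len(hits) == 1:
            return hits[0]
        for t in hits:
            if t.split(".")[0] in uri:
                return t
        raise CompileError(f"cannot resolve model URI {uri!r} to a type")

    def resolve_input_type(self, type_text: str | None, mode: str) -> str | None:
        if type_text is None:
            return None
        if type_text in self.aliases:
            return self.aliases[type_text]
        if "." in type_text and type_text in self.models.types:
            return type_text
        hits = [t for t in self.models.types if t.split(".")[-1] == type_text]
        if len(hits) == 1:
            return hits[0]
        # disambiguate by the families the group input's mode draws from
        scoped = [t for t in hits if t.split(".")[0] in self.mode_families[mode]]
        if len(scoped) == 1:
            return scoped[0]
        if hits:
            raise AmbiguityError(
                f"type name {type_text!r} is ambiguous: {sorted(hits)}")
        raise CompileError(f"unknown type {type_text!r} in group input")

    def element_type(self, context_type: str | None, element: str) -> str | None:
        if context_type is None or context_type.startswith("xs:"):
            return None
        try:
            return self.models.resolve_element_type(context_type, element)
        except Exception:
            return None

    # -- registration of names ----------------------------------------------

    def _register(self, fml_name: str, py_name: str):
        existing = self.symbol_table.get(fml_name)
        if existing is not None and existing != py_name:
            return  # shadowed variable with a uniquified name; keep first
        for other, py in self.symbol_table.items():
            if py == py_name and other != fml_name:
                raise CompileError(
                    f"identifier collision after sanitization: {other!r} and "
                    f"{fml_name!r} both map to {py_name!r}")
        self.symbol_table[fml_name] = py_name

    # -- program assembly ----------------------------------------------------

    def compile(self) -> GeneratedProgram:
        if not self.ast.groups:
            raise CompileError("map has no groups")
        group_texts = [self.compile_group(g) for g in self.ast.groups]
        entry = self.ast.groups[0]
        entry_py = self.symbol_table[entry.name]
        src_input = next(i for i in entry.inputs if i[2] == "source")
        tgt_input = next(i for i in entry.inputs if i[2] == "target")
        source_root = self.resolve_input_type(src_input[1], "source")
        target_root = self.resolve_input_type(tgt_input[1], "target")
        if source_root is None or target_root is None:
            raise CompileError("entry group inputs must carry resolvable types")
        cm_literals = ",\n    ".join(self._cm_literal(cm) for cm in self.conceptmaps)
        cm_block = f"[\n    {cm_literals},\n]" if self.conceptmaps else "[]"
        origins = list(self.models.origins)
        header = [
            f"# Transformation program generated from map {self.ast.name!r}",
            f"# {self.ast.url}",
            "import sys",
            "",
            "from fmlc import runtime as rt",
            "",
            f"MODELS = rt.load_models({origins!r})",
            f"CONCEPTMAPS = {cm_block}",
            f"SOURCE_ROOT = {source_root!r}",
            f"TARGET_ROOT = {target_root!r}",
            "_E = ()",
            "_IN = rt.InstanceNode",
        ]
        for url, (name, table) in self._cm_tables.items():
            header.append(f"# ConceptMap {url}, inlined at compile time")
            header.append(f"{name} = {table!r}")
        if self._need_cm_types:
            header.append(f"_CM_TYPES = {self._coding_types()!r}")
        header.extend(["", ""])
        footer = [
            "",
            "def transform(ctx, src):",
            "    tgt = rt.create(MODELS, TARGET_ROOT)",
            f"    {entry_py}(ctx, src, tgt)",
            "    return tgt",
            "",
            "",
            "def main(argv=None):",
            "    return rt.program_main(argv if argv is not None else sys.argv[1:],",
            "                           MODELS, CONCEPTMAPS, SOURCE_ROOT,",
            "                           TARGET_ROOT, transform)",
            "",
            "",
            'if __name__ == "__main__":',
            "    sys.exit(main())",
            "",
        ]
        text = "\n".join(header) + "\n\n\n".join(group_texts) + "\n" + "\n".join(footer)
        return GeneratedProgram(
            source_text=text,
            symbol_table=dict(self.symbol_table),
            entry_point=entry_py,
            required_models=origins,
            required_conceptmaps=[cm.url for cm in self.conceptmaps],
        )

    def _cm_literal(self, cm: ConceptMapDef) -> str:
        groups = [
            {"source": g.source_system, "target": g.target_system,
             "elements": [[e.source_code, e.relationship, e.target_code]
                          for e in g.elements]}
            for g in cm.groups
        ]
        return repr({"url": cm.url, "groups": groups})

    # -- groups --------------------------------------------------------------

    _RESERVED = {"ctx", "rt", "sys", "MODELS", "CONCEPTMAPS", "SOURCE_ROOT",
                 "TARGET_ROOT", "transform", "main", "_E", "_IN"}

    def compile_group(self, group: MapGroup) -> str:
        py_name = sanitize_identifier(group.name)
        if py_name in self._RESERVED:
            raise CompileError(
                f"group name {group.name!r} collides with a reserved identifier")
        self._register(group.name, py_name)
        env = TypeEnv()
        env._taken.update(self._RESERVED)
        params = ["ctx"]
        for name, type_text, mode in group.inputs:
            qname = self.resolve_input_type(type_text, mode)
            py = env.bind(name, qname)
            self._register(name, py)
            params.append(py)
        lines = [f"def {py_name}({', '.join(params)}):"]
        if group.extends:
            parent = self.groups_by_name.get(group.extends)
            if parent is None:
                raise CompileError(
                    f"group {group.name!r} extends unknown group {group.extends!r}")
            if len(parent.inputs) > len(group.inputs):
                raise CompileError(
                    f"group {group.name!r} has fewer inputs than its parent")
            args = ", ".join(["ctx"] + [env.lookup(n)[0]
                                        for n, _, _ in group.inputs[:len(parent.inputs)]])
            lines.append(f"    {sanitize_identifier(parent.name)}({args})")
        body: list[str] = []
        for rule in group.rules:
            body.extend(self.compile_rule(rule, env.child(), indent=1))
        if not body and not group.extends:
            body = ["    pass"]
        lines.extend(body)
        return "\n".join(lines) + "\n"

    # -- rules ---------------------------------------------------------------

    def compile_rule(self, rule: MapRule, env: TypeEnv, indent: int) -> list[str]:
        ind = "    " * indent
        lines: list[str] = []
        if self.emit_fml_comments:
            lines.append(f"{ind}# FML: {_rule_comment(rule)}")
        s = rule.sources[0]
        ctx_binding = env.lookup(s.context)
        if ctx_binding is None:
            raise CompileError(
                f"variable {s.context!r} not in scope (rule {rule.rule_id})")
        ctx_py, ctx_type = ctx_binding
        body_env = env.child()

        # context-only source: no iteration needed, the focus is the variable
        if s.element is None and s.list_mode is None and s.default_value is None:
            item_type = ctx_type
            if s.declared_type is not None:
                item_type = self.resolve_input_type(
                    s.declared_type, "source") or item_type
            if s.variable is not None:
                var_py = body_env.bind(s.variable, item_type)
                self._register(s.variable, var_py)
                lines.append(f"{ind}{var_py} = {ctx_py}")
            else:
                var_py = ctx_py
            body_indent = indent
            varmap = body_env.varmap()
            if s.condition is not None:
                cond = emit_expression(s.condition.ast, item_type, self.models,
                                       focus=f"[{var_py}]", varmap=varmap)
                lines.append(f"{ind}if rt.truthy({cond}):")
                body_indent = indent + 1
            inner = self._rule_body(rule, s, body_env, body_indent, var_py,
                                    item_type)
            if s.condition is not None and not inner:
                inner = ["    " * body_indent + "pass"]
            lines.extend(inner)
            return lines

        if s.element is not None:
            item_type = self.element_type(ctx_type, s.element)
            if item_type is not None:
                # type known statically: direct access, no dynamic dispatch
                items = f"{ctx_py}.values.get({s.element!r}, _E)"
            else:
                items = f"rt.iter_items({ctx_py}, {s.element!r})"
        else:
            items = f"[{ctx_py}]"
            item_type = ctx_type
        if s.declared_type is not None:
            declared = self.resolve_input_type(s.declared_type, "source")
            item_type = declared or item_type
        if s.default_value is not None:
            items = f"({items} or [{_literal_repr(s.default_value)}])"
        if s.list_mode in _LIST_SLICE:
            items = f"({items}){_LIST_SLICE[s.list_mode]}"
        elif s.list_mode == "only_one":
            items = f"rt.only_one({items}, {(s.context + '.' + (s.element or '')) !r})"
        if s.variable is not None:
            var_py = body_env.bind(s.variable, item_type)
            self._register(s.variable, var_py)
        else:
            var_py = body_env.bind(f"_item_{rule.rule_id}", item_type)
        lines.append(f"{ind}for {var_py} in {items}:")
        bind = "    " * (indent + 1)
        inner: list[str] = []
        if s.condition is not None:
            cond = emit_expression(s.condition.ast, item_type, self.models,
                                   focus=f"[{var_py}]", varmap=body_env.varmap())
            inner.append(f"{bind}if not rt.truthy({cond}):")
            inner.append(f"{bind}    continue")
        inner.extend(self._rule_body(rule, s, body_env, indent + 1, var_py,
                                     item_type))
        if not inner:
            inner = [f"{bind}pass"]
        lines.extend(inner)
        return lines

    def _rule_body(self, rule: MapRule, s, body_env: TypeEnv, indent: int,
                   var_py: str, item_type: str | None) -> list[str]:
        ind = "    " * indent
        inner: list[str] = []
        if s.check is not None:
            chk = emit_expression(s.check.ast, item_type, self.models,
                                  focus=f"[{var_py}]", varmap=body_env.varmap())
            inner.append(f"{ind}rt.check(rt.truthy({chk}), {s.check.text!r})")
        for target in rule.targets:
            inner.extend(self.compile_transform(target, body_env, indent))
        for nested in rule.nested_rules:
            inner.extend(self.compile_rule(nested, body_env.child(), indent))
        for gname, args in rule.dependent_calls:
            inner.extend(self._dependent_call(gname, args, body_env, indent))
        return inner

    def _dependent_call(self, gname: str, args, env: TypeEnv, indent: int) -> list[str]:
        ind = "    " * indent
        group = resolve_dependent_group((gname, tuple(args)), self.ast)
        if len(args) != len(group.inputs):
            raise CompileError(
                f"dependent call to {gname!r}: {len(args)} arguments for "
                f"{len(group.inputs)} inputs")
        py_args = []
        for a in args:
            binding = env.lookup(a)
            if binding is None:
                raise CompileError(f"variable {a!r} not in scope in call to {gname!r}")
            py_args.append(binding[0])
        return [f"{ind}{sanitize_identifier(group.name)}(ctx, {', '.join(py_args)})"]

    # -- targets / transforms ------------------------------------------------

    def compile_transform(self, target: RuleTarget, env: TypeEnv,
                          indent: int) -> list[str]:
        ind = "    " * indent
        t = target.transform
        if t is not None:
            lo, hi = _ARITY[t]
            if not lo <= len(target.parameters) <= hi:
                raise CompileError(
                    f"transform {t!r} takes {lo}..{hi} parameters, "
                    f"got {len(target.parameters)}")
        ctx_py = ctx_type = None
        if target.context is not None:
            binding = env.lookup(target.context)
            if binding is None:
                raise CompileError(f"variable {target.context!r} not in scope")
            ctx_py, ctx_type = binding
        elem_type = (self.element_type(ctx_type, target.element)
                     if target.element is not None else None)

        # no transform: bind (get-or-create) the element
        if t is None:
            if target.element is None or ctx_py is None:
                raise CompileError("target without transform needs context.element")
            lhs = ""
            if target.variable is not None:
                var_py = env.bind(target.variable, elem_type)
                self._register(target.variable, var_py)
                lhs = f"{var_py} = "
            e = (self.models.element_map(ctx_type).get(target.element)
                 if ctx_type is not None and ctx_type in self.models.types else None)
            if (e is not None and not e.type_ref.startswith("xs:")
                    and not self.models.is_primitive_model(e.type_ref)):
                rk = self.models.resource_kind_of(e.type_ref)
                rk_arg = f", {rk!r}" if rk is not None else ""
                if e.repeats:
                    if lhs:
                        var = lhs[:-3]
                        return [
                            f"{ind}{lhs}{self._create_expr(e.type_ref)}",
                            f"{ind}{ctx_py}.values.setdefault("
                            f"{target.element!r}, []).append({var})",
                        ]
                    return [f"{ind}rt.add_new({ctx_py}, {target.element!r}, "
                            f"{e.type_ref!r}{rk_arg})"]
                # singleton: reuse the existing child or create in place
                el = target.element
                return [f"{ind}{lhs}({ctx_py}.values.get({el!r}) or "
                        f"{ctx_py}.values.setdefault({el!r}, "
                        f"[{self._create_expr(e.type_ref)}]))[0]"]
            return [f"{ind}{lhs}rt.get_or_create({ctx_py}, {target.element!r}, ctx)"]

        value, value_type, collection, kind = self._value_expr(
            t, target, env, ctx_type, elem_type)
        lines: list[str] = []
        if target.context is None:
            if target.variable is None:
                raise CompileError(f"transform-only target {t!r} needs a variable")
            var_py = env.bind(target.variable, value_type)
            self._register(target.variable, var_py)
            return [f"{ind}{var_py} = {value}"]
        if target.element is None:
            raise CompileError("target assignment needs an element")
        if collection:
            stmt = f"rt.assign_all({ctx_py}, {target.element!r}, {value}, ctx)"
        else:
            if target.variable is None:
                # hot path: plain statement, no binding needed
                lines.append(f"{ind}" + self._assign_stmt(
                    ctx_py, ctx_type, target.element, value, kind, inline=True,
                    vtype=value_type))
                return lines
            if elem_type is not None and self.models.is_container(elem_type):
                # bind the resource itself, then wrap it into the container
                var_py = env.bind(target.variable, value_type)
                self._register(target.variable, var_py)
                lines.append(f"{ind}{var_py} = {value}")
                lines.append(f"{ind}" + self._assign_stmt(
                    ctx_py, ctx_type, target.element, var_py, "node", inline=True,
                    vtype=value_type))
                return lines
            stmt = self._assign_stmt(ctx_py, ctx_type, target.element, value,
                                     kind, inline=False, vtype=value_type)
        if target.variable is not None:
            var_py = env.bind(target.variable, value_type or elem_type)
            self._register(target.variable, var_py)
            stmt = f"{var_py} = {stmt}"
        lines.append(f"{ind}{stmt}")
        return lines

    def _assign_stmt(self, ctx_py: str, ctx_type: str | None, element: str,
                     value: str, kind: str, inline: bool,
                     vtype: str | None = None) -> str:
        """Specialized assignment when the element resolves statically;
        dynamic runtime dispatch otherwise.

        ``kind`` is the static shape of the value expression: "str" (a Python
        str at run time), "lex" (scalar needing lexicalization), "node" (an
        InstanceNode), or "any".  With ``inline`` the statement mutates the
        values dict directly; otherwise an expression-form helper is used so
        the stored value can be bound.
        """
        e = None
        if ctx_type is not None and not ctx_type.startswith("xs:"):
            e = self.models.element_map(ctx_type).get(element) \
                if ctx_type in self.models.types else None
        if e is None:
            return f"rt.assign({ctx_py}, {element!r}, {value}, ctx)"
        etype = e.type_ref
        if etype.startswith("xs:"):
            fitted = value if kind == "str" else f"rt.to_lexical({value})"
        elif self.models.is_container(etype):
            if vtype is not None and vtype in self.models.types:
                member = vtype.split(".")[-1]
                fitted = f"_IN({etype!r}, {{{member!r}: [{value}]}})"
            else:
                fitted = f"rt.wrap_container({etype!r}, {value})"
        elif self.models.is_primitive_model(etype):
            slot = "value" if "value" in self.models.element_map(etype) else TEXT_ELEMENT
            if kind == "str":
                fitted = f"_IN({etype!r}, {{{slot!r}: [{value}]}})"
            elif kind == "lex":
                fitted = (f"_IN({etype!r}, "
                          f"{{{slot!r}: [rt.to_lexical({value})]}})")
            else:
                fitted = f"rt.wrap_prim({etype!r}, {slot!r}, {value})"
        else:
            if kind in ("str", "lex"):
                # scalar into a complex element: invalid map; keep the
                # dynamic path so the runtime raises the shared error
                return f"rt.assign({ctx_py}, {element!r}, {value}, ctx)"
            fitted = value
        if inline:
            if e.repeats:
                return (f"{ctx_py}.values.setdefault({element!r}, [])"
                        f".append({fitted})")
            return f"{ctx_py}.values[{element!r}] = [{fitted}]"
        fn = "rt.add_item" if e.repeats else "rt.set_single"
        return f"{fn}({ctx_py}, {element!r}, {fitted})"

    def _cm_table(self, url: str) -> str | None:
        """Generated-constant name of the inlined table for a ConceptMap;
        built on first use.  Duplicate source codes map to a sentinel so the
        ambiguity error survives inlining."""
        if url in self._cm_tables:
            return self._cm_tables[url][0]
        cm = next((c for c in self.conceptmaps if c.url == url), None)
        if cm is None:
            return None
        table: dict = {}
        for g in cm.groups:
            for e in g.elements:
                if e.source_code in table:
                    table[e.source_code] = None  # ambiguous
                else:
                    table[e.source_code] = (g.target_system, e.target_code)
        name = f"_CMAP_{len(self._cm_tables)}"
        self._cm_tables[url] = (name, table)
        return name

    def _coding_types(self) -> tuple | None:
        hits = [ty for ty in self.models.types if ty.split(".")[-1] == "Coding"]
        if len(hits) != 1:
            return None
        cd = hits[0]
        em = self.models.element_map(cd)
        if "system" not in em or "code" not in em:
            return None
        sys_t, code_t = em["system"].type_ref, em["code"].type_ref
        slot = "value" if "value" in self.models.element_map(sys_t) else TEXT_ELEMENT
        return (cd, sys_t, code_t, slot)

    def _create_expr(self, qname: str) -> str:
        """Node construction with the resource kind resolved at compile time."""
        rk = self.models.resource_kind_of(qname)
        if rk:
            return f"_IN({qname!r}, None, {rk!r})"
        return f"_IN({qname!r})"

    def _value_expr(self, t: str, target: RuleTarget, env: TypeEnv,
                    ctx_type: str | None, elem_type: str | None):
        """Value expression for a transform; returns (expr, static type,
        is_collection, static value kind)."""
        ps = target.parameters

        def var_expr(p: Param):
            binding = env.lookup(p.value)
            if binding is None:
                raise CompileError(f"variable {p.value!r} not in scope")
            return binding

        def p_expr(p: Param):
            if p.kind == "var":
                return var_expr(p)[0]
            return _literal_repr(p)

        if t == "copy":
            p = ps[0]
            if p.kind == "var":
                py, vtype = var_expr(p)
                if vtype is not None and vtype.startswith("xs:"):
                    return py, vtype, False, "str"  # immutable lexical value
                if (vtype is not None and elem_type is not None
                        and vtype != elem_type
                        and self.models.is_primitive_model(vtype)
                        and self.models.is_primitive_model(elem_type)):
                    # cross-type primitive copy lexicalizes; no deep copy
                    return py, vtype, False, "lex"
                return (f"rt.copy_value({py})", vtype, False,
                        "node" if vtype is not None else "any")
            if p.kind == "string":
                return _literal_repr(p), None, False, "str"
            return _literal_repr(p), None, False, "lex"
        if t == "create":
            if ps:
                if ps[0].kind != "string":
                    raise CompileError("create takes a quoted type name")
                qname = self.resolve_input_type(ps[0].value, "target")
                return self._create_expr(qname), qname, False, "node"
            if elem_type is not None and not elem_type.startswith("xs:"):
                return self._create_expr(elem_type), elem_type, False, "node"
            if target.context is not None and target.element is not None:
                # type unknown statically: resolve at run time
                py = env.lookup(target.context)[0]
                return (f"rt.create_for(MODELS, {py}, {target.element!r})",
                        None, False, "node")
            raise CompileError(
                f"create: cannot resolve type for element {target.element!r}")
        if t == "translate":
            code = p_expr(ps[0])
            if ps[1].kind not in ("string", "var"):
                raise CompileError("translate: map URL must be a string")
            url = ps[1].value if ps[1].kind == "string" else None
            if url is None:
                raise CompileError("translate: dynamic map URLs are not supported")
            if ps[2].kind != "string" or ps[2].value not in ("code", "Coding"):
                raise CompileError("translate: output must be 'code' or 'Coding'")
            out = ps[2].value
            known = {cm.url for cm in self.conceptmaps}
            if url not in known and not url.startswith("#"):
                raise CompileError(f"translate: ConceptMap {url!r} is not available")
            url = url.lstrip("#")
            resolved = next((cm.url for cm in self.conceptmaps
                             if cm.url == url or cm.url.endswith("/" + url)), url)
            table = self._cm_table(resolved)
            if out == "code":
                if table is not None:
                    return (f"rt.cm_code({table}, {code}, {resolved!r})",
                            None, False, "str")
                return (f"rt.translate_code(ctx, {code}, None, {resolved!r}, "
                        f"'code')", None, False, "str")
            coding_types = self._coding_types()
            if table is not None and coding_types is not None:
                self._need_cm_types = True
                return (f"rt.cm_coding({table}, {code}, {resolved!r}, _CM_TYPES)",
                        coding_types[0], False, "node")
            return (f"rt.translate_code(ctx, {code}, None, {resolved!r}, "
                    f"'Coding')", coding_types[0] if coding_types else None,
                    False, "node")
        if t == "append":
            parts = ", ".join(p_expr(p) for p in ps)
            return f"rt.str_concat([{parts}])", None, False, "str"
        if t == "cast":
            if ps[1].kind != "string" or ps[1].value not in _CAST_KINDS:
                raise CompileError(
                    f"cast: target kind must be one of {sorted(_CAST_KINDS)}")
            kind = "str" if ps[1].value in ("string", "decimal", "date",
                                            "dateTime") else "lex"
            return (f"rt.cast_value({p_expr(ps[0])}, {ps[1].value!r})",
                    None, False, kind)
        if t == "truncate":
            if ps[1].kind != "integer":
                raise CompileError("truncate: length must be an integer literal")
            return f"rt.truncate({p_expr(ps[0])}, {ps[1].value})", None, False, "str"
        if t == "evaluate":
            if ps[-1].kind != "fp":
                raise CompileError("evaluate: last parameter must be an expression")
            fp = ps[-1].value
            if len(ps) == 2:
                if ps[0].kind != "var":
                    raise CompileError("evaluate: first parameter must be a variable")
                py, vtype = var_expr(ps[0])
                focus = f"[{py}]"
                stype = vtype
            else:
                focus, stype = "[]", None
            expr = emit_expression(fp.ast, stype, self.models, focus=focus,
                                   varmap=env.varmap())
            return expr, None, True, "any"
        if t == "cc":
            args = ", ".join(p_expr(p) for p in ps)
            hits = [ty for ty in self.models.types
                    if ty.split(".")[-1] == "CodeableConcept"]
            return (f"rt.make_cc(ctx, {args})",
                    hits[0] if len(hits) == 1 else None, False, "node")
        if t == "c":
            args = ", ".join(p_expr(p) for p in ps)
            hits = [ty for ty in self.models.types if ty.split(".")[-1] == "Coding"]
            return (f"rt.make_coding(ctx, {args})",
                    hits[0] if len(hits) == 1 else None, False, "node")
        if t == "uuid":
            return "rt.new_uuid(ctx)", None, False, "str"
        raise CompileError(f"unsupported transform {t!r}")


def _literal_repr(p: Param) -> str:
    if p.kind == "string":
        return repr(p.value)
    if p.kind == "integer":
        return repr(int(p.value))
    if p.kind == "decimal":
        return f"rt.dec({str(p.value)!r})"
    if p.kind == "boolean":
        return repr(bool(p.value))
    raise CompileError(f"parameter {p!r} is not a literal")


def _rule_comment(rule: MapRule) -> str:
    s = rule.sources[0]
    text = s.context + (f".{s.element}" if s.element else "")
    if s.variable:
        text += f" as {s.variable}"
    parts = []
    for t in rule.targets:
        seg = (t.context or "") + (f".{t.element}" if t.element else "")
        if t.transform:
            args = ", ".join(
                p.value if p.kind == "var" else
                (p.value.text if p.kind == "fp" else repr(p.value))
                for p in t.parameters)
            seg += f" = {t.transform}({args})" if seg else f"{t.transform}({args})"
        parts.append(seg)
    if parts:
        text += " -> " + ", ".join(parts)
    return text


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def compile_map(ast: StructureMapAST, models: ModelSet, conceptmaps=(),
                emit_fml_comments: bool = False) -> GeneratedProgram:
    """Compile a StructureMapAST into a standalone Python program."""
    return _Compiler(ast, models, conceptmaps, emit_fml_comments).compile()


def compile_group(group: MapGroup, ast: StructureMapAST, models: ModelSet,
                  conceptmaps=()) -> str:
    """Compile a single group to its function text (diagnostic use)."""
    return _Compiler(ast, models, conceptmaps).compile_group(group)


def resolve_dependent_group(call_or_types, ast: StructureMapAST) -> MapGroup:
    """Resolve a dependent-group reference.

    Explicit calls ``(name, args)`` always win; a ``(source type, target
    type)`` pair selects the unique matching ``types``-mode group; ambiguity
    is an error, never a silent pick.
    """
    first, second = call_or_types
    groups = list(ast.groups)
    if isinstance(second, tuple):  # explicit call: (group name, argument list)
        for g in groups:
            if g.name == first:
                return g
        raise CompileError(f"unknown group {first!r}")
    src_t, tgt_t = first, second  # type-based: (source type, target type)
    candidates = []
    for g in groups:
        if g.type_mode not in ("types", "type-and-types"):
            continue
        src_inputs = [i for i in g.inputs if i[2] == "source"]
        tgt_inputs = [i for i in g.inputs if i[2] == "target"]
        if (len(src_inputs) == 1 and len(tgt_inputs) == 1
                and _type_matches(src_inputs[0][1], src_t)
                and _type_matches(tgt_inputs[0][1], tgt_t)):
            candidates.append(g)
    if not candidates:
        raise CompileError(f"no types-mode group matches ({src_t!r}, {tgt_t!r})")
    if len(candidates) > 1:
        raise AmbiguityError(
            "ambiguous types-mode groups for "
            f"({src_t!r}, {tgt_t!r}): {[g.name for g in candidates]}")
    return candidates[0]


def _type_matches(declared: str | None, actual: str) -> bool:
    if declared is None:
        return False
    return declared == actual or declared == actual.split(".")[-1]
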