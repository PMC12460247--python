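"""FML text and StructureMap resource front end.

Parses FHIR Mapping Language text or StructureMap resources (XML/JSON) into
one format-neutral :class:`StructureMapAST`, and serializes the AST back to
StructureMap form.  Embedded FHIRPath strings are parsed eagerly (the
original text is retained for re-serialization); comments are discarded —
AST equality, not source fidelity, is the round-trip contract.

Supported transforms: copy, create, translate, append, cast, truncate,
evaluate, cc, c, uuid.  Anything else is rejected with an
unsupported-transform error.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

from lxml import etree

from ._lexer import TokenStream, tokenize
from .errors import (
    ImportCycleError,
    ImportError_,
    ParseError,
    UnsupportedFeatureError,
    UnsupportedTransformError,
)
from .fhirpath import FhirPathParser, parse_fhirpath
from .schema_models import _Obj, _Raw, _dump_json

TRANSFORMS = {"copy", "create", "translate", "append", "cast", "truncate",
              "evaluate", "cc", "c", "uuid"}

LIST_MODES = {"first", "not_first", "last", "not_last", "only_one"}

RELATIONSHIPS = {"equivalent", "wider", "narrower", "related"}

_REL_SYMBOLS = {"==": "equivalent", "<=": "wider", ">=": "narrower", "-": "related"}
_REL_TO_SYMBOL = {v: k for k, v in _REL_SYMBOLS.items()}

FHIR_NS = "http://hl7.org/fhir"


# ---------------------------------------------------------------------------
# AST types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FPExpr:
    """A FHIRPath expression: original text plus eagerly parsed AST."""

    text: str
    ast: object

    @staticmethod
    def parse(text: str) -> "FPExpr":
        return FPExpr(text, parse_fhirpath(text))


@dataclass(frozen=True)
class Param:
    """Transform parameter: kind in {var, string, integer, decimal, boolean, fp}."""

    kind: str
    value: object


@dataclass(frozen=True)
class RuleSource:
    context: str
    element: str | None = None
    declared_type: str | None = None
    variable: str | None = None
    condition: FPExpr | None = None
    check: FPExpr | None = None
    list_mode: str | None = None
    default_value: object = None


@dataclass(frozen=True)
class RuleTarget:
    context: str | None = None
    element: str | None = None
    variable: str | None = None
    transform: str | None = None
    parameters: tuple = ()
    list_mode_share: str | None = None


@dataclass(frozen=True)
class MapRule:
    name: str | None
    sources: tuple
    targets: tuple = ()
    nested_rules: tuple = ()
    dependent_calls: tuple = ()  # ((group name, (arg, ...)), ...)
    rule_id: str = field(default="", compare=False)


@dataclass(frozen=True)
class MapGroup:
    name: str
    type_mode: str = "none"  # none | types | type-and-types
    inputs: tuple = ()  # ((name, type text, mode), ...)
    rules: tuple = ()
    extends: str | None = None


@dataclass(frozen=True)
class CMElement:
    source_code: str
    relationship: str
    target_code: str


@dataclass(frozen=True)
class CMGroup:
    source_system: str
    target_system: str
    elements: tuple = ()


@dataclass(frozen=True)
class ConceptMapDef:
    url: str
    groups: tuple = ()


@dataclass(frozen=True)
class StructureMapAST:
    url: str
    name: str
    uses_declarations: tuple = ()  # ((model URI, alias, mode), ...)
    imports: tuple = ()
    concept_maps: tuple = ()
    groups: tuple = ()


# ---------------------------------------------------------------------------
# FML parser
# ---------------------------------------------------------------------------

class _FmlParser:
    def __init__(self, text: str):
        self.ts = TokenStream(tokenize(text))
        self._group_idx = 0

    # header --------------------------------------------------------------

    def parse_map(self) -> StructureMapAST:
        ts = self.ts
        ts.expect_ident("map")
        url = self._dq()
        ts.expect_sym("=")
        if ts.cur.kind == "DQSTRING":
            name = ts.advance().value
        else:
            name = ts.expect_ident().value
        uses, imports, cms, groups = [], [], [], []
        while ts.cur.kind != "EOF":
            if ts.cur.is_ident("uses"):
                uses.append(self._uses())
            elif ts.cur.is_ident("imports"):
                ts.advance()
                imports.append(self._dq())
            elif ts.cur.is_ident("conceptmap"):
                cms.append(self._conceptmap())
            elif ts.cur.is_ident("group"):
                groups.append(self._group())
            else:
                raise ts.error(f"unexpected {ts.cur.value!r} at map level")
        self._check_groups(groups)
        return StructureMapAST(url, name, tuple(uses), tuple(imports),
                               tuple(cms), tuple(groups))

    def _check_groups(self, groups):
        seen = set()
        for g in groups:
            if g.name in seen:
                raise ParseError(f"duplicate group name {g.name!r}")
            seen.add(g.name)

    def _dq(self) -> str:
        t = self.ts.cur
        if t.kind != "DQSTRING":
            raise self.ts.error(f"expected quoted string, found {t.value or t.kind!r}")
        return self.ts.advance().value

    def _uses(self):
        ts = self.ts
        ts.expect_ident("uses")
        uri = self._dq()
        alias = None
        if ts.cur.is_ident("alias"):
            ts.advance()
            alias = ts.expect_ident().value
        ts.expect_ident("as")
        mode = ts.expect_ident("source", "target").value
        return (uri, alias, mode)

    # conceptmap blocks ----------------------------------------------------

    def _conceptmap(self) -> ConceptMapDef:
        ts = self.ts
        ts.expect_ident("conceptmap")
        url = self._dq()
        ts.expect_sym("{")
        prefixes: dict[str, str] = {}
        # (src prefix, src code, relationship, tgt prefix, tgt code)
        entries: list[tuple] = []
        while not ts.cur.is_sym("}"):
            if ts.cur.is_ident("prefix"):
                ts.advance()
                p = ts.expect_ident().value
                ts.expect_sym("=")
                prefixes[p] = self._dq()
                continue
            sp = ts.expect_ident().value
            ts.expect_sym(":")
            scode = self._code_token()
            t = ts.cur
            if not t.is_sym(*_REL_SYMBOLS):
                raise ts.error(f"expected relationship operator, found {t.value!r}")
            rel = _REL_SYMBOLS[ts.advance().value]
            tp = ts.expect_ident().value
            ts.expect_sym(":")
            tcode = self._code_token()
            entries.append((sp, scode, rel, tp, tcode))
        ts.expect_sym("}")
        groups: dict[tuple[str, str], list[CMElement]] = {}
        seen_src = set()
        for sp, scode, rel, tp, tcode in entries:
            for p in (sp, tp):
                if p not in prefixes:
                    raise ParseError(f"undeclared conceptmap prefix {p!r}")
            key = (prefixes[sp], prefixes[tp])
            if (key[0], scode) in seen_src:
                raise ParseError(f"duplicate source code {scode!r} in conceptmap {url!r}")
            seen_src.add((key[0], scode))
            groups.setdefault(key, []).append(CMElement(scode, rel, tcode))
        return ConceptMapDef(url, tuple(
            CMGroup(s, t, tuple(els)) for (s, t), els in groups.items()))

    def _code_token(self) -> str:
        t = self.ts.cur
        if t.kind in ("IDENT", "DQSTRING", "STRING", "NUMBER"):
            return self.ts.advance().value
        raise self.ts.error(f"expected code, found {t.value or t.kind!r}")

    # groups ---------------------------------------------------------------

    def _group(self) -> MapGroup:
        ts = self.ts
        ts.expect_ident("group")
        self._group_idx += 1
        name = ts.expect_ident().value
        ts.expect_sym("(")
        inputs = [self._input()]
        while ts.cur.is_sym(","):
            ts.advance()
            inputs.append(self._input())
        ts.expect_sym(")")
        extends = None
        if ts.cur.is_ident("extends"):
            ts.advance()
            extends = ts.expect_ident().value
        type_mode = "none"
        if ts.cur.is_sym("<<"):
            ts.advance()
            kw = ts.expect_ident("types", "type").value
            if kw == "type":
                ts.expect_sym("+")
                type_mode = "type-and-types"
            else:
                type_mode = "types"
            ts.expect_sym(">>")
        ts.expect_sym("{")
        rules = []
        while not ts.cur.is_sym("}"):
            rules.append(self._rule(f"g{self._group_idx}", len(rules) + 1))
        ts.expect_sym("}")
        modes = [m for _, _, m in inputs]
        if "source" not in modes or "target" not in modes:
            raise ParseError(f"group {name!r} needs at least one source and one target input")
        return MapGroup(name, type_mode, tuple(inputs), tuple(rules), extends)

    def _input(self):
        ts = self.ts
        mode = ts.expect_ident("source", "target").value
        name = ts.expect_ident().value
        type_text = None
        if ts.cur.is_sym(":"):
            ts.advance()
            type_text = ts.expect_ident().value
        return (name, type_text, mode)

    # rules ----------------------------------------------------------------

    def _rule(self, gid: str, idx: int) -> MapRule:
        ts = self.ts
        source = self._source()
        if ts.cur.is_sym(","):
            raise ts.error("only one source clause per rule is supported")
        targets: list[RuleTarget] = []
        nested: list[MapRule] = []
        dependents: list[tuple] = []
        if ts.cur.is_sym("->"):
            ts.advance()
            targets.append(self._target())
            while ts.cur.is_sym(","):
                ts.advance()
                targets.append(self._target())
        if ts.cur.is_ident("then"):
            ts.advance()
            if ts.cur.is_sym("{"):
                ts.advance()
                while not ts.cur.is_sym("}"):
                    nested.append(self._rule(f"{gid}_r{idx}", len(nested) + 1))
                ts.expect_sym("}")
            else:
                dependents.append(self._dependent())
                while ts.cur.is_sym(","):
                    ts.advance()
                    dependents.append(self._dependent())
        name = None
        if ts.cur.kind == "DQSTRING":
            name = ts.advance().value
        ts.expect_sym(";")
        return MapRule(name, (source,), tuple(targets), tuple(nested),
                       tuple(dependents), rule_id=f"{gid}_r{idx}")

    def _segment(self) -> str:
        t = self.ts.cur
        if t.kind in ("IDENT", "DQSTRING"):
            return self.ts.advance().value
        raise self.ts.error(f"expected element name, found {t.value or t.kind!r}")

    def _source(self) -> RuleSource:
        ts = self.ts
        context = ts.expect_ident().value
        element = declared_type = variable = list_mode = None
        condition = check = None
        default_value = None
        if ts.cur.is_sym("."):
            ts.advance()
            element = self._segment()
        if ts.cur.is_sym(":"):
            ts.advance()
            declared_type = ts.expect_ident().value
        while True:
            t = ts.cur
            if t.is_ident("default") and default_value is None:
                ts.advance()
                default_value = self._literal()
            elif t.kind == "IDENT" and t.value in LIST_MODES and list_mode is None:
                list_mode = ts.advance().value
            elif t.is_ident("as") and variable is None:
                ts.advance()
                variable = ts.expect_ident().value
            elif t.is_ident("where") and condition is None:
                ts.advance()
                condition = self._inline_fp()
            elif t.is_ident("check") and check is None:
                ts.advance()
                check = self._inline_fp()
            else:
                break
        return RuleSource(context, element, declared_type, variable,
                          condition, check, list_mode, default_value)

    def _inline_fp(self) -> FPExpr:
        ts = self.ts
        start = ts.pos
        if ts.cur.kind == "STRING":  # quoted FHIRPath
            text = ts.advance().value
            return FPExpr.parse(text)
        ast = FhirPathParser(ts).parse()
        text = _tokens_text(ts.tokens[start:ts.pos])
        return FPExpr(text, ast)

    def _literal(self):
        t = self.ts.cur
        if t.kind == "STRING":
            return Param("string", self.ts.advance().value)
        if t.kind == "NUMBER":
            v = self.ts.advance().value
            return Param("decimal", v) if "." in v else Param("integer", int(v))
        if t.is_ident("true", "false"):
            return Param("boolean", self.ts.advance().value == "true")
        raise self.ts.error(f"expected literal, found {t.value or t.kind!r}")

    def _target(self) -> RuleTarget:
        ts = self.ts
        context = element = variable = transform = None
        params: tuple = ()
        # transform-only target: e.g. `create('X') as v`
        if (ts.cur.kind == "IDENT" and ts.cur.value in TRANSFORMS
                and ts.peek().is_sym("(")):
            transform, params = self._invocation()
        else:
            if ts.cur.kind == "IDENT" and ts.peek().is_sym("("):
                # call syntax with an unknown transform keyword
                raise UnsupportedTransformError(ts.cur.value, ts.cur.line, ts.cur.col)
            context = ts.expect_ident().value
            if ts.cur.is_sym("."):
                ts.advance()
                element = self._segment()
            if ts.cur.is_sym("="):
                ts.advance()
                t = ts.cur
                if t.kind == "IDENT" and ts.peek().is_sym("("):
                    if t.value not in TRANSFORMS:
                        raise UnsupportedTransformError(t.value, t.line, t.col)
                    transform, params = self._invocation()
                elif t.kind == "IDENT" and not t.is_ident("true", "false"):
                    transform = "copy"
                    params = (Param("var", ts.advance().value),)
                else:
                    transform = "copy"
                    params = (self._literal(),)
        if ts.cur.is_ident("as"):
            ts.advance()
            variable = ts.expect_ident().value
        list_mode_share = None
        if ts.cur.is_ident("share"):
            ts.advance()
            list_mode_share = ts.expect_ident().value
        return RuleTarget(context, element, variable, transform, params,
                          list_mode_share)

    def _invocation(self):
        ts = self.ts
        name = ts.expect_ident().value
        ts.expect_sym("(")
        params: list[Param] = []
        while not ts.cur.is_sym(")"):
            if params:
                ts.expect_sym(",")
            params.append(self._param(name, len(params)))
        ts.expect_sym(")")
        return name, tuple(params)

    def _param(self, transform: str, index: int) -> Param:
        ts = self.ts
        t = ts.cur
        if transform == "evaluate" and index >= 1:
            return Param("fp", self._inline_fp())
        if t.kind == "STRING":
            return Param("string", ts.advance().value)
        if t.kind == "NUMBER" or t.is_sym("-"):
            if t.is_sym("-"):
                ts.advance()
                v = "-" + ts.advance().value
            else:
                v = ts.advance().value
            return Param("decimal", v) if "." in v else Param("integer", int(v))
        if t.is_ident("true", "false"):
            return Param("boolean", ts.advance().value == "true")
        if t.kind == "IDENT":
            return Param("var", ts.advance().value)
        raise ts.error(f"expected parameter, found {t.value or t.kind!r}")

    def _dependent(self):
        ts = self.ts
        name = ts.expect_ident().value
        ts.expect_sym("(")
        args = [ts.expect_ident().value]
        while ts.cur.is_sym(","):
            ts.advance()
            args.append(ts.expect_ident().value)
        ts.expect_sym(")")
        return (name, tuple(args))


def _tokens_text(tokens) -> str:
    """Reconstruct canonical expression text from tokens (for inline FHIRPath)."""
    parts: list[str] = []
    for t in tokens:
        if t.kind == "STRING":
            v = t.value.replace("\\", "\\\\").replace("'", "\\'")
            parts.append(f"'{v}'")
        elif t.kind == "DQSTRING":
            parts.append(f'"{t.value}"')
        elif t.kind == "DATE":
            parts.append(f"@{t.value}")
        else:
            parts.append(t.value)
    text = ""
    for i, p in enumerate(parts):
        if text and _needs_space(parts[i - 1], p):
            text += " "
        text += p
    return text


def _needs_space(prev: str, cur: str) -> bool:
    wordish = ("and", "or", "xor", "implies", "div", "mod", "is", "as")
    if prev in wordish or cur in wordish:
        return True
    if prev[-1:].isalnum() and cur[:1].isalnum():
        return True
    return False


def parse_fml(fml_text: str) -> StructureMapAST:
    """Parse FML text (supported grammar subset) into a StructureMapAST."""
    return _FmlParser(fml_text).parse_map()


# ---------------------------------------------------------------------------
# StructureMap resource serialization
# ---------------------------------------------------------------------------

_PARAM_KEYS = {"string": "valueString", "integer": "valueInteger",
               "decimal": "valueDecimal", "boolean": "valueBoolean",
               "var": "valueId"}


def _param_jsonable(p: Param):
    if p.kind == "fp":
        return ("valueString", p.value.text)
    if p.kind == "decimal":
        return ("valueDecimal", _Raw(str(p.value)))
    if p.kind == "boolean":
        return ("valueBoolean", bool(p.value))
    if p.kind == "integer":
        return ("valueInteger", _Raw(str(p.value)))
    return (_PARAM_KEYS[p.kind], p.value)


def _ast_jsonable(ast: StructureMapAST) -> _Obj:
    pairs: list = [("resourceType", "StructureMap")]
    if ast.concept_maps:
        pairs.append(("contained", [_cm_jsonable(cm) for cm in ast.concept_maps]))
    pairs.append(("url", ast.url))
    pairs.append(("name", ast.name))
    if ast.uses_declarations:
        pairs.append(("structure", [
            _Obj([("url", u)] + ([("alias", a)] if a else []) + [("mode", m)])
            for u, a, m in ast.uses_declarations]))
    if ast.imports:
        pairs.append(("import", list(ast.imports)))
    pairs.append(("group", [_group_jsonable(g) for g in ast.groups]))
    return _Obj(pairs)


def _cm_jsonable(cm: ConceptMapDef) -> _Obj:
    return _Obj([
        ("resourceType", "ConceptMap"),
        ("url", cm.url),
        ("group", [
            _Obj([
                ("source", g.source_system),
                ("target", g.target_system),
                ("element", [
                    _Obj([("code", e.source_code),
                          ("target", [_Obj([("code", e.target_code),
                                            ("relationship", e.relationship)])])])
                    for e in g.elements]),
            ]) for g in cm.groups]),
    ])


def _group_jsonable(g: MapGroup) -> _Obj:
    pairs: list = [("name", g.name)]
    if g.extends:
        pairs.append(("extends", g.extends))
    pairs.append(("typeMode", g.type_mode))
    pairs.append(("input", [
        _Obj([("name", n)] + ([("type", t)] if t else []) + [("mode", m)])
        for n, t, m in g.inputs]))
    pairs.append(("rule", [_rule_jsonable(r) for r in g.rules]))
    return _Obj(pairs)


def _rule_jsonable(r: MapRule) -> _Obj:
    pairs: list = []
    if r.name is not None:
        pairs.append(("name", r.name))
    pairs.append(("source", [_source_jsonable(s) for s in r.sources]))
    if r.targets:
        pairs.append(("target", [_target_jsonable(t) for t in r.targets]))
    if r.nested_rules:
        pairs.append(("rule", [_rule_jsonable(n) for n in r.nested_rules]))
    if r.dependent_calls:
        pairs.append(("dependent", [
            _Obj([("name", name),
                  ("parameter", [_Obj([("valueId", a)]) for a in args])])
            for name, args in r.dependent_calls]))
    return _Obj(pairs)


def _source_jsonable(s: RuleSource) -> _Obj:
    pairs: list = [("context", s.context)]
    if s.element:
        pairs.append(("element", s.element))
    if s.declared_type:
        pairs.append(("type", s.declared_type))
    if s.default_value is not None:
        key, val = _param_jsonable(s.default_value)
        pairs.append(("defaultValue" + key[5:], val))
    if s.list_mode:
        pairs.append(("listMode", s.list_mode))
    if s.variable:
        pairs.append(("variable", s.variable))
    if s.condition:
        pairs.append(("condition", s.condition.text))
    if s.check:
        pairs.append(("check", s.check.text))
    return _Obj(pairs)


def _target_jsonable(t: RuleTarget) -> _Obj:
    pairs: list = []
    if t.context:
        pairs.append(("context", t.context))
    if t.element:
        pairs.append(("element", t.element))
    if t.variable:
        pairs.append(("variable", t.variable))
    if t.list_mode_share:
        pairs.append(("listMode", [ "share" ]))
        pairs.append(("listRuleId", t.list_mode_share))
    if t.transform:
        pairs.append(("transform", t.transform))
        if t.parameters:
            pairs.append(("parameter", [
                _Obj([_param_jsonable(p)]) for p in t.parameters]))
    return _Obj(pairs)


def serialize_structuremap(ast: StructureMapAST, fmt: str = "json") -> str:
    """Serialize the AST to a StructureMap resource; deterministic output."""
    if fmt == "json":
        return _dump_json(_ast_jsonable(ast), 0) + "\n"
    if fmt == "xml":
        out: list[str] = ['<?xml version="1.0" encoding="UTF-8"?>']
        out.append(f'<StructureMap xmlns="{FHIR_NS}">')
        for k, v in _ast_jsonable(ast).pairs:
            if k == "resourceType":
                continue
            _value_to_xml(k, v, 1, out)
        out.append("</StructureMap>")
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def _value_to_xml(key: str, v, depth: int, out: list[str]):
    ind = "  " * depth
    items = v if isinstance(v, list) else [v]
    for item in items:
        if isinstance(item, _Obj):
            if key == "contained":
                out.append(f"{ind}<contained>")
                rtype = dict(item.pairs).get("resourceType")
                sub = _Obj([(k2, v2) for k2, v2 in item.pairs if k2 != "resourceType"])
                out.append(f"{ind}  <{rtype}>")
                for k2, v2 in sub.pairs:
                    _value_to_xml(k2, v2, depth + 2, out)
                out.append(f"{ind}  </{rtype}>")
                out.append(f"{ind}</contained>")
            else:
                out.append(f"{ind}<{key}>")
                for k2, v2 in item.pairs:
                    _value_to_xml(k2, v2, depth + 1, out)
                out.append(f"{ind}</{key}>")
        else:
            if isinstance(item, _Raw):
                text = item.text
            elif isinstance(item, bool):
                text = "true" if item else "false"
            else:
                text = str(item)
            from xml.sax.saxutils import quoteattr

            out.append(f"{ind}<{key} value={quoteattr(text)}/>")


# ---------------------------------------------------------------------------
# StructureMap resource parsing
# ---------------------------------------------------------------------------

def parse_structuremap(doc_text: str, fmt: str) -> StructureMapAST:
    """Parse a StructureMap resource (XML or JSON) into the same AST shape
    that :func:`parse_fml` produces; raw FHIRPath strings are parsed here."""
    data = _resource_to_dict(doc_text, fmt)
    if data.get("resourceType") != "StructureMap":
        raise UnsupportedFeatureError(
            f"expected StructureMap, found {data.get('resourceType')!r}")
    known = {"resourceType", "contained", "url", "name", "structure", "import",
             "group"}
    for k in data:
        if k not in known:
            raise UnsupportedFeatureError(f"unsupported StructureMap element {k!r}")
    cms = tuple(parse_conceptmap_dict(c) for c in data.get("contained", []))
    uses = tuple((s["url"], s.get("alias"), s["mode"])
                 for s in data.get("structure", []))
    imports = tuple(data.get("import", []))
    groups = tuple(_group_from_dict(g) for g in data.get("group", []))
    ast = StructureMapAST(data.get("url", ""), data.get("name", ""), uses,
                          imports, cms, groups)
    return ast


def _group_from_dict(g: dict) -> MapGroup:
    counters = {"n": 0}
    gid = f"g{g.get('name', '')}"
    rules = tuple(_rule_from_dict(r, gid, i + 1)
                  for i, r in enumerate(g.get("rule", [])))
    return MapGroup(
        g["name"], g.get("typeMode", "none"),
        tuple((i["name"], i.get("type"), i["mode"]) for i in g.get("input", [])),
        rules, g.get("extends"))


def _rule_from_dict(r: dict, gid: str, idx: int) -> MapRule:
    rid = f"{gid}_r{idx}"
    sources = tuple(_source_from_dict(s) for s in r.get("source", []))
    if len(sources) != 1:
        raise UnsupportedFeatureError("exactly one source clause per rule is supported")
    targets = tuple(_target_from_dict(t) for t in r.get("target", []))
    nested = tuple(_rule_from_dict(n, rid, i + 1)
                   for i, n in enumerate(r.get("rule", [])))
    dependents = tuple(
        (d["name"], tuple(p["valueId"] for p in d.get("parameter", [])))
        for d in r.get("dependent", []))
    return MapRule(r.get("name"), sources, targets, nested, dependents,
                   rule_id=rid)


def _source_from_dict(s: dict) -> RuleSource:
    default = None
    for k, v in s.items():
        if k.startswith("defaultValue"):
            kind = k[len("defaultValue"):].lower()
            if kind == "string":
                default = Param("string", v)
            elif kind == "integer":
                default = Param("integer", int(str(v)))
            elif kind == "decimal":
                default = Param("decimal", str(v))
            elif kind == "boolean":
                default = Param("boolean", v in (True, "true"))
            else:
                raise UnsupportedFeatureError(f"unsupported default value kind {k!r}")
    return RuleSource(
        s["context"], s.get("element"), s.get("type"), s.get("variable"),
        FPExpr.parse(s["condition"]) if s.get("condition") else None,
        FPExpr.parse(s["check"]) if s.get("check") else None,
        s.get("listMode"), default)


def _target_from_dict(t: dict) -> RuleTarget:
    transform = t.get("transform")
    if transform is not None and transform not in TRANSFORMS:
        raise UnsupportedTransformError(transform)
    params: list[Param] = []
    raw_params = t.get("parameter", [])
    for i, p in enumerate(raw_params):
        if "valueId" in p:
            params.append(Param("var", p["valueId"]))
        elif "valueString" in p:
            if transform == "evaluate" and i >= 1:
                params.append(Param("fp", FPExpr.parse(p["valueString"])))
            else:
                params.append(Param("string", p["valueString"]))
        elif "valueInteger" in p:
            params.append(Param("integer", int(str(p["valueInteger"]))))
        elif "valueDecimal" in p:
            params.append(Param("decimal", str(p["valueDecimal"])))
        elif "valueBoolean" in p:
            v = p["valueBoolean"]
            params.append(Param("boolean", v in (True, "true")))
        else:
            raise UnsupportedFeatureError(f"unsupported parameter {p!r}")
    share = None
    if t.get("listMode") == ["share"] or t.get("listMode") == "share":
        share = t.get("listRuleId")
    return RuleTarget(t.get("context"), t.get("element"), t.get("variable"),
                      transform, tuple(params), share)


# -- ConceptMap resources ----------------------------------------------------

def parse_conceptmap_dict(data: dict) -> ConceptMapDef:
    if data.get("resourceType") != "ConceptMap":
        raise UnsupportedFeatureError(
            f"expected ConceptMap, found {data.get('resourceType')!r}")
    groups = []
    for g in data.get("group", []):
        elements = []
        for e in g.get("element", []):
            for tgt in e.get("target", []):
                rel = tgt.get("relationship", "equivalent")
                if rel not in RELATIONSHIPS:
                    raise UnsupportedFeatureError(f"unsupported relationship {rel!r}")
                elements.append(CMElement(e["code"], rel, tgt["code"]))
        groups.append(CMGroup(g.get("source", ""), g.get("target", ""),
                              tuple(elements)))
    return ConceptMapDef(data.get("url", ""), tuple(groups))


def parse_conceptmap(doc_text: str, fmt: str) -> ConceptMapDef:
    return parse_conceptmap_dict(_resource_to_dict(doc_text, fmt))


def serialize_conceptmap(cm: ConceptMapDef, fmt: str = "json") -> str:
    if fmt == "json":
        return _dump_json(_cm_jsonable(cm), 0) + "\n"
    if fmt == "xml":
        out: list[str] = ['<?xml version="1.0" encoding="UTF-8"?>']
        jz = _cm_jsonable(cm)
        out.append(f'<ConceptMap xmlns="{FHIR_NS}">')
        for k, v in jz.pairs:
            if k == "resourceType":
                continue
            _value_to_xml(k, v, 1, out)
        out.append("</ConceptMap>")
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


# -- FHIR XML <-> dict -------------------------------------------------------

#: (parent tag, child tag) pairs that are repeating in the supported subset
_LIST_SPECS = {
    ("StructureMap", "contained"), ("StructureMap", "structure"),
    ("StructureMap", "import"), ("StructureMap", "group"),
    ("group", "input"), ("group", "rule"),
    ("rule", "source"), ("rule", "target"), ("rule", "rule"),
    ("rule", "dependent"),
    ("target", "parameter"), ("dependent", "parameter"),
    ("ConceptMap", "group"), ("group", "element"), ("element", "target"),
}

_INT_KEYS = {"valueInteger"}
_BOOL_KEYS = {"valueBoolean"}


def _resource_to_dict(doc_text: str, fmt: str) -> dict:
    if fmt == "json":
        return json.loads(doc_text, parse_float=str)
    if fmt == "xml":
        root = etree.fromstring(
            doc_text.encode() if isinstance(doc_text, str) else doc_text)
        return _xml_el_to_dict(root)
    raise ValueError(f"unknown format {fmt!r}")


def _xml_el_to_dict(el) -> dict:
    parent = etree.QName(el).localname
    d: dict = {"resourceType": parent}
    for child in el:
        if child.tag is etree.Comment:
            continue
        name = etree.QName(child).localname
        if name == "contained":
            kids = [k for k in child if k.tag is not etree.Comment]
            if len(kids) != 1:
                raise UnsupportedFeatureError("contained must hold one resource")
            value = _xml_el_to_dict(kids[0])
        elif child.get("value") is not None and len(child) == 0:
            raw = child.get("value")
            if name in _INT_KEYS:
                value = int(raw)
            elif name in _BOOL_KEYS:
                value = raw == "true"
            else:
                value = raw
        else:
            sub = _xml_el_to_dict(child)
            sub.pop("resourceType", None)
            value = sub
        if (parent, name) in _LIST_SPECS:
            d.setdefault(name, []).append(value)
        else:
            d[name] = value
    return d


# ---------------------------------------------------------------------------
# Import resolution
# ---------------------------------------------------------------------------

@dataclass
class ImportClosure:
    maps: list
    conceptmaps: list


def load_imports(ast: StructureMapAST, resolver: dict) -> ImportClosure:
    """Resolve the transitive import closure of ``ast`` using a local
    URI -> text mapping.  Cycles and missing URIs are errors."""
    maps: list[StructureMapAST] = []
    conceptmaps: list[ConceptMapDef] = []
    visiting: list[str] = []
    done: set[str] = set()

    def visit(current: StructureMapAST):
        if current.url in visiting:
            raise ImportCycleError(visiting + [current.url])
        if current.url in done:
            return
        visiting.append(current.url)
        maps.append(current)
        for uri in current.imports:
            if uri in visiting:
                raise ImportCycleError(visiting + [uri])
            if uri in done:
                continue
            if uri not in resolver:
                raise ImportError_(f"unresolved import {uri!r}")
            text = resolver[uri]
            stripped = text.lstrip()
            if stripped.startswith("<"):
                root_tag = etree.QName(etree.fromstring(text.encode())).localname
                if root_tag == "ConceptMap":
                    conceptmaps.append(parse_conceptmap(text, "xml"))
                else:
                    visit(parse_structuremap(text, "xml"))
            elif stripped.startswith("{"):
                data = json.loads(text)
                if data.get("resourceType") == "ConceptMap":
                    conceptmaps.append(parse_conceptmap_dict(data))
                else:
                    visit(parse_structuremap(text, "json"))
            else:
                visit(parse_fml(text))
        visiting.pop()
        done.add(current.url)
        for cm in current.concept_maps:
            if cm not in conceptmaps:
                conceptmaps.append(cm)

    visit(ast)
    return ImportClosure(maps, conceptmaps)
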