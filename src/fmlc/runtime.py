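"""Runtime helper layer shipped with generated transformation programs.

Generated programs import this module (conventionally as ``rt``) and nothing
else from the package.  The same helpers back the reference interpreter and
the FHIRPath evaluator, so the compiled and interpreted execution paths share
one semantics and differ only in dispatch.

Contents: execution context (shared timestamp, seeded UUID source, registered
concept maps), cardinality-aware assignment, ConceptMap code translation,
dynamic element access, FHIRPath collection helpers, and the small CLI shim
(`program_main`) that gives every generated program the ``-s/-t`` contract.
"""
from __future__ import annotations

import argparse
import datetime as _dt
import random
import re
import sys
import uuid as _uuid
from decimal import Decimal

from .errors import (
    CardinalityError,
    FhirPathTypeError,
    MapRuntimeError,
    TranslateError,
)
from .schema_models import (
    TEXT_ELEMENT,
    InstanceNode,
    ModelSet,
    parse_schema,
    read_fhir_json,
    read_xml,
    write_fhir_json,
    write_xml,
)

#: packaged fixture schemas addressable by registry name in generated programs
_PACKAGED_SCHEMAS = {
    "mini-cda": ("minicda", "schemas/mini-cda.xsd"),
    "mini-fhir": ("minifhir", "schemas/mini-fhir.xsd"),
}


def _read_packaged(relpath: str) -> str:
    from importlib.resources import files

    return (files("fmlc") / "data" / relpath).read_text()


def load_models(origins: list[str]) -> ModelSet:
    """Load a model set from origin strings.

    An origin is either a packaged registry name (``mini-cda``, ``mini-fhir``)
    or ``family:/path/to/schema.xsd``.
    """
    models = ModelSet()
    for origin in origins:
        if origin in _PACKAGED_SCHEMAS:
            family, rel = _PACKAGED_SCHEMAS[origin]
            models.update(parse_schema(_read_packaged(rel), family=family, origin=origin))
        elif ":" in origin:
            family, path = origin.split(":", 1)
            with open(path) as fh:
                models.update(parse_schema(fh.read(), family=family, origin=origin))
        else:
            raise MapRuntimeError(f"unknown model origin {origin!r}")
    return models.validate()


# ---------------------------------------------------------------------------
# Execution context
# ---------------------------------------------------------------------------

class ExecutionContext:
    """Per-execution state: one timestamp, one UUID stream, concept maps."""

    def __init__(self, models: ModelSet | None = None, conceptmaps=(),
                 seed: int | None = None, now: str | None = None):
        self.models = models
        self.shared_now: str = now or _dt.datetime.now().astimezone().isoformat(
            timespec="seconds")
        self.shared_today: str = self.shared_now[:10]
        self._uuid_rng = random.Random(seed) if seed is not None else None
        self._coding_types = None  # lazy (Coding, system type, code type, slot)
        self.conceptmaps: dict[str, dict] = {}
        for cm in conceptmaps:
            self.register_conceptmap(cm)

    def register_conceptmap(self, cm):
        """Register a ConceptMap given as a dict or any object with
        ``url``/``groups`` attributes (``fml_frontend.ConceptMapDef`` works)."""
        if isinstance(cm, dict):
            url = cm["url"]
            groups = [
                (g["source"], g["target"],
                 [tuple(e) for e in g["elements"]])
                for g in cm["groups"]
            ]
        else:
            url = cm.url
            groups = [
                (g.source_system, g.target_system,
                 [(e.source_code, e.relationship, e.target_code) for e in g.elements])
                for g in cm.groups
            ]
        index: dict[str, list] = {}
        for src_sys, tgt_sys, elements in groups:
            for src_code, rel, tgt_code in elements:
                index.setdefault(src_code, []).append(
                    (src_sys, tgt_sys, tgt_code, rel))
        self.conceptmaps[url] = {"url": url, "groups": groups, "index": index}


def shared_now(ctx: ExecutionContext) -> str:
    """The execution-scoped timestamp (ISO-8601 with timezone offset)."""
    return ctx.shared_now


def new_uuid(ctx: ExecutionContext) -> str:
    """An RFC-4122 v4 UUID; reproducible sequence when the context is seeded."""
    rng = ctx._uuid_rng
    if rng is None:
        return str(_uuid.uuid4())
    b = rng.getrandbits(128)
    return "%08x-%04x-4%03x-%x%03x-%012x" % (
        b >> 96, (b >> 80) & 0xFFFF, (b >> 68) & 0xFFF,
        8 | ((b >> 64) & 3), (b >> 52) & 0xFFF, b & 0xFFFFFFFFFFFF)


def translate_code(ctx: ExecutionContext, code, source_system: str | None,
                   map_url: str, output: str = "code"):
    """Translate ``code`` through a registered ConceptMap.

    Exactly one matching element must exist; unmapped and ambiguous codes are
    runtime errors (no silent pass-through).  ``output`` selects a bare target
    code or a Coding node carrying the target system.
    """
    cm = ctx.conceptmaps.get(map_url)
    if cm is None:
        raise TranslateError(f"ConceptMap {map_url!r} is not registered")
    lex = to_lexical(code)
    matches = cm["index"].get(lex, ())
    if source_system is not None:
        matches = [m for m in matches if m[0] == source_system]
    if not matches:
        raise TranslateError(f"code {lex!r} has no mapping in {map_url!r}")
    if len(matches) > 1:
        raise TranslateError(f"code {lex!r} is ambiguous in {map_url!r}")
    _src_sys, tgt_sys, tgt_code, _rel = matches[0]
    if output == "code":
        return tgt_code
    if output == "Coding":
        types = ctx._coding_types
        if types is None:
            cd = _unique_local(ctx.models, "Coding")
            em = ctx.models.element_map(cd)
            sys_t, code_t = em["system"].type_ref, em["code"].type_ref
            slot = "value" if "value" in ctx.models.element_map(sys_t) else TEXT_ELEMENT
            types = ctx._coding_types = (cd, sys_t, code_t, slot)
        cd, sys_t, code_t, slot = types
        return InstanceNode(cd, {"system": [InstanceNode(sys_t, {slot: [tgt_sys]})],
                                 "code": [InstanceNode(code_t, {slot: [tgt_code]})]})
    raise TranslateError(f"unsupported translate output {output!r}")


def cm_code(table: dict, code, map_url: str) -> str:
    """Static-table code translation used by compiled programs.

    The compiler inlines ConceptMap contents as constant dictionaries; this
    helper preserves the dynamic path's error behavior for unmapped and
    ambiguous codes."""
    lex = to_lexical(code)
    try:
        m = table[lex]
    except KeyError:
        raise TranslateError(f"code {lex!r} has no mapping in {map_url!r}") from None
    if m is None:
        raise TranslateError(f"code {lex!r} is ambiguous in {map_url!r}")
    return m[1]


def cm_coding(table: dict, code, map_url: str, types: tuple) -> InstanceNode:
    """Static-table translation to a Coding node (compiled programs).

    ``types`` carries the statically resolved (Coding type, system type,
    code type, value slot) tuple."""
    lex = to_lexical(code)
    try:
        m = table[lex]
    except KeyError:
        raise TranslateError(f"code {lex!r} has no mapping in {map_url!r}") from None
    if m is None:
        raise TranslateError(f"code {lex!r} is ambiguous in {map_url!r}")
    cd, sys_t, code_t, slot = types
    return InstanceNode(cd, {"system": [InstanceNode(sys_t, {slot: [m[0]]})],
                             "code": [InstanceNode(code_t, {slot: [m[1]]})]})


def _unique_local(models: ModelSet, local: str) -> str:
    hits = [t for t in models.types if t.split(".")[-1] == local]
    if len(hits) != 1:
        raise MapRuntimeError(
            f"type {local!r} is {'ambiguous' if hits else 'unknown'} in the model set")
    return hits[0]


# ---------------------------------------------------------------------------
# Node construction and assignment
# ---------------------------------------------------------------------------

def create(models: ModelSet, qname: str) -> InstanceNode:
    if "." not in qname:
        qname = _unique_local(models, qname)
    d = models.descriptor(qname)  # raises for unknown types
    return InstanceNode(
        qname,
        resource_kind=qname.split(".")[-1] if models.is_resource(qname) else None,
    )


def create_for(models: ModelSet, context_node: InstanceNode, element: str) -> InstanceNode:
    """Create a node of the type the model declares for (context, element);
    run-time counterpart of the compiler's static type resolution."""
    return create(models, models.resolve_element_type(context_node.type_ref, element))


def copy_value(v):
    """Deep copy for nodes; scalars are immutable and pass through."""
    if isinstance(v, InstanceNode):
        return InstanceNode(
            v.type_ref,
            {k: [copy_value(x) for x in vs] for k, vs in v.values.items()},
            v.resource_kind,
        )
    return v


def to_lexical(v) -> str:
    """Lexical string form of a value (primitive nodes unwrap)."""
    if type(v) is str:
        return v
    u = unwrap(v)
    if isinstance(u, InstanceNode):
        raise MapRuntimeError(f"complex value of type {u.type_ref!r} has no lexical form")
    if isinstance(u, bool):
        return "true" if u else "false"
    if isinstance(u, (int, Decimal)):
        return str(u)
    if isinstance(u, dict):
        raise MapRuntimeError("complex value has no lexical form")
    return str(u)


def _coerce_for(value, elem_type: str, models: ModelSet):
    """Fit a raw value (scalar or node) to the declared element type."""
    if elem_type.startswith("xs:"):
        return to_lexical(value)
    d = models.types.get(elem_type)
    if d is None:
        raise MapRuntimeError(f"unknown element type {elem_type!r}")
    if models.is_container(elem_type):
        if isinstance(value, InstanceNode) and models.is_resource(value.type_ref):
            wrapper = InstanceNode(elem_type)
            wrapper.add(value.type_ref.split(".")[-1], value)
            return wrapper
        if isinstance(value, InstanceNode) and value.type_ref == elem_type:
            return value
        raise MapRuntimeError(
            f"cannot place value in resource container {elem_type!r}")
    if d.is_primitive:
        if isinstance(value, InstanceNode) and value.type_ref == elem_type:
            return value
        node = InstanceNode(elem_type)
        slot = "value" if "value" in models.element_map(elem_type) else TEXT_ELEMENT
        node.add(slot, to_lexical(value))
        return node
    if isinstance(value, InstanceNode):
        if value.type_ref == elem_type or _extends(models, value.type_ref, elem_type):
            return value
        raise MapRuntimeError(
            f"cannot assign node of type {value.type_ref!r} to element of type {elem_type!r}")
    raise MapRuntimeError(
        f"cannot assign scalar {value!r} to complex element type {elem_type!r}")


def _extends(models: ModelSet, sub: str, base: str) -> bool:
    d = models.types.get(sub)
    while d is not None and d.base_type:
        if d.base_type == base:
            return True
        d = models.types.get(d.base_type)
    return False


def assign(target: InstanceNode, element: str, value, ctx: ExecutionContext):
    """Cardinality-aware assignment: replace singletons, append to lists.

    The stored (possibly wrapped) value is returned so target variables can
    bind to it.  Assigning a second value to a singleton element replaces the
    first; this is documented behavior, not an error.
    """
    models = ctx.models
    e = models.element_map(target.type_ref).get(element)
    if e is None:
        raise MapRuntimeError(
            f"unknown element {element!r} on type {target.type_ref!r}")
    fitted = _coerce_for(value, e.type_ref, models)
    if e.repeats:
        target.add(element, fitted)
    else:
        target.set(element, fitted)
    # a resource wrapped into a container binds as the resource itself
    if fitted is not value and isinstance(value, InstanceNode) \
            and models.is_container(e.type_ref):
        return value
    return fitted


# specialised fast paths used by compiled programs when the element
# descriptor was resolved statically (dynamic `assign` is the fallback)

def node(type_ref: str, resource_kind: str | None = None) -> InstanceNode:
    """Node constructor for statically resolved types (no model lookups)."""
    return InstanceNode(type_ref, resource_kind=resource_kind)


def prim(type_ref: str, slot: str, lexical: str) -> InstanceNode:
    """Fast primitive-node constructor for statically typed assignments."""
    return InstanceNode(type_ref, {slot: [lexical]})


def add_new(target: InstanceNode, element: str, type_ref: str,
            resource_kind: str | None = None) -> InstanceNode:
    """Append a fresh node of a statically known type to a repeating element."""
    node = InstanceNode(type_ref, resource_kind=resource_kind)
    target.values.setdefault(element, []).append(node)
    return node


def first_or_add(target: InstanceNode, element: str, type_ref: str,
                 resource_kind: str | None = None) -> InstanceNode:
    """Reuse the existing singleton child or create one of the known type."""
    vs = target.values.get(element)
    if vs:
        return vs[0]
    node = InstanceNode(type_ref, resource_kind=resource_kind)
    target.values[element] = [node]
    return node


def set_single(target: InstanceNode, element: str, value):
    target.values[element] = [value]
    return value


def add_item(target: InstanceNode, element: str, value):
    target.values.setdefault(element, []).append(value)
    return value


def wrap_prim(elem_type: str, slot: str, value) -> InstanceNode:
    if isinstance(value, InstanceNode):
        if value.type_ref == elem_type:
            return value
        value = to_lexical(value)
    elif not isinstance(value, str):
        value = to_lexical(value)
    return InstanceNode(elem_type, {slot: [value]})


def wrap_container(container_type: str, resource: InstanceNode) -> InstanceNode:
    return InstanceNode(container_type,
                        {resource.type_ref.split(".")[-1]: [resource]})


def assign_all(target: InstanceNode, element: str, values, ctx: ExecutionContext):
    last = None
    for v in values:
        last = assign(target, element, v, ctx)
    return last


def get_or_create(target: InstanceNode, element: str, ctx: ExecutionContext):
    """Reuse an existing singleton child, otherwise create one of the
    element's declared type (repeating elements always get a fresh node)."""
    models = ctx.models
    e = models.element_map(target.type_ref).get(element)
    if e is None:
        raise MapRuntimeError(
            f"unknown element {element!r} on type {target.type_ref!r}")
    if not e.repeats:
        existing = target.values.get(element)
        if existing:
            return existing[0]
    if e.type_ref.startswith("xs:") or models.is_primitive_model(e.type_ref):
        node = InstanceNode(e.type_ref) if not e.type_ref.startswith("xs:") else ""
    else:
        node = create(models, e.type_ref)
    return assign(target, element, node, ctx)


# ---------------------------------------------------------------------------
# Navigation
# ---------------------------------------------------------------------------

def dynamic_get(node, element: str, models: ModelSet | None = None) -> list:
    """Element access with FHIRPath navigation semantics: unknown elements
    yield an empty collection.  Works on typed nodes and plain JSON dicts."""
    if isinstance(node, InstanceNode):
        return list(node.values.get(element, ()))
    if isinstance(node, dict):
        v = node.get(element)
        if v is None:
            return []
        return list(v) if isinstance(v, list) else [v]
    return []


def get(focus, element: str) -> list:
    """Collection-valued navigation over a collection or a single item."""
    if isinstance(focus, list):
        out: list = []
        for item in focus:
            out.extend(dynamic_get(item, element))
        return out
    return dynamic_get(focus, element)


def iter_items(node, element: str | None = None) -> list:
    if element is None:
        return [node]
    return dynamic_get(node, element)


def only_one(items: list, where: str = "") -> list:
    if len(items) > 1:
        raise CardinalityError(
            f"listMode only_one: {len(items)} items{f' at {where}' if where else ''}")
    return items


def check(result: bool, message: str):
    if not result:
        raise MapRuntimeError(f"check failed: {message}")


# ---------------------------------------------------------------------------
# FHIRPath collection helpers (shared by evaluator and emitted code)
# ---------------------------------------------------------------------------

def dec(lexical: str) -> Decimal:
    return Decimal(lexical)


def as_coll(v) -> list:
    if v is None:
        return []
    return list(v) if isinstance(v, list) else [v]


_NUM_RE = re.compile(r"-?\d+(\.\d+)?([eE][+-]?\d+)?$")


def unwrap(item):
    """Unwrap primitive-model nodes to their lexical string; leave complex
    nodes, dicts and Python scalars alone."""
    if type(item) is str:
        return item
    if isinstance(item, InstanceNode):
        keys = set(item.values)
        if keys and keys <= {"value", TEXT_ELEMENT}:
            vals = item.values.get("value") or item.values.get(TEXT_ELEMENT)
            if vals and len(vals) == 1 and isinstance(vals[0], str):
                return vals[0]
    if isinstance(item, float):
        return Decimal(str(item))
    return item


def _coerce_pair(a, b):
    """Make a comparable pair: lexical strings meet numbers and booleans."""
    if isinstance(a, str) and isinstance(b, (int, Decimal)) and not isinstance(b, bool):
        if _NUM_RE.match(a.strip()):
            a = Decimal(a)
    elif isinstance(b, str) and isinstance(a, (int, Decimal)) and not isinstance(a, bool):
        if _NUM_RE.match(b.strip()):
            b = Decimal(b)
    elif isinstance(a, str) and isinstance(b, bool) and a in ("true", "false"):
        a = a == "true"
    elif isinstance(b, str) and isinstance(a, bool) and b in ("true", "false"):
        b = b == "true"
    return a, b


def _item_eq(x, y) -> bool:
    ux, uy = _coerce_pair(unwrap(x), unwrap(y))
    if isinstance(ux, bool) or isinstance(uy, bool):
        return isinstance(ux, bool) and isinstance(uy, bool) and ux == uy
    if isinstance(ux, (int, Decimal)) and isinstance(uy, (int, Decimal)):
        return Decimal(ux) == Decimal(uy)
    if type(ux) is not type(uy) and not (
            isinstance(ux, InstanceNode) and isinstance(uy, InstanceNode)):
        return False
    return ux == uy


def fp_eq(a: list, b: list) -> list:
    if not a or not b:
        return []
    if len(a) != len(b):
        return [False]
    return [all(_item_eq(x, y) for x, y in zip(a, b))]


def fp_ne(a: list, b: list) -> list:
    r = fp_eq(a, b)
    return [not r[0]] if r else []


def _cmp_pair(a: list, b: list):
    if not a or not b:
        return None
    if len(a) != 1 or len(b) != 1:
        raise FhirPathTypeError("comparison requires singleton operands")
    x, y = _coerce_pair(unwrap(a[0]), unwrap(b[0]))
    if isinstance(x, bool) or isinstance(y, bool):
        raise FhirPathTypeError("booleans are not ordered")
    if isinstance(x, (int, Decimal)) and isinstance(y, (int, Decimal)):
        return Decimal(x), Decimal(y)
    if isinstance(x, str) and isinstance(y, str):
        return x, y
    raise FhirPathTypeError(f"cannot compare {type(x).__name__} with {type(y).__name__}")


def fp_lt(a, b):
    p = _cmp_pair(a, b)
    return [] if p is None else [p[0] < p[1]]


def fp_le(a, b):
    p = _cmp_pair(a, b)
    return [] if p is None else [p[0] <= p[1]]


def fp_gt(a, b):
    p = _cmp_pair(a, b)
    return [] if p is None else [p[0] > p[1]]


def fp_ge(a, b):
    p = _cmp_pair(a, b)
    return [] if p is None else [p[0] >= p[1]]


def _num_pair(a: list, b: list, op: str):
    if not a or not b:
        return None
    if len(a) != 1 or len(b) != 1:
        raise FhirPathTypeError(f"operator {op!r} requires singleton operands")
    x, y = unwrap(a[0]), unwrap(b[0])
    if isinstance(x, str) and _NUM_RE.match(x.strip()):
        x = Decimal(x)
    if isinstance(y, str) and _NUM_RE.match(y.strip()):
        y = Decimal(y)
    if isinstance(x, bool) or isinstance(y, bool) or not isinstance(
            x, (int, Decimal)) or not isinstance(y, (int, Decimal)):
        raise FhirPathTypeError(f"operator {op!r} requires numeric operands")
    return x, y


def _norm_num(v):
    if isinstance(v, Decimal) and v == v.to_integral_value() and v.as_tuple().exponent >= 0:
        return int(v)
    return v


def fp_add(a, b):
    if not a or not b:
        return []
    x, y = unwrap(a[0]) if len(a) == 1 else None, unwrap(b[0]) if len(b) == 1 else None
    if isinstance(x, str) and isinstance(y, str) and not (
            _NUM_RE.match(x.strip()) and _NUM_RE.match(y.strip())):
        return [x + y]
    p = _num_pair(a, b, "+")
    return [_norm_num(p[0] + p[1])]


def fp_sub(a, b):
    p = _num_pair(a, b, "-")
    return [] if p is None else [_norm_num(p[0] - p[1])]


def fp_mul(a, b):
    p = _num_pair(a, b, "*")
    return [] if p is None else [_norm_num(p[0] * p[1])]


def fp_truediv(a, b):
    p = _num_pair(a, b, "/")
    if p is None:
        return []
    if p[1] == 0:
        return []
    return [Decimal(p[0]) / Decimal(p[1])]


def fp_intdiv(a, b):
    p = _num_pair(a, b, "div")
    if p is None:
        return []
    if p[1] == 0:
        return []
    q = Decimal(p[0]) / Decimal(p[1])
    return [int(q.to_integral_value(rounding="ROUND_DOWN"))]


def fp_mod(a, b):
    p = _num_pair(a, b, "mod")
    if p is None:
        return []
    if p[1] == 0:
        return []
    x, y = p
    r = x - y * (Decimal(x) / Decimal(y)).to_integral_value(rounding="ROUND_DOWN")
    return [_norm_num(r)]


def fp_neg(a):
    if not a:
        return []
    p = _num_pair(a, [0], "-")
    return [_norm_num(-p[0])]


def to_bool(coll: list):
    """FHIRPath boolean conversion: empty -> unknown (None)."""
    if not coll:
        return None
    if len(coll) == 1:
        u = unwrap(coll[0])
        if isinstance(u, bool):
            return u
        if isinstance(u, str) and u in ("true", "false"):
            return u == "true"
    return True


def truthy(coll) -> bool:
    if isinstance(coll, bool):
        return coll
    return bool(to_bool(coll))


def _tri(v):
    return [] if v is None else [v]


def fp_and(a, b):
    x, y = to_bool(a), to_bool(b)
    if x is False or y is False:
        return [False]
    if x is True and y is True:
        return [True]
    return []


def fp_or(a, b):
    x, y = to_bool(a), to_bool(b)
    if x is True or y is True:
        return [True]
    if x is False and y is False:
        return [False]
    return []


def fp_xor(a, b):
    x, y = to_bool(a), to_bool(b)
    if x is None or y is None:
        return []
    return [x != y]


def fp_implies(a, b):
    x, y = to_bool(a), to_bool(b)
    if x is False:
        return [True]
    if y is True:
        return [True]
    if x is True:
        return _tri(y)
    return []  # x unknown, y not true


def fp_not(a):
    x = to_bool(a)
    return [] if x is None else [not x]


def fp_concat(a, b):
    xs = "" if not a else to_lexical(a[0]) if len(a) == 1 else None
    ys = "" if not b else to_lexical(b[0]) if len(b) == 1 else None
    if xs is None or ys is None:
        raise FhirPathTypeError("'&' requires singleton or empty operands")
    return [xs + ys]


def fp_union(a, b):
    out = list(a)
    for item in b:
        if not any(_item_eq(item, x) for x in out):
            out.append(item)
    return out


def where(coll: list, pred) -> list:
    return [item for item in coll if pred(item)]


def select(coll: list, f) -> list:
    out: list = []
    for item in coll:
        out.extend(f(item))
    return out


def fp_index(coll: list, idx: list) -> list:
    if not idx:
        return []
    i = unwrap(idx[0])
    if isinstance(i, str):
        i = int(i)
    if not isinstance(i, int) or isinstance(i, bool):
        raise FhirPathTypeError("indexer requires an integer")
    if i < 0 or i >= len(coll):
        return []
    return [coll[i]]


def fp_contains(focus: list, arg: list) -> list:
    if not focus:
        return []
    s, sub = to_lexical(focus[0]), to_lexical(arg[0]) if arg else ""
    return [sub in s]


def fp_startswith(focus: list, arg: list) -> list:
    if not focus:
        return []
    return [to_lexical(focus[0]).startswith(to_lexical(arg[0]) if arg else "")]


def fp_substring(focus: list, start: list, length: list | None = None) -> list:
    if not focus or not start:
        return []
    s = to_lexical(focus[0])
    i = int(unwrap(start[0]))
    if i < 0 or i >= len(s):
        return []
    if length is None:
        return [s[i:]]
    ln = int(unwrap(length[0]))
    if ln < 0:
        return []
    return [s[i:i + ln]]


def fp_tostring(focus: list) -> list:
    if not focus:
        return []
    return [to_lexical(focus[0])]


def fp_tointeger(focus: list) -> list:
    if not focus:
        return []
    u = unwrap(focus[0])
    if isinstance(u, bool):
        return [1 if u else 0]
    if isinstance(u, int):
        return [u]
    if isinstance(u, str) and re.match(r"[+-]?\d+$", u.strip()):
        return [int(u)]
    return []


_TYPE_ALIASES = {
    "string": "string", "String": "string",
    "integer": "integer", "Integer": "integer",
    "decimal": "decimal", "Decimal": "decimal",
    "boolean": "boolean", "Boolean": "boolean",
}


def _item_is(item, type_name: str) -> bool:
    if isinstance(item, InstanceNode):
        return item.type_ref.split(".")[-1] == type_name
    u = unwrap(item)
    alias = _TYPE_ALIASES.get(type_name)
    if alias == "string":
        return isinstance(u, str)
    if alias == "integer":
        return isinstance(u, int) and not isinstance(u, bool)
    if alias == "decimal":
        return isinstance(u, (int, Decimal)) and not isinstance(u, bool)
    if alias == "boolean":
        return isinstance(u, bool)
    return False


def fp_is(coll: list, type_name: str) -> list:
    if not coll:
        return []
    if len(coll) != 1:
        raise FhirPathTypeError("'is' requires a singleton operand")
    return [_item_is(coll[0], type_name)]


def fp_as(coll: list, type_name: str) -> list:
    return [item for item in coll if _item_is(item, type_name)]


# ---------------------------------------------------------------------------
# Transform helpers
# ---------------------------------------------------------------------------

def str_concat(parts) -> str:
    return "".join(to_lexical(p) for p in parts)


_CAST_TABLE = {
    ("string", "integer"), ("integer", "string"),
    ("string", "decimal"), ("decimal", "string"),
    ("string", "boolean"), ("boolean", "string"),
    ("dateTime", "date"), ("date", "dateTime"), ("date", "string"),
    ("dateTime", "string"), ("string", "date"), ("string", "dateTime"),
}


def cast_value(v, target_kind: str):
    """Lexical conversion between primitive kinds per the fixed cast table."""
    lex = to_lexical(v)
    if target_kind == "integer":
        try:
            return int(lex)
        except ValueError:
            raise MapRuntimeError(f"cannot cast {lex!r} to integer") from None
    if target_kind == "decimal":
        # validated but lexically preserved: decimals never pass through
        # floats, and NaN/Infinity spellings are rejected
        if not _NUM_RE.match(lex):
            raise MapRuntimeError(f"cannot cast {lex!r} to decimal")
        return lex.strip()
    if target_kind == "boolean":
        if lex in ("true", "false"):
            return lex == "true"
        raise MapRuntimeError(f"cannot cast {lex!r} to boolean")
    if target_kind == "date":
        return lex[:10]  # dateTime -> date widening
    if target_kind in ("string", "dateTime"):
        return lex
    raise MapRuntimeError(f"unsupported cast target {target_kind!r}")


def truncate(v, length) -> str:
    n = int(unwrap(length)) if not isinstance(length, int) else length
    return to_lexical(v)[:n]


def make_cc(ctx: ExecutionContext, *params):
    """cc(text) or cc(system, code): build a CodeableConcept node."""
    cc = create(ctx.models, _unique_local(ctx.models, "CodeableConcept"))
    if len(params) == 1:
        assign(cc, "text", params[0], ctx)
    elif len(params) == 2:
        assign(cc, "coding", make_coding(ctx, params[0], params[1]), ctx)
    else:
        raise MapRuntimeError("cc takes 1 or 2 parameters")
    return cc


def make_coding(ctx: ExecutionContext, system, code, display=None):
    """c(system, code[, display]): build a Coding node."""
    coding = create(ctx.models, _unique_local(ctx.models, "Coding"))
    assign(coding, "system", system, ctx)
    assign(coding, "code", code, ctx)
    if display is not None:
        assign(coding, "display", display, ctx)
    return coding


# ---------------------------------------------------------------------------
# Program I/O shim
# ---------------------------------------------------------------------------

def read_instance(path: str, models: ModelSet, root_type: str):
    with open(path) as fh:
        text = fh.read()
    if path.endswith(".xml"):
        return read_xml(text, models, root_type)
    if path.endswith(".json"):
        return read_fhir_json(text, models, root_type)
    raise MapRuntimeError(f"cannot infer format from extension of {path!r}")


def write_instance(node: InstanceNode, models: ModelSet, path: str):
    if path.endswith(".xml"):
        text = write_xml(node, models)
    elif path.endswith(".json"):
        text = write_fhir_json(node, models)
    else:
        raise MapRuntimeError(f"cannot infer format from extension of {path!r}")
    with open(path, "w") as fh:
        fh.write(text)


def program_main(argv, models: ModelSet, conceptmaps, source_root: str,
                 target_root: str, transform) -> int:
    """Shared entry point for generated programs: ``-s <source> -t <target>``."""
    ap = argparse.ArgumentParser()
    ap.add_argument("-s", required=True, dest="source")
    ap.add_argument("-t", required=True, dest="target")
    ap.add_argument("--seed", type=int, default=None)
    ap.add_argument("--now", default=None)
    try:
        args = ap.parse_args(argv)
    except SystemExit:
        return 2
    try:
        ctx = ExecutionContext(models=models, conceptmaps=conceptmaps,
                               seed=args.seed, now=args.now)
        src = read_instance(args.source, models, source_root)
        tgt = transform(ctx, src)
        write_instance(tgt, models, args.target)
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        print(f"error: {exc}", file=sys.stderr)
        return 4
    return 0
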