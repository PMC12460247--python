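"""Typed data models derived from a restricted XML-Schema dialect.

A :class:`ModelSet` is the compiler's only type oracle: it is parsed from one
or more XSD files (sequence / choice / attribute / extension / simpleContent
subset) and drives exact XML and FHIR-style-JSON readers and writers for
:class:`InstanceNode` trees.

Conventions
-----------
* Type names are qualified as ``family.Local`` where the *family* is a short
  name for one schema document (e.g. ``minicda``, ``minifhir``).  XSD builtin
  simple types keep their ``xs:`` prefix.
* FHIR-style primitive types are complex types with a single ``value``
  attribute; the XSD type of that attribute decides how the JSON writer
  renders the value (string / boolean / integer / decimal).
* Text content of a ``simpleContent`` type is stored under the reserved
  element name ``_text``.
* Decimals are kept in their lexical form end to end; no value ever passes
  through binary floating point.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from lxml import etree
from xml.sax.saxutils import escape, quoteattr

from .errors import (
    InstanceParseError,
    NamespaceError,
    SchemaError,
    SchemaUnsupportedError,
    SerializationError,
    TypeResolutionError,
)

XS_NS = "http://www.w3.org/2001/XMLSchema"

#: marker for maxOccurs="unbounded"
UNBOUNDED = None

TEXT_ELEMENT = "_text"

_XS_KIND = {
    "xs:string": "string",
    "xs:anyURI": "string",
    "xs:ID": "string",
    "xs:date": "string",
    "xs:dateTime": "string",
    "xs:time": "string",
    "xs:token": "string",
    "xs:boolean": "boolean",
    "xs:integer": "integer",
    "xs:int": "integer",
    "xs:positiveInt": "integer",
    "xs:nonNegativeInteger": "integer",
    "xs:decimal": "decimal",
}


@dataclass(frozen=True)
class ElementDescriptor:
    name: str
    type_ref: str
    min_occurs: int = 0
    max_occurs: int | None = 1  # None == UNBOUNDED
    kind: str = "element"  # element | attribute | text
    choice_group: str | None = None

    def __post_init__(self):
        if self.max_occurs is not None and self.min_occurs > self.max_occurs:
            raise SchemaError(
                f"element {self.name!r}: minOccurs {self.min_occurs} > maxOccurs {self.max_occurs}"
            )

    @property
    def repeats(self) -> bool:
        return self.max_occurs is None or self.max_occurs > 1


@dataclass
class ModelDescriptor:
    type_name: str
    namespace: str
    base_type: str | None = None
    is_primitive: bool = False
    elements: list[ElementDescriptor] = field(default_factory=list)

    def __post_init__(self):
        if sum(1 for e in self.elements if e.kind == "text") > 1:
            raise SchemaError(f"type {self.type_name!r}: more than one text-content element")


class InstanceNode:
    """In-memory typed document tree.

    ``values`` maps element names to ordered lists of children, each child an
    :class:`InstanceNode` or a lexical string (for XSD simple-typed values).
    A plain ``__slots__`` class rather than a dataclass: transformation and
    serialization construct these in tight loops.
    """

    __slots__ = ("type_ref", "values", "resource_kind")

    def __init__(self, type_ref: str, values: dict | None = None,
                 resource_kind: str | None = None):
        self.type_ref = type_ref
        self.values = values if values is not None else {}
        self.resource_kind = resource_kind

    def get(self, name: str) -> list:
        return self.values.get(name, [])

    def add(self, name: str, value):
        self.values.setdefault(name, []).append(value)

    def set(self, name: str, value):
        self.values[name] = [value]

    def __eq__(self, other):
        return (isinstance(other, InstanceNode)
                and self.type_ref == other.type_ref
                and self.values == other.values
                and self.resource_kind == other.resource_kind)

    def __hash__(self):
        return hash(self.type_ref)

    def __repr__(self):
        return f"InstanceNode({self.type_ref!r}, {self.values!r})"


class ModelSet:
    """A resolved set of model descriptors from one or more schema documents."""

    def __init__(self):
        self.types: dict[str, ModelDescriptor] = {}
        #: (family, element name) -> type qname for top-level xs:element decls
        self.roots: dict[tuple[str, str], str] = {}
        #: family -> namespace URI, in declaration order
        self.families: dict[str, str] = {}
        #: origin strings (file paths or registry names) for program embedding
        self.origins: list[str] = []
        self._elem_cache: dict[str, dict[str, ElementDescriptor]] = {}
        self._flag_cache: dict[tuple[str, str], object] = {}
        self._json_plans: dict[str, tuple] = {}

    def _invalidate(self):
        self._elem_cache.clear()
        self._flag_cache.clear()
        self._json_plans.clear()

    # -- construction --------------------------------------------------------

    def add_descriptor(self, d: ModelDescriptor):
        if d.type_name in self.types:
            raise SchemaError(f"duplicate type name {d.type_name!r}")
        self.types[d.type_name] = d
        self._invalidate()

    def update(self, other: "ModelSet") -> "ModelSet":
        for d in other.types.values():
            self.add_descriptor(d)
        self.roots.update(other.roots)
        for fam, ns in other.families.items():
            self.families.setdefault(fam, ns)
        self.origins.extend(o for o in other.origins if o not in self.origins)
        return self

    def validate(self):
        """Check that every type reference resolves; dangling refs are errors."""
        for d in self.types.values():
            if d.base_type and d.base_type not in self.types:
                raise TypeResolutionError(
                    f"type {d.type_name!r}: dangling base type {d.base_type!r}"
                )
            for e in d.elements:
                if not e.type_ref.startswith("xs:") and e.type_ref not in self.types:
                    raise TypeResolutionError(
                        f"type {d.type_name!r}, element {e.name!r}: "
                        f"dangling type reference {e.type_ref!r}"
                    )
        return self

    # -- lookups -------------------------------------------------------------

    def descriptor(self, qname: str) -> ModelDescriptor:
        try:
            return self.types[qname]
        except KeyError:
            raise TypeResolutionError(f"unknown type {qname!r}") from None

    def effective_elements(self, qname: str) -> list[ElementDescriptor]:
        """Elements of ``qname`` including inherited ones, base elements first."""
        d = self.descriptor(qname)
        if d.base_type:
            return self.effective_elements(d.base_type) + list(d.elements)
        return list(d.elements)

    def element_map(self, qname: str) -> dict[str, ElementDescriptor]:
        m = self._elem_cache.get(qname)
        if m is None:
            m = {e.name: e for e in self.effective_elements(qname)}
            self._elem_cache[qname] = m
        return m

    def resolve_element_type(self, context_type: str, element: str) -> str:
        """Declared type of ``element`` on ``context_type`` (base chain walked).

        Choice members resolve only by their concrete name; the abstract
        choice-group name is not addressable.
        """
        e = self.element_map(context_type).get(element)
        if e is None:
            raise TypeResolutionError(
                f"no element {element!r} on type {context_type!r}",
                candidates=tuple(self.element_map(context_type)),
            )
        return e.type_ref

    def is_primitive_model(self, qname: str) -> bool:
        if qname.startswith("xs:"):
            return True
        d = self.types.get(qname)
        return d is not None and d.is_primitive

    def primitive_value_kind(self, qname: str) -> str | None:
        """JSON kind (string/boolean/integer/decimal) of a primitive model type."""
        key = ("pk", qname)
        if key in self._flag_cache:
            return self._flag_cache[key]  # type: ignore[return-value]
        kind: str | None
        if qname.startswith("xs:"):
            kind = _XS_KIND.get(qname, "string")
        else:
            d = self.types.get(qname)
            if d is None or not d.is_primitive:
                kind = None
            else:
                kind = "string"
                for e in self.effective_elements(qname):
                    if e.name in ("value", TEXT_ELEMENT):
                        kind = _XS_KIND.get(e.type_ref, "string")
                        break
        self._flag_cache[key] = kind
        return kind

    def is_resource(self, qname: str) -> bool:
        """True when the type derives (transitively) from a type named Resource."""
        key = ("res", qname)
        if key in self._flag_cache:
            return self._flag_cache[key]  # type: ignore[return-value]
        result = False
        d = self.types.get(qname)
        while d is not None:
            if d.type_name.split(".")[-1] == "Resource":
                result = True
                break
            d = self.types.get(d.base_type) if d.base_type else None
        self._flag_cache[key] = result
        return result

    def is_container(self, qname: str) -> bool:
        """A resource container: all elements form one choice of resource types."""
        key = ("cont", qname)
        if key in self._flag_cache:
            return self._flag_cache[key]  # type: ignore[return-value]
        d = self.types.get(qname)
        if d is None or not d.elements or d.base_type:
            result = False
        else:
            result = all(
                e.choice_group is not None and self.is_resource(e.type_ref)
                for e in d.elements
            )
        self._flag_cache[key] = result
        return result

    def resource_kind_of(self, qname: str) -> str | None:
        return qname.split(".")[-1] if self.is_resource(qname) else None

    def root_type(self, family: str, element_name: str) -> str:
        try:
            return self.roots[(family, element_name)]
        except KeyError:
            raise TypeResolutionError(
                f"no root element {element_name!r} in family {family!r}"
            ) from None

    def root_element_name(self, qname: str) -> str:
        for (fam, name), t in self.roots.items():
            if t == qname:
                return name
        return qname.split(".")[-1]

    def family_of(self, qname: str) -> str:
        return qname.split(".")[0]

    def namespace_of(self, qname: str) -> str:
        return self.descriptor(qname).namespace


# ---------------------------------------------------------------------------
# XSD parsing
# ---------------------------------------------------------------------------

_SUPPORTED_PARTICLES = {"sequence", "choice", "attribute", "element",
                        "complexType", "simpleType", "complexContent",
                        "simpleContent", "extension", "restriction",
                        "annotation", "documentation", "schema", "enumeration"}


def _loc(el) -> str:
    return f"line {el.sourceline}" if el.sourceline else "?"


def _tag(el) -> str:
    q = etree.QName(el)
    if q.namespace != XS_NS:
        raise SchemaUnsupportedError(el.tag, _loc(el))
    return q.localname


def _family_from_namespace(ns: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "", ns.rsplit("/", 1)[-1].rsplit(":", 1)[-1]).lower() or "model"


def parse_schema(xsd_text: str, family: str | None = None, origin: str | None = None) -> ModelSet:
    """Parse one XSD document (restricted dialect) into a :class:`ModelSet`.

    Unsupported constructs (xs:any, substitution groups, ref=, xs:all, ...)
    raise :class:`SchemaUnsupportedError` naming the construct and location.
    Dangling type references surface via :meth:`ModelSet.validate`.
    """
    root = etree.fromstring(xsd_text.encode() if isinstance(xsd_text, str) else xsd_text)
    if _tag(root) != "schema":
        raise SchemaUnsupportedError(root.tag, _loc(root))
    ns = root.get("targetNamespace", "")
    fam = family or _family_from_namespace(ns)

    models = ModelSet()
    models.families[fam] = ns
    if origin:
        models.origins.append(origin)

    def qualify(type_attr: str) -> str:
        # 'xs:string' stays; unprefixed names belong to this schema's family
        if ":" in type_attr:
            prefix, local = type_attr.split(":", 1)
            uri = root.nsmap.get(prefix)
            if uri == XS_NS:
                return f"xs:{local}"
            if uri == ns:
                return f"{fam}.{local}"
            raise SchemaUnsupportedError(f"foreign type reference {type_attr!r}", _loc(root))
        return f"{fam}.{type_attr}"

    choice_counter = 0

    def parse_occurs(el) -> tuple[int, int | None]:
        mn = int(el.get("minOccurs", "1"))
        mx_raw = el.get("maxOccurs", "1")
        mx = UNBOUNDED if mx_raw == "unbounded" else int(mx_raw)
        return mn, mx

    def parse_element_decl(el, choice_group=None) -> ElementDescriptor:
        for bad in ("ref", "substitutionGroup"):
            if el.get(bad) is not None:
                raise SchemaUnsupportedError(f"element @{bad}", _loc(el))
        name = el.get("name")
        type_attr = el.get("type")
        if name is None or type_attr is None:
            raise SchemaUnsupportedError("anonymous or ref element", _loc(el))
        mn, mx = parse_occurs(el)
        return ElementDescriptor(name, qualify(type_attr), mn, mx, "element", choice_group)

    def parse_attribute_decl(el) -> ElementDescriptor:
        name = el.get("name")
        type_attr = el.get("type", "xs:string")
        use = el.get("use", "optional")
        mn = 1 if use == "required" else 0
        if use == "prohibited":
            raise SchemaUnsupportedError("attribute use=prohibited", _loc(el))
        return ElementDescriptor(name, qualify(type_attr), mn, 1, "attribute")

    def parse_body(ct, elements: list, allow_particles=True):
        nonlocal choice_counter
        for child in ct:
            if child.tag is etree.Comment:
                continue
            t = _tag(child)
            if t == "annotation":
                continue
            if t == "sequence" and allow_particles:
                for sub in child:
                    if sub.tag is etree.Comment:
                        continue
                    st = _tag(sub)
                    if st == "element":
                        elements.append(parse_element_decl(sub))
                    elif st == "choice":
                        choice_counter += 1
                        cg = f"c{choice_counter}"
                        for m in sub:
                            if m.tag is etree.Comment:
                                continue
                            if _tag(m) != "element":
                                raise SchemaUnsupportedError(_tag(m), _loc(m))
                            elements.append(parse_element_decl(m, choice_group=cg))
                    elif st == "annotation":
                        continue
                    else:
                        raise SchemaUnsupportedError(st, _loc(sub))
            elif t == "choice" and allow_particles:
                choice_counter += 1
                cg = f"c{choice_counter}"
                for m in child:
                    if m.tag is etree.Comment:
                        continue
                    if _tag(m) != "element":
                        raise SchemaUnsupportedError(_tag(m), _loc(m))
                    elements.append(parse_element_decl(m, choice_group=cg))
            elif t == "attribute":
                elements.append(parse_attribute_decl(child))
            else:
                raise SchemaUnsupportedError(t, _loc(child))

    def parse_complex_type(ct) -> ModelDescriptor:
        name = ct.get("name")
        if name is None:
            raise SchemaUnsupportedError("anonymous complexType", _loc(ct))
        qname = f"{fam}.{name}"
        elements: list[ElementDescriptor] = []
        base = None
        is_primitive = False
        kids = [k for k in ct if k.tag is not etree.Comment and _tag(k) != "annotation"]
        if len(kids) == 1 and _tag(kids[0]) in ("complexContent", "simpleContent"):
            content = kids[0]
            mode = _tag(content)
            ext = [k for k in content if k.tag is not etree.Comment]
            if len(ext) != 1 or _tag(ext[0]) != "extension":
                raise SchemaUnsupportedError(
                    _tag(ext[0]) if ext else "empty content", _loc(content))
            ext = ext[0]
            base_q = qualify(ext.get("base"))
            if mode == "simpleContent":
                # text content of the base simple type, plus attributes
                if not base_q.startswith("xs:"):
                    raise SchemaUnsupportedError(
                        "simpleContent over non-builtin base", _loc(ext))
                elements.append(ElementDescriptor(TEXT_ELEMENT, base_q, 0, 1, "text"))
                parse_body(ext, elements, allow_particles=False)
            else:
                base = base_q
                parse_body(ext, elements)
        else:
            parse_body(ct, elements)
        # FHIR-style primitive: only a 'value' attribute (plus optional text)
        non_meta = [e for e in elements if e.kind != "text"]
        if (non_meta and all(e.kind == "attribute" for e in non_meta)
                and {e.name for e in non_meta} <= {"value"} and base is None):
            is_primitive = True
        if (len(elements) == 1 and elements[0].kind == "text" and base is None):
            is_primitive = True
        return ModelDescriptor(qname, ns, base, is_primitive, elements)

    def parse_simple_type(st) -> ModelDescriptor:
        name = st.get("name")
        if name is None:
            raise SchemaUnsupportedError("anonymous simpleType", _loc(st))
        kids = [k for k in st if k.tag is not etree.Comment and _tag(k) != "annotation"]
        if len(kids) != 1 or _tag(kids[0]) != "restriction":
            raise SchemaUnsupportedError("simpleType without restriction", _loc(st))
        base_q = qualify(kids[0].get("base"))
        for facet in kids[0]:
            if facet.tag is not etree.Comment and _tag(facet) not in ("enumeration", "annotation"):
                raise SchemaUnsupportedError(_tag(facet), _loc(facet))
        return ModelDescriptor(
            f"{fam}.{name}", ns, None, True,
            [ElementDescriptor(TEXT_ELEMENT, base_q, 0, 1, "text")],
        )

    for child in root:
        if child.tag is etree.Comment:
            continue
        t = _tag(child)
        if t == "annotation":
            continue
        if t == "element":
            if child.get("substitutionGroup") is not None:
                raise SchemaUnsupportedError("element @substitutionGroup", _loc(child))
            name, type_attr = child.get("name"), child.get("type")
            if name is None or type_attr is None:
                raise SchemaUnsupportedError("anonymous root element", _loc(child))
            models.roots[(fam, name)] = qualify(type_attr)
        elif t == "complexType":
            models.add_descriptor(parse_complex_type(child))
        elif t == "simpleType":
            models.add_descriptor(parse_simple_type(child))
        else:
            raise SchemaUnsupportedError(t, _loc(child))
    return models


# ---------------------------------------------------------------------------
# XML reader / writer
# ---------------------------------------------------------------------------

def read_xml(doc_text: str, models: ModelSet, root_type: str | None = None) -> InstanceNode:
    """Parse an XML instance document into a fully typed :class:`InstanceNode`.

    Unknown elements or attributes are errors (valid-input assumption); the
    error message carries an XPath-like location.
    """
    root = etree.fromstring(doc_text.encode() if isinstance(doc_text, str) else doc_text)
    q = etree.QName(root)
    fam = next((f for f, ns in models.families.items() if ns == q.namespace), None)
    if fam is None:
        raise NamespaceError(f"unknown namespace {q.namespace!r}", f"/{q.localname}")
    declared = models.roots.get((fam, q.localname))
    if declared is None:
        raise InstanceParseError(f"unknown root element {q.localname!r}", f"/{q.localname}")
    if root_type is not None and declared != root_type:
        raise InstanceParseError(
            f"root element {q.localname!r} has type {declared!r}, expected {root_type!r}",
            f"/{q.localname}")
    return _read_xml_node(root, declared, models, f"/{q.localname}")


def _read_xml_node(el, qname: str, models: ModelSet, path: str) -> InstanceNode:
    emap = models.element_map(qname)
    node = InstanceNode(qname, resource_kind=qname.split(".")[-1] if models.is_resource(qname) else None)
    for aname, aval in el.attrib.items():
        if aname.startswith("{"):  # namespaced attribute (xsi etc.) unsupported
            raise InstanceParseError(f"unknown attribute {aname!r}", path)
        d = emap.get(aname)
        if d is None or d.kind != "attribute":
            raise InstanceParseError(f"unknown attribute {aname!r}", path)
        node.add(aname, aval)
    text_desc = next((e for e in emap.values() if e.kind == "text"), None)
    text = "".join(el.itertext()) if text_desc is not None and len(el) == 0 else None
    if text_desc is not None:
        if text:
            node.add(TEXT_ELEMENT, text)
    elif el.text and el.text.strip():
        raise InstanceParseError(f"unexpected character data {el.text.strip()!r}", path)
    counts: dict[str, int] = {}
    for child in el:
        if child.tag is etree.Comment:
            continue
        cq = etree.QName(child)
        cpath = f"{path}/{cq.localname}"
        if cq.namespace != models.namespace_of(qname) and cq.namespace is not None:
            # cross-namespace children: match by the declared element's family
            pass
        d = emap.get(cq.localname)
        if d is None or d.kind != "element":
            raise InstanceParseError(f"unknown element {cq.localname!r}", cpath)
        counts[d.name] = counts.get(d.name, 0) + 1
        if d.max_occurs is not None and counts[d.name] > d.max_occurs:
            raise InstanceParseError(
                f"element {d.name!r} occurs more than maxOccurs={d.max_occurs}", cpath)
        if d.type_ref.startswith("xs:"):
            node.add(d.name, child.text or "")
        else:
            node.add(d.name, _read_xml_node(child, d.type_ref, models, cpath))
        if child.tail and child.tail.strip():
            raise InstanceParseError("unexpected mixed content", cpath)
    return node


def write_xml(node: InstanceNode, models: ModelSet) -> str:
    """Serialize an :class:`InstanceNode` to canonical XML.

    Canonical form: UTF-8, LF newlines, 2-space indent, attributes and child
    elements in schema order, self-closing empty elements, deterministic
    namespace prefixes (``ns1, ns2, ...`` in family declaration order).
    """
    root_ns = models.namespace_of(node.type_ref)
    prefixes = {root_ns: ""}
    for fam, ns in models.families.items():
        if ns not in prefixes:
            prefixes[ns] = f"ns{len(prefixes)}"
    used: list[str] = [root_ns]

    def collect(n: InstanceNode):
        ns = models.namespace_of(n.type_ref)
        if ns not in used:
            used.append(ns)
        for vs in n.values.values():
            for v in vs:
                if isinstance(v, InstanceNode):
                    collect(v)

    collect(node)
    out: list[str] = ['<?xml version="1.0" encoding="UTF-8"?>']
    _write_xml_node(node, models.root_element_name(node.type_ref), models, prefixes, 0, out,
                    declare=[(prefixes[ns], ns) for ns in used])
    return "\n".join(out) + "\n"


def _pfx(prefixes, ns):
    p = prefixes[ns]
    return f"{p}:" if p else ""


def _write_xml_node(node: InstanceNode, name: str, models: ModelSet, prefixes, depth: int,
                    out: list[str], declare=None):
    ind = "  " * depth
    ns = models.namespace_of(node.type_ref)
    tag = f"{_pfx(prefixes, ns)}{name}"
    attrs = []
    if declare:
        for p, uri in declare:
            attrs.append((f"xmlns:{p}" if p else "xmlns", uri))
    emap_list = models.effective_elements(node.type_ref)
    known = {e.name for e in emap_list}
    for vname in node.values:
        if vname not in known:
            raise SerializationError(f"unknown element {vname!r} on {node.type_ref!r}")
    for e in emap_list:
        vs = node.values.get(e.name, [])
        if e.max_occurs is not None and len(vs) > e.max_occurs:
            raise SerializationError(
                f"element {e.name!r} on {node.type_ref!r}: {len(vs)} values exceed "
                f"maxOccurs={e.max_occurs}")
        if e.kind == "attribute":
            for v in vs:
                attrs.append((e.name, v if isinstance(v, str) else str(v)))
    attr_text = "".join(f" {k}={quoteattr(v)}" for k, v in attrs)
    text_desc = next((e for e in emap_list if e.kind == "text"), None)
    children = [
        (e, v)
        for e in emap_list if e.kind == "element"
        for v in node.values.get(e.name, [])
    ]
    if text_desc is not None and node.values.get(TEXT_ELEMENT):
        text = node.values[TEXT_ELEMENT][0]
        out.append(f"{ind}<{tag}{attr_text}>{escape(text)}</{tag}>")
    elif not children:
        out.append(f"{ind}<{tag}{attr_text}/>")
    else:
        out.append(f"{ind}<{tag}{attr_text}>")
        for e, v in children:
            if isinstance(v, InstanceNode):
                _write_xml_node(v, e.name, models, prefixes, depth + 1, out)
            else:
                ctag = f"{_pfx(prefixes, ns)}{e.name}"
                out.append(f"{ind}  <{ctag}>{escape(str(v))}</{ctag}>")
        out.append(f"{ind}</{tag}>")


# ---------------------------------------------------------------------------
# FHIR-style JSON reader / writer
# ---------------------------------------------------------------------------

_DECIMAL_RE = re.compile(r"-?(\d+)(\.\d+)?([eE][+-]?\d+)?$")


class _Raw:
    """Raw JSON number text (exact decimal lexical form)."""

    __slots__ = ("text",)

    def __init__(self, text: str):
        self.text = text


class _Obj:
    """A JSON object as an ordered pair list."""

    __slots__ = ("pairs",)

    def __init__(self, pairs: list):
        self.pairs = pairs


_INDENTS = ["  " * i for i in range(24)]


def _indent(depth: int) -> str:
    while depth >= len(_INDENTS):
        _INDENTS.append("  " * len(_INDENTS))
    return _INDENTS[depth]


def write_fhir_json(node: InstanceNode, models: ModelSet) -> str:
    """Serialize a FHIR-family node to FHIR JSON conventions.

    Resource roots get ``resourceType`` first; repeating elements become
    arrays; primitives unwrap their ``value`` attribute, typed by the schema;
    key order is schema order; decimals keep their exact lexical form.
    """
    if models.is_primitive_model(node.type_ref) or not _fhir_family(node, models):
        raise SerializationError(
            f"type {node.type_ref!r} is not part of a FHIR-style model family")
    return _emit_json(node, models, 0) + "\n"


def _fhir_family(node: InstanceNode, models: ModelSet) -> bool:
    # FHIR-style family == family that declares a Resource base type
    fam = models.family_of(node.type_ref)
    return f"{fam}.Resource" in models.types or models.is_resource(node.type_ref)


def _json_plan(models: ModelSet, qname: str) -> tuple:
    """Cached per-type serialization plan: (resource name or None, entries);
    entries are (element name, repeats, mode, mode argument)."""
    plan = models._json_plans.get(qname)
    if plan is None:
        entries = []
        for e in models.effective_elements(qname):
            t = e.type_ref
            if t.startswith("xs:"):
                mode, arg = "scalar", _XS_KIND.get(t, "string")
            elif models.is_container(t):
                mode, arg = "container", None
            else:
                kind = models.primitive_value_kind(t)
                if kind is not None:
                    slot = "value" if "value" in models.element_map(t) else TEXT_ELEMENT
                    mode, arg = "prim", (kind, slot)
                else:
                    mode, arg = "complex", None
            entries.append((e.name, e.repeats, mode, arg))
        plan = (models.resource_kind_of(qname), entries)
        models._json_plans[qname] = plan
    return plan


def _scalar_text(lexical: str, kind: str) -> str:
    if kind == "string":
        return json.dumps(lexical, ensure_ascii=False)
    if kind == "boolean":
        if lexical not in ("true", "false"):
            raise SerializationError(f"invalid boolean lexical {lexical!r}")
        return lexical
    if kind == "integer":
        return str(int(lexical))
    if not _DECIMAL_RE.match(lexical):
        raise SerializationError(f"invalid decimal lexical {lexical!r}")
    return lexical


def _prim_text(v: InstanceNode, kind: str, slot: str) -> str:
    vals = v.values.get(slot) or v.values.get("value") \
        or v.values.get(TEXT_ELEMENT) or [""]
    return _scalar_text(vals[0], kind)


def _unwrap_container(v: InstanceNode, type_ref: str) -> InstanceNode:
    members = [x for vs in v.values.values() for x in vs]
    if len(members) != 1 or not isinstance(members[0], InstanceNode):
        raise SerializationError(
            f"resource container {type_ref!r} must hold exactly one resource")
    return members[0]


def _emit_json(node: InstanceNode, models: ModelSet, depth: int) -> str:
    """Render a node as a JSON object text; inner lines indented ``depth+1``,
    closing brace at ``depth``."""
    rname, entries = _json_plan(models, node.type_ref)
    ind1 = _indent(depth + 1)
    lines: list[str] = []
    if rname is not None:
        lines.append(f'{ind1}"resourceType": {json.dumps(rname)}')
    values = node.values
    for name, repeats, mode, arg in entries:
        vs = values.get(name)
        if not vs:
            continue
        item_depth = depth + 2 if repeats else depth + 1
        if mode == "scalar":
            rendered = [_scalar_text(v, arg) for v in vs]
        elif mode == "prim":
            kind, slot = arg
            rendered = [_prim_text(v, kind, slot) for v in vs]
        elif mode == "container":
            rendered = [_emit_json(_unwrap_container(v, v.type_ref), models,
                                   item_depth) for v in vs]
        else:
            rendered = [_emit_json(v, models, item_depth) for v in vs]
        if repeats:
            ind2 = _indent(depth + 2)
            val = "[\n" + ",\n".join(ind2 + r for r in rendered) + "\n" + ind1 + "]"
        else:
            val = rendered[0]
        lines.append(f'{ind1}{json.dumps(name)}: {val}')
    if not lines:
        return "{}"
    return "{\n" + ",\n".join(lines) + "\n" + _indent(depth) + "}"


def _dump_json(value, depth: int) -> str:
    ind, ind1 = "  " * depth, "  " * (depth + 1)
    if isinstance(value, _Obj):
        if not value.pairs:
            return "{}"
        body = ",\n".join(
            f"{ind1}{json.dumps(k)}: {_dump_json(v, depth + 1)}" for k, v in value.pairs)
        return "{\n" + body + f"\n{ind}}}"
    if isinstance(value, list):
        if not value:
            return "[]"
        body = ",\n".join(f"{ind1}{_dump_json(v, depth + 1)}" for v in value)
        return "[\n" + body + f"\n{ind}]"
    if isinstance(value, _Raw):
        return value.text
    if isinstance(value, bool):
        return "true" if value else "false"
    return json.dumps(value, ensure_ascii=False)


def read_fhir_json(json_text: str, models: ModelSet, root_type: str) -> InstanceNode:
    """Inverse of :func:`write_fhir_json` on its image."""
    data = json.loads(json_text, parse_float=str)
    return _read_json_node(data, root_type, models, "$")


def _lexical_of(value, kind: str, path: str) -> str:
    if kind == "boolean":
        if not isinstance(value, bool):
            raise InstanceParseError(f"expected JSON boolean, got {value!r}", path)
        return "true" if value else "false"
    if kind == "integer":
        if isinstance(value, bool) or not isinstance(value, int):
            raise InstanceParseError(f"expected JSON integer, got {value!r}", path)
        return str(value)
    if kind == "decimal":
        if isinstance(value, bool) or not isinstance(value, (int, str)):
            raise InstanceParseError(f"expected JSON number, got {value!r}", path)
        return str(value)
    if not isinstance(value, str):
        raise InstanceParseError(f"expected JSON string, got {value!r}", path)
    return value


def _read_json_node(data, qname: str, models: ModelSet, path: str) -> InstanceNode:
    if not isinstance(data, dict):
        raise InstanceParseError(f"expected JSON object for {qname!r}", path)
    node = InstanceNode(qname, resource_kind=qname.split(".")[-1] if models.is_resource(qname) else None)
    emap = models.element_map(qname)
    if models.is_resource(qname):
        rt = data.get("resourceType")
        if rt != qname.split(".")[-1]:
            raise InstanceParseError(
                f"resourceType {rt!r} does not match {qname!r}", path)
    for key, raw in data.items():
        if key == "resourceType" and models.is_resource(qname):
            continue
        d = emap.get(key)
        if d is None:
            raise InstanceParseError(f"unknown key {key!r} on {qname!r}", f"{path}.{key}")
        if d.repeats:
            if not isinstance(raw, list):
                raise InstanceParseError(f"expected array for {key!r}", f"{path}.{key}")
            items = raw
        else:
            if isinstance(raw, list):
                raise InstanceParseError(f"unexpected array for {key!r}", f"{path}.{key}")
            items = [raw]
        for i, item in enumerate(items):
            ipath = f"{path}.{key}[{i}]" if d.repeats else f"{path}.{key}"
            if d.type_ref.startswith("xs:"):
                node.add(key, _lexical_of(item, _XS_KIND.get(d.type_ref, "string"), ipath))
            elif models.is_container(d.type_ref):
                if not isinstance(item, dict) or "resourceType" not in item:
                    raise InstanceParseError("expected inline resource object", ipath)
                rname = item["resourceType"]
                member = next(
                    (m for m in models.effective_elements(d.type_ref) if m.name == rname), None)
                if member is None:
                    raise InstanceParseError(f"unknown resourceType {rname!r}", ipath)
                wrapper = InstanceNode(d.type_ref)
                wrapper.add(rname, _read_json_node(item, member.type_ref, models, ipath))
                node.add(key, wrapper)
            else:
                kind = models.primitive_value_kind(d.type_ref)
                if kind is not None:
                    prim = InstanceNode(d.type_ref)
                    pd = models.element_map(d.type_ref)
                    slot = "value" if "value" in pd else TEXT_ELEMENT
                    prim.add(slot, _lexical_of(item, kind, ipath))
                    node.add(key, prim)
                else:
                    node.add(key, _read_json_node(item, d.type_ref, models, ipath))
    return node


def resolve_element_type(models: ModelSet, context_type: str, element: str) -> str:
    """Module-level convenience wrapper over :meth:`ModelSet.resolve_element_type`."""
    return models.resolve_element_type(context_type, element)
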