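"""FML parsing, StructureMap serialization round-trips, import resolution."""
import dataclasses

import pytest

from fmlc.errors import (
    ImportCycleError,
    ImportError_,
    ParseError,
    UnsupportedTransformError,
)
from fmlc.fhirpath import Func
from fmlc.fixtures import conceptmap_fixture, example_map
from fmlc.fml_frontend import (
    FPExpr,
    load_imports,
    parse_conceptmap,
    parse_fml,
    parse_structuremap,
    serialize_conceptmap,
    serialize_structuremap,
)

MINI_HEADER = """
map "urn:t" = "t"
uses "http://example.org/models/minicda/ClinicalDocument" alias ClinicalDocument as source
uses "http://example.org/models/minifhir/Bundle" alias Bundle as target
"""


class TestParseFml:
    def test_activity_map_has_one_group_with_source_and_target(self):
        ast = parse_fml(example_map("activity_supply"))
        assert len(ast.groups) == 1
        modes = [m for _, _, m in ast.groups[0].inputs]
        assert modes == ["source", "target"]

    def test_minimal_map_without_rules(self):
        ast = parse_fml(example_map("noop"))
        assert ast.groups[0].rules == ()

    def test_lab_map_carries_embedded_conceptmaps(self):
        ast = parse_fml(example_map("cda_lab_bundle"))
        assert len(ast.concept_maps) == 2
        urls = {cm.url for cm in ast.concept_maps}
        assert "http://example.org/conceptmaps/lab-codes" in urls

    def test_embedded_fhirpath_parsed_eagerly(self):
        ast = parse_fml(example_map("activity_supply"))
        rules = ast.groups[0].rules
        conditions = [r.sources[0].condition for r in rules if r.sources[0].condition]
        assert conditions and all(isinstance(c, FPExpr) for c in conditions)
        evaluates = [p for r in rules for t in r.targets
                     if t.transform == "evaluate" for p in t.parameters
                     if p.kind == "fp"]
        assert all(isinstance(p.value.ast, Func) for p in evaluates)

    def test_comments_do_not_affect_the_ast(self):
        plain = MINI_HEADER + "group G(source s : ClinicalDocument, target t : Bundle) { s -> t.type = 'collection'; }"
        commented = MINI_HEADER + """
// leading comment
group G(source s : ClinicalDocument, target t : Bundle) {
  /* block */ s -> t.type = 'collection';  // trailing
}
"""
        assert parse_fml(plain) == parse_fml(commented)

    def test_quoted_identifiers_allow_keywords_as_element_names(self):
        text = MINI_HEADER + (
            'group G(source s : ClinicalDocument, target t : Bundle) '
            '{ s."first" as v -> t.type = copy(v); }')
        rule = parse_fml(text).groups[0].rules[0]
        assert rule.sources[0].element == "first"

    def test_multiple_sources_per_rule_rejected(self):
        text = MINI_HEADER + (
            "group G(source s : ClinicalDocument, target t : Bundle) "
            "{ s.id as a, s.code as b -> t.type = copy(a); }")
        with pytest.raises(ParseError, match="one source"):
            parse_fml(text)

    def test_unsupported_transform_keyword(self):
        text = MINI_HEADER + (
            "group G(source s : ClinicalDocument, target t : Bundle) "
            "{ s -> t.type = pointer(s); }")
        with pytest.raises(UnsupportedTransformError, match="pointer"):
            parse_fml(text)

    def test_syntax_error_is_position_annotated(self):
        with pytest.raises(ParseError, match=r"line \d+"):
            parse_fml('map "u" = "n"\nuses ???')

    def test_duplicate_group_names_rejected(self):
        text = MINI_HEADER + (
            "group G(source s : ClinicalDocument, target t : Bundle) {}\n"
            "group G(source s : ClinicalDocument, target t : Bundle) {}")
        with pytest.raises(ParseError, match="duplicate group"):
            parse_fml(text)

    def test_group_requires_source_and_target_inputs(self):
        text = MINI_HEADER + "group G(source s : ClinicalDocument) {}"
        with pytest.raises(ParseError, match="target"):
            parse_fml(text)

    def test_duplicate_conceptmap_source_code_rejected(self):
        text = MINI_HEADER + """
conceptmap "urn:cm" {
  prefix a = "urn:a"
  prefix b = "urn:b"
  a:X == b:Y
  a:X == b:Z
}
group G(source s : ClinicalDocument, target t : Bundle) {}
"""
        with pytest.raises(ParseError, match="duplicate source code"):
            parse_fml(text)


class TestStructureMapRoundTrip:
    @pytest.mark.parametrize("fmt", ["json", "xml"])
    def test_serialize_parse_identity(self, any_map_ast, fmt):
        text = serialize_structuremap(any_map_ast, fmt)
        assert parse_structuremap(text, fmt) == any_map_ast

    @pytest.mark.parametrize("fmt", ["json", "xml"])
    def test_serialization_deterministic(self, any_map_ast, fmt):
        assert serialize_structuremap(any_map_ast, fmt) == \
            serialize_structuremap(any_map_ast, fmt)

    def test_xml_and_json_renderings_yield_identical_asts(self, any_map_ast):
        via_json = parse_structuremap(serialize_structuremap(any_map_ast, "json"), "json")
        via_xml = parse_structuremap(serialize_structuremap(any_map_ast, "xml"), "xml")
        assert via_json == via_xml

    def test_empty_map_round_trips_with_zero_rules(self, noop_ast):
        text = serialize_structuremap(noop_ast, "json")
        assert parse_structuremap(text, "json").groups[0].rules == ()

    def test_contained_conceptmap_attached(self, lab_ast):
        for fmt in ("json", "xml"):
            text = serialize_structuremap(lab_ast, fmt)
            assert parse_structuremap(text, fmt).concept_maps == lab_ast.concept_maps


class TestConceptMapResources:
    def test_fixture_files_parse_equal_in_both_formats(self):
        cm_json = parse_conceptmap(conceptmap_fixture("json"), "json")
        cm_xml = parse_conceptmap(conceptmap_fixture("xml"), "xml")
        assert cm_json == cm_xml

    def test_standalone_fixture_matches_embedded_definition(self, lab_ast):
        standalone = parse_conceptmap(conceptmap_fixture("json"), "json")
        embedded = next(cm for cm in lab_ast.concept_maps
                        if cm.url.endswith("lab-codes"))
        assert standalone == embedded

    @pytest.mark.parametrize("fmt", ["json", "xml"])
    def test_serialize_round_trip(self, fmt):
        cm = parse_conceptmap(conceptmap_fixture("json"), "json")
        assert parse_conceptmap(serialize_conceptmap(cm, fmt), fmt) == cm


class TestLoadImports:
    def test_conceptmap_import_registered(self, noop_ast):
        with_import = dataclasses.replace(
            noop_ast, imports=("http://example.org/conceptmaps/lab-codes",))
        closure = load_imports(with_import, {
            "http://example.org/conceptmaps/lab-codes": conceptmap_fixture("json")})
        assert [cm.url for cm in closure.conceptmaps] == \
            ["http://example.org/conceptmaps/lab-codes"]

    def test_no_imports_yields_singleton(self, noop_ast):
        closure = load_imports(noop_ast, {})
        assert closure.maps == [noop_ast]

    def test_missing_uri_is_an_error(self, noop_ast):
        broken = dataclasses.replace(noop_ast, imports=("urn:missing",))
        with pytest.raises(ImportError_, match="urn:missing"):
            load_imports(broken, {})

    def test_self_import_is_a_cycle(self, noop_ast):
        selfish = dataclasses.replace(noop_ast, imports=(noop_ast.url,))
        with pytest.raises(ImportCycleError):
            load_imports(selfish, {noop_ast.url: example_map("noop")})

    def test_mutual_import_cycle_lists_the_chain(self, noop_ast):
        a = dataclasses.replace(noop_ast, url="urn:a", imports=("urn:b",))
        b_text = example_map("noop").replace(
            'map "http://example.org/maps/Noop" = "Noop"',
            'map "urn:b" = "NoopB"\nimports "urn:a"')
        with pytest.raises(ImportCycleError) as err:
            load_imports(a, {"urn:b": b_text, "urn:a": example_map("noop")})
        assert "urn:a" in err.value.chain and "urn:b" in err.value.chain
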