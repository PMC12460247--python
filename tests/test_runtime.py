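"""Runtime helper layer: assignment, translation, timestamps, UUIDs."""
import re

import pytest

from fmlc import runtime as rt
from fmlc.errors import CardinalityError, MapRuntimeError, TranslateError
from fmlc.fixtures import conceptmap_fixture
from fmlc.fml_frontend import CMElement, CMGroup, ConceptMapDef, parse_conceptmap
from fmlc.schema_models import InstanceNode

UUID_V4 = re.compile(
    r"^[0-9a-f]{8}-[0-9a-f]{4}-4[0-9a-f]{3}-[89ab][0-9a-f]{3}-[0-9a-f]{12}$")


@pytest.fixture
def ctx(models):
    return rt.ExecutionContext(models=models, seed=11,
                               now="2024-03-01T08:00:00+01:00")


class TestAssign:
    def test_append_to_empty_unbounded_element(self, models, ctx):
        pat = rt.create(models, "minifhir.Patient")
        rt.assign(pat, "identifier", rt.create(models, "minifhir.Identifier"), ctx)
        assert len(pat.get("identifier")) == 1

    def test_two_appends_preserve_order(self, models, ctx):
        pat = rt.create(models, "minifhir.Patient")
        a = rt.assign(pat, "identifier", rt.create(models, "minifhir.Identifier"), ctx)
        b = rt.assign(pat, "identifier", rt.create(models, "minifhir.Identifier"), ctx)
        assert pat.get("identifier") == [a, b]

    def test_singleton_replacement_keeps_length_one(self, models, ctx):
        pat = rt.create(models, "minifhir.Patient")
        rt.assign(pat, "gender", "female", ctx)
        rt.assign(pat, "gender", "male", ctx)
        assert len(pat.get("gender")) == 1
        assert pat.get("gender")[0].get("value") == ["male"]

    def test_scalar_wrapped_into_primitive_model_node(self, models, ctx):
        pat = rt.create(models, "minifhir.Patient")
        stored = rt.assign(pat, "birthDate", "1980-04-02", ctx)
        assert isinstance(stored, InstanceNode)
        assert stored.type_ref == "minifhir.date"

    def test_unknown_element_is_a_runtime_error(self, models, ctx):
        pat = rt.create(models, "minifhir.Patient")
        with pytest.raises(MapRuntimeError, match="bogus"):
            rt.assign(pat, "bogus", "x", ctx)

    def test_resource_into_container_binds_the_resource(self, models, ctx):
        entry = rt.create(models, "minifhir.BundleEntry")
        obs = rt.create(models, "minifhir.Observation")
        stored = rt.assign(entry, "resource", obs, ctx)
        assert stored is obs
        wrapper = entry.get("resource")[0]
        assert wrapper.type_ref == "minifhir.ResourceContainer"
        assert wrapper.get("Observation") == [obs]


class TestTranslate:
    @pytest.fixture
    def lab_ctx(self, models):
        cm = parse_conceptmap(conceptmap_fixture("json"), "json")
        return rt.ExecutionContext(models=models, conceptmaps=[cm])

    def test_fixture_code_lookup(self, lab_ctx):
        # hand lookup in the committed table: L01 -> 718-7
        assert rt.translate_code(lab_ctx, "L01",
                                 None, "http://example.org/conceptmaps/lab-codes",
                                 "code") == "718-7"

    def test_unmapped_code_raises(self, lab_ctx):
        with pytest.raises(TranslateError, match="X99"):
            rt.translate_code(lab_ctx, "X99", None,
                              "http://example.org/conceptmaps/lab-codes", "code")

    def test_unregistered_map_raises(self, ctx):
        with pytest.raises(TranslateError, match="not registered"):
            rt.translate_code(ctx, "L01", None, "urn:nowhere", "code")

    def test_coding_output_carries_target_system(self, lab_ctx):
        coding = rt.translate_code(
            lab_ctx, "L02", None, "http://example.org/conceptmaps/lab-codes",
            "Coding")
        assert coding.get("system")[0].get("value") == ["http://loinc.org"]
        assert coding.get("code")[0].get("value") == ["787-2"]

    def test_ambiguous_code_raises(self, models):
        cm = ConceptMapDef("urn:amb", (
            CMGroup("urn:a", "urn:b", (CMElement("X", "equivalent", "1"),)),
            CMGroup("urn:a2", "urn:b", (CMElement("X", "wider", "2"),)),
        ))
        ctx = rt.ExecutionContext(models=models, conceptmaps=[cm])
        with pytest.raises(TranslateError, match="ambiguous"):
            rt.translate_code(ctx, "X", None, "urn:amb", "code")

    def test_static_table_helpers_match_dynamic_errors(self, lab_ctx):
        table = {"L01": ("http://loinc.org", "718-7"), "DUP": None}
        assert rt.cm_code(table, "L01", "urn:m") == "718-7"
        with pytest.raises(TranslateError, match="no mapping"):
            rt.cm_code(table, "X99", "urn:m")
        with pytest.raises(TranslateError, match="ambiguous"):
            rt.cm_code(table, "DUP", "urn:m")


class TestContextState:
    def test_shared_now_constant_within_context(self, ctx):
        assert rt.shared_now(ctx) == rt.shared_now(ctx)

    def test_shared_now_iso8601_with_offset(self):
        c = rt.ExecutionContext()
        assert re.match(r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}[+-]\d{2}:?\d{2}",
                        rt.shared_now(c))

    def test_contexts_started_at_different_times_differ(self):
        a = rt.ExecutionContext(now="2024-01-01T00:00:00+00:00")
        b = rt.ExecutionContext(now="2025-01-01T00:00:00+00:00")
        assert rt.shared_now(a) != rt.shared_now(b)

    def test_uuid_v4_format(self, ctx):
        for _ in range(50):
            assert UUID_V4.match(rt.new_uuid(ctx))

    def test_seeded_uuid_sequence_reproducible(self, models):
        a = rt.ExecutionContext(models=models, seed=5)
        b = rt.ExecutionContext(models=models, seed=5)
        assert [rt.new_uuid(a) for _ in range(10)] == \
            [rt.new_uuid(b) for _ in range(10)]

    def test_unseeded_uuids_distinct(self):
        c = rt.ExecutionContext()
        assert len({rt.new_uuid(c) for _ in range(100)}) == 100


class TestDynamicGet:
    def test_existing_element(self, models, ctx):
        pat = rt.create(models, "minifhir.Patient")
        rt.assign(pat, "gender", "male", ctx)
        assert rt.dynamic_get(pat, "gender", models) == pat.get("gender")

    def test_unknown_element_yields_empty(self, models):
        pat = rt.create(models, "minifhir.Patient")
        assert rt.dynamic_get(pat, "nothing", models) == []

    def test_choice_member_resolves_but_abstract_name_is_empty(self, models, ctx):
        obs = rt.create(models, "minifhir.Observation")
        rt.assign(obs, "valueString", "pos", ctx)
        assert rt.dynamic_get(obs, "valueString", models) != []
        assert rt.dynamic_get(obs, "value", models) == []


class TestTransformHelpers:
    def test_cast_table(self):
        assert rt.cast_value("42", "integer") == 42
        assert rt.cast_value(42, "string") == "42"
        assert rt.cast_value("7.20", "decimal") == "7.20"
        assert rt.cast_value("true", "boolean") is True
        assert rt.cast_value("2024-03-01T08:00:00", "date") == "2024-03-01"

    def test_incompatible_cast_raises(self):
        with pytest.raises(MapRuntimeError):
            rt.cast_value("hello", "integer")
        with pytest.raises(MapRuntimeError):
            rt.cast_value("NaN", "decimal")

    def test_truncate_takes_a_prefix(self):
        assert rt.truncate("hello", 3) == "hel"

    def test_only_one_guards_cardinality(self):
        assert rt.only_one(["a"]) == ["a"]
        with pytest.raises(CardinalityError):
            rt.only_one(["a", "b"], "src.id")
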