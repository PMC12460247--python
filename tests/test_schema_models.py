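"""Schema parsing, typed instance trees, and exact XML / FHIR-JSON I/O."""
import json

import pytest

from fmlc.errors import (
    InstanceParseError,
    NamespaceError,
    SchemaUnsupportedError,
    SerializationError,
    TypeResolutionError,
)
from fmlc.fixtures import GeneratorConfig, mini_activity_definition, mini_cda_document
from fmlc.schema_models import (
    UNBOUNDED,
    InstanceNode,
    parse_schema,
    read_fhir_json,
    read_xml,
    resolve_element_type,
    write_fhir_json,
    write_xml,
)

XS = 'xmlns:xs="http://www.w3.org/2001/XMLSchema"'


def _schema(body, ns="urn:test"):
    return (f'<?xml version="1.0"?><xs:schema {XS} targetNamespace="{ns}" '
            f'xmlns="{ns}" elementFormDefault="qualified">{body}</xs:schema>')


class TestParseSchema:
    def test_unbounded_marker(self):
        ms = parse_schema(_schema(
            '<xs:complexType name="A"><xs:sequence>'
            '<xs:element name="x" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>'
            "</xs:sequence></xs:complexType>"), family="t")
        (e,) = ms.descriptor("t.A").elements
        assert e.max_occurs is UNBOUNDED and e.repeats

    def test_extension_appends_own_elements_after_base(self):
        ms = parse_schema(_schema(
            '<xs:complexType name="Base"><xs:sequence>'
            '<xs:element name="a" type="xs:string" minOccurs="0"/></xs:sequence>'
            "</xs:complexType>"
            '<xs:complexType name="Derived"><xs:complexContent>'
            '<xs:extension base="Base"><xs:sequence>'
            '<xs:element name="b" type="xs:string" minOccurs="0"/>'
            "</xs:sequence></xs:extension></xs:complexContent></xs:complexType>"),
            family="t").validate()
        assert [e.name for e in ms.effective_elements("t.Derived")] == ["a", "b"]

    def test_fixture_type_names_match_manifest(self, models, manifest):
        for family, names in manifest["types"].items():
            parsed = {t.split(".")[1] for t in models.types
                      if t.startswith(family + ".")}
            assert parsed == set(names), family

    @pytest.mark.parametrize("construct", [
        '<xs:complexType name="A"><xs:sequence><xs:any/></xs:sequence></xs:complexType>',
        '<xs:complexType name="A"><xs:all><xs:element name="x" type="xs:string"/>'
        "</xs:all></xs:complexType>",
        '<xs:element name="r" type="A" substitutionGroup="q"/>',
    ])
    def test_unsupported_constructs_are_named_errors(self, construct):
        with pytest.raises(SchemaUnsupportedError) as err:
            parse_schema(_schema(construct), family="t")
        assert "line" in str(err.value)

    def test_dangling_type_reference_reported(self):
        ms = parse_schema(_schema(
            '<xs:complexType name="A"><xs:sequence>'
            '<xs:element name="x" type="Missing"/></xs:sequence></xs:complexType>'),
            family="t")
        with pytest.raises(TypeResolutionError, match="Missing"):
            ms.validate()


class TestResolveElementType:
    def test_every_manifest_pair_resolves(self, models, manifest):
        for qname, elements in manifest["element_types"].items():
            key = qname.replace("minicda.ENXP", "minicda.ENXP")
            for element, expected in elements.items():
                assert resolve_element_type(models, key, element) == expected

    def test_inherited_element_resolves_via_derived_type(self, models):
        assert resolve_element_type(models, "minifhir.Patient", "id") == "minifhir.id"

    def test_choice_member_resolves_but_abstract_name_does_not(self, models):
        assert resolve_element_type(
            models, "minifhir.Observation", "valueQuantity") == "minifhir.Quantity"
        with pytest.raises(TypeResolutionError) as err:
            resolve_element_type(models, "minifhir.Observation", "value")
        assert "valueQuantity" in str(err.value)  # candidates listed


class TestXmlRoundTrip:
    @pytest.mark.parametrize("n", [0, 1, 3])
    @pytest.mark.parametrize("seed", [0, 7])
    def test_write_read_identity_on_generated_documents(self, models, n, seed):
        doc = mini_cda_document(GeneratorConfig(n_observations=n, seed=seed))
        node = read_xml(doc, models)
        assert write_xml(node, models) == doc

    def test_observation_count_forced_by_generator_parameter(self, models):
        node = read_xml(mini_cda_document(GeneratorConfig(n_observations=3, seed=1)),
                        models)
        assert len(node.get("component")[0].get("observation")) == 3

    def test_serialization_is_deterministic(self, models):
        doc = mini_cda_document(GeneratorConfig(n_observations=2, seed=3))
        node = read_xml(doc, models)
        assert write_xml(node, models) == write_xml(node, models)

    def test_empty_root_of_all_optional_type(self, models):
        node = read_xml('<ClinicalDocument xmlns="urn:example:minicda"/>', models)
        assert node.values == {}

    def test_unknown_element_error_carries_path(self, models):
        bad = ('<ClinicalDocument xmlns="urn:example:minicda">'
               "<bogus/></ClinicalDocument>")
        with pytest.raises(InstanceParseError, match="bogus"):
            read_xml(bad, models)

    def test_namespace_mismatch(self, models):
        with pytest.raises(NamespaceError):
            read_xml('<ClinicalDocument xmlns="urn:wrong"/>', models)

    def test_text_content_element_renders_character_data(self, models):
        node = InstanceNode("minicda.ENXP", {"_text": ["Anna"]})
        pn = InstanceNode("minicda.PN", {"given": [node]})
        patient = InstanceNode("minicda.Patient", {"name": [pn]})
        role = InstanceNode("minicda.PatientRole", {"patient": [patient]})
        rec = InstanceNode("minicda.RecordTarget", {"patientRole": [role]})
        doc = InstanceNode("minicda.ClinicalDocument", {"recordTarget": [rec]})
        assert "<given>Anna</given>" in write_xml(doc, models)

    def test_cardinality_violation_names_the_element(self, models):
        doc = InstanceNode("minicda.ClinicalDocument",
                           {"id": [InstanceNode("minicda.II", {"root": ["1"]}),
                                   InstanceNode("minicda.II", {"root": ["2"]})]})
        with pytest.raises(SerializationError, match="id"):
            write_xml(doc, models)


class TestFhirJson:
    def test_resource_root_starts_with_resource_type(self, models):
        text = mini_activity_definition(0)
        assert text.splitlines()[1].strip().startswith('"resourceType": "ActivityDefinition"')

    def test_repeating_element_is_always_an_array(self, models):
        pat = InstanceNode("minifhir.Patient", resource_kind="Patient")
        name = InstanceNode("minifhir.HumanName")
        name.add("given", InstanceNode("minifhir.string", {"value": ["A"]}))
        pat.add("name", name)
        data = json.loads(write_fhir_json(pat, models))
        assert isinstance(data["name"], list) and isinstance(
            data["name"][0]["given"], list)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_json_round_trip_identity(self, models, seed):
        text = mini_activity_definition(seed)
        node = read_fhir_json(text, models, "minifhir.ActivityDefinition")
        assert write_fhir_json(node, models) == text

    def test_decimal_lexical_form_preserved(self, models):
        q = InstanceNode("minifhir.Quantity")
        q.add("value", InstanceNode("minifhir.decimal", {"value": ["7.20"]}))
        obs = InstanceNode("minifhir.Observation", resource_kind="Observation")
        obs.add("valueQuantity", q)
        out = write_fhir_json(obs, models)
        assert '"value": 7.20' in out
        assert write_fhir_json(
            read_fhir_json(out, models, "minifhir.Observation"), models) == out

    def test_unknown_key_is_an_error(self, models):
        with pytest.raises(InstanceParseError, match="bogus"):
            read_fhir_json('{"resourceType": "Patient", "bogus": 1}',
                           models, "minifhir.Patient")

    def test_scalar_where_array_expected_is_a_shape_error(self, models):
        with pytest.raises(InstanceParseError, match="array"):
            read_fhir_json('{"resourceType": "Patient", "name": {}}',
                           models, "minifhir.Patient")

    def test_non_fhir_family_rejected(self, models):
        cda = InstanceNode("minicda.ClinicalDocument")
        with pytest.raises(SerializationError):
            write_fhir_json(cda, models)

    def test_cross_format_consistency(self, models):
        xml_text = mini_activity_definition(3, fmt="xml")
        node = read_xml(xml_text, models)
        j1 = write_fhir_json(node, models)
        j2 = write_fhir_json(
            read_fhir_json(j1, models, "minifhir.ActivityDefinition"), models)
        assert j1 == j2


class TestRoundTripProperties:
    from hypothesis import given, settings, strategies as st

    _name = st.text(alphabet=st.characters(min_codepoint=32, max_codepoint=0x2FF,
                                           blacklist_characters="\x7f"),
                    min_size=1, max_size=20)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(_name, min_size=0, max_size=4), _name)
    def test_patient_names_survive_xml_and_json_round_trips(self, givens, family):
        from fmlc.fixtures import fixture_models

        models = fixture_models()
        pat = InstanceNode("minifhir.Patient", resource_kind="Patient")
        name = InstanceNode("minifhir.HumanName")
        for g in givens:
            name.add("given", InstanceNode("minifhir.string", {"value": [g]}))
        name.add("family", InstanceNode("minifhir.string", {"value": [family]}))
        pat.add("name", name)
        xml_text = write_xml(pat, models)
        assert read_xml(xml_text, models) == pat
        json_text = write_fhir_json(pat, models)
        assert read_fhir_json(json_text, models, "minifhir.Patient") == pat

    @settings(max_examples=50, derandomize=True)
    @given(st.decimals(allow_nan=False, allow_infinity=False,
                       places=4).map(str))
    def test_decimal_lexical_forms_round_trip_through_json(self, lexical):
        from fmlc.fixtures import fixture_models

        models = fixture_models()
        obs = InstanceNode("minifhir.Observation", resource_kind="Observation")
        q = InstanceNode("minifhir.Quantity")
        q.add("value", InstanceNode("minifhir.decimal", {"value": [lexical]}))
        obs.add("valueQuantity", q)
        out = write_fhir_json(obs, models)
        node = read_fhir_json(out, models, "minifhir.Observation")
        stored = node.get("valueQuantity")[0].get("value")[0].get("value")
        assert stored == [lexical]
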