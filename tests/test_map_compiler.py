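"""Compiler: generated-code contract, static typing, oracle equivalence."""
import re

import pytest

from fmlc import compile_map, interpret_map, parse_fml, runtime as rt
from fmlc.errors import CardinalityError, CompileError, AmbiguityError
from fmlc.fixtures import GeneratorConfig, mini_cda_document
from fmlc.fml_frontend import MapGroup, StructureMapAST
from fmlc.map_compiler import resolve_dependent_group, sanitize_identifier
from fmlc.schema_models import read_xml, write_fhir_json

from conftest import NOW, exec_program, run_compiled, source_for

HEADER = """
map "urn:test" = "Test"
uses "http://example.org/models/minicda/ClinicalDocument" alias ClinicalDocument as source
uses "http://example.org/models/minifhir/Bundle" alias Bundle as target
"""


def both_engines(map_text, models, doc_text, seed=0):
    ast = parse_fml(map_text)
    src = read_xml(doc_text, models)
    compiled = run_compiled(ast, models, src, seed=seed)
    interpreted = interpret_map(
        ast, src, models,
        ctx=rt.ExecutionContext(models=models, seed=seed, now=NOW))
    return compiled, interpreted


def _collect_rule_names(groups):
    names = []

    def walk(rules):
        for r in rules:
            if r.name:
                names.append(r.name)
            walk(r.nested_rules)

    for g in groups:
        walk(g.rules)
    return names


def _collect_variables(groups):
    out = set()

    def walk(rules):
        for r in rules:
            s = r.sources[0]
            if s.variable:
                out.add(s.variable)
            for t in r.targets:
                if t.variable:
                    out.add(t.variable)
            walk(r.nested_rules)

    for g in groups:
        out.update(n for n, _, _ in g.inputs)
        walk(g.rules)
    return out


class TestTraceability:
    def test_entry_function_carries_the_fml_group_name(self, activity_ast, models):
        prog = compile_map(activity_ast, models)
        assert prog.entry_point == "ActivityDefinitionToSupplyRequest"
        assert "def ActivityDefinitionToSupplyRequest(" in prog.source_text

    def test_every_group_and_variable_identifier_preserved(self, lab_ast, models):
        prog = compile_map(lab_ast, models)
        for g in lab_ast.groups:
            assert prog.symbol_table[g.name] == sanitize_identifier(g.name)
            assert re.search(rf"\b{sanitize_identifier(g.name)}\b", prog.source_text)
        for var in _collect_variables(lab_ast.groups):
            assert var in prog.symbol_table
            assert re.search(rf"\b{sanitize_identifier(var)}\b", prog.source_text)

    def test_rule_names_never_appear_in_generated_code(self, lab_ast, activity_ast,
                                                       models):
        for ast in (lab_ast, activity_ast):
            text = compile_map(ast, models).source_text
            for rule_name in _collect_rule_names(ast.groups):
                assert rule_name not in text

    def test_symbol_table_injective_on_group_names(self, lab_ast, models):
        prog = compile_map(lab_ast, models)
        generated = [prog.symbol_table[g.name] for g in lab_ast.groups]
        assert len(set(generated)) == len(generated)

    def test_string_literal_embedded_verbatim(self, activity_ast, models):
        text = compile_map(activity_ast, models).source_text
        assert "'routine'" in text and "'draft'" in text

    def test_now_compiled_to_shared_timestamp(self, activity_ast, models):
        text = compile_map(activity_ast, models).source_text
        assert "ctx.shared_now" in text
        assert "datetime" not in text

    def test_generated_code_imports_only_the_runtime(self, lab_ast, models):
        text = compile_map(lab_ast, models).source_text
        imports = [ln for ln in text.splitlines()
                   if ln.startswith(("import ", "from "))]
        assert imports == ["import sys", "from fmlc import runtime as rt"]

    def test_fml_comments_flag(self, activity_ast, models):
        off = compile_map(activity_ast, models).source_text
        on = compile_map(activity_ast, models, emit_fml_comments=True).source_text
        assert "# FML:" not in off and "# FML:" in on
        for rule_name in _collect_rule_names(activity_ast.groups):
            assert rule_name not in on  # names stay excluded even with comments


class TestDeterminism:
    def test_compiling_twice_is_byte_identical(self, any_map_ast, models):
        assert compile_map(any_map_ast, models).source_text == \
            compile_map(any_map_ast, models).source_text

    def test_same_seed_reruns_are_byte_identical(self, lab_ast, models):
        doc = mini_cda_document(GeneratorConfig(n_observations=3, seed=4))
        src = read_xml(doc, models)
        out1 = run_compiled(lab_ast, models, src, seed=9)
        out2 = run_compiled(lab_ast, models, src, seed=9)
        assert write_fhir_json(out1, models) == write_fhir_json(out2, models)

    def test_different_seeds_agree_after_uuid_normalization(self, lab_ast, models):
        from fmlc import diff_canonical

        doc = mini_cda_document(GeneratorConfig(n_observations=3, seed=4))
        src = read_xml(doc, models)
        a = write_fhir_json(run_compiled(lab_ast, models, src, seed=1), models)
        b = write_fhir_json(run_compiled(lab_ast, models, src, seed=2), models)
        assert a != b  # the UUID streams differ
        assert diff_canonical(a, b, "json") == ""


class TestSanitization:
    def test_rules(self):
        assert sanitize_identifier("a-b") == "a_b"
        assert sanitize_identifier("1st") == "_1st"
        assert sanitize_identifier("plain_name") == "plain_name"

    def test_collision_after_sanitization_is_a_compile_error(self, noop_ast, models):
        g = noop_ast.groups[0]
        clash = StructureMapAST(
            noop_ast.url, noop_ast.name, noop_ast.uses_declarations, (), (),
            (MapGroup("a-b", "none", g.inputs, ()),
             MapGroup("a_b", "none", g.inputs, ())))
        with pytest.raises(CompileError, match="collision"):
            compile_map(clash, models)


class TestGroupCompilation:
    def test_extends_emits_parent_call_first(self, models):
        text = HEADER + """
group Ext(source cda : ClinicalDocument, target b : Bundle) extends Base {
  cda -> b.timestamp = evaluate(cda, now()) "RuleStamp";
}
group Base(source cda : ClinicalDocument, target b : Bundle) {
  cda -> b.type = 'collection' "RuleType";
}
"""
        prog = compile_map(parse_fml(text), models)
        body = prog.source_text.split("def Ext(")[1].split("def ")[0]
        first_stmt = [ln for ln in body.splitlines()[1:] if ln.strip()][0]
        assert first_stmt.strip().startswith("Base(ctx,")
        doc = mini_cda_document(GeneratorConfig(n_observations=0, seed=0))
        compiled, interpreted = both_engines(text, models, doc)
        assert compiled.get("type") and compiled.get("timestamp")
        assert compiled == interpreted

    def test_extends_unknown_group(self, models):
        text = HEADER + ("group G(source cda : ClinicalDocument, "
                         "target b : Bundle) extends Nowhere {}")
        with pytest.raises(CompileError, match="Nowhere"):
            compile_map(parse_fml(text), models)


def _list_mode_map(mode):
    mode_txt = f" {mode}" if mode else ""
    return HEADER + f"""
group G(source cda : ClinicalDocument, target b : Bundle) {{
  cda.component as comp then {{
    comp.observation{mode_txt} as o -> b.entry as e then {{
      o.code as ce then {{
        ce.code as cd -> e.fullUrl = copy(cd) "RuleCopyCode";
      }} "RuleCode";
    }} "RuleObs";
  }} "RuleComp";
}}
"""


class TestRuleSemantics:
    @pytest.mark.parametrize("mode,expected_entries", [
        (None, 4), ("first", 1), ("last", 1), ("not_first", 3), ("not_last", 3),
    ])
    def test_list_modes_agree_with_interpreter(self, models, mode, expected_entries):
        doc = mini_cda_document(GeneratorConfig(n_observations=4, seed=2))
        compiled, interpreted = both_engines(_list_mode_map(mode), models, doc)
        assert len(compiled.get("entry")) == expected_entries
        assert compiled == interpreted

    def test_only_one_violation_is_a_runtime_error_in_both_engines(self, models):
        text = _list_mode_map("only_one")
        doc2 = mini_cda_document(GeneratorConfig(n_observations=2, seed=2))
        ast = parse_fml(text)
        src = read_xml(doc2, models)
        with pytest.raises(CardinalityError):
            run_compiled(ast, models, src)
        with pytest.raises(CardinalityError):
            interpret_map(ast, src, models,
                          ctx=rt.ExecutionContext(models=models, now=NOW))
        doc1 = mini_cda_document(GeneratorConfig(n_observations=1, seed=2))
        compiled, interpreted = both_engines(text, models, doc1)
        assert compiled == interpreted

    def test_where_condition_filters_like_the_interpreter(self, models):
        text = HEADER + """
group G(source cda : ClinicalDocument, target b : Bundle) {
  cda.component as comp then {
    comp.observation as o where valuePQ.exists() -> b.entry as e then {
      o.valuePQ as pq then {
        pq.value as v -> e.fullUrl = copy(v) "RuleVal";
      } "RulePQ";
    } "RuleObs";
  } "RuleComp";
}
"""
        doc = mini_cda_document(GeneratorConfig(n_observations=10, seed=5))
        src_node = read_xml(doc, models)
        with_pq = sum(
            1 for o in src_node.get("component")[0].get("observation")
            if o.get("valuePQ"))
        assert 0 < with_pq < 10  # the seed yields a genuine mix
        compiled, interpreted = both_engines(text, models, doc, seed=3)
        assert len(compiled.get("entry")) == with_pq
        assert compiled == interpreted

    def test_default_value_applies_when_source_is_empty(self, models):
        text = HEADER + """
group G(source cda : ClinicalDocument, target b : Bundle) {
  cda.id default 'none' as i -> b.type = copy(i) "RuleDefault";
}
"""
        doc = '<?xml version="1.0" encoding="UTF-8"?>\n<ClinicalDocument xmlns="urn:example:minicda"/>\n'
        compiled, interpreted = both_engines(text, models, doc)
        assert compiled.get("type")[0].get("value") == ["none"]
        assert compiled == interpreted

    def test_check_failure_raises(self, models):
        text = HEADER + """
group G(source cda : ClinicalDocument, target b : Bundle) {
  cda as c check id.exists() -> b.type = 'collection' "RuleChecked";
}
"""
        doc = '<ClinicalDocument xmlns="urn:example:minicda"/>'
        ast = parse_fml(text)
        src = read_xml(doc, models)
        with pytest.raises(Exception, match="check failed"):
            run_compiled(ast, models, src)
        with pytest.raises(Exception, match="check failed"):
            interpret_map(ast, src, models,
                          ctx=rt.ExecutionContext(models=models, now=NOW))


class TestTransformCompilation:
    def test_truncate_literal_semantics(self, models):
        text = HEADER + """
group G(source cda : ClinicalDocument, target b : Bundle) {
  cda.effectiveTime as t then {
    t.value as v -> b.timestamp = truncate(v, 4) "RuleTrunc";
  } "RuleTime";
}
"""
        doc = mini_cda_document(GeneratorConfig(n_observations=0, seed=0))
        compiled, _ = both_engines(text, models, doc)
        assert compiled.get("timestamp")[0].get("value") == ["2024"]

    def test_create_with_omitted_type_uses_the_model(self, models, manifest):
        # (Bundle, entry) resolves to BundleEntry per the fixture manifest
        text = HEADER + """
group G(source cda : ClinicalDocument, target b : Bundle) {
  cda -> b.entry = create() as e, e.fullUrl = 'urn:x' "RuleCreate";
}
"""
        doc = mini_cda_document(GeneratorConfig(n_observations=0, seed=0))
        compiled, interpreted = both_engines(text, models, doc)
        expected_type = manifest["element_types"]["minifhir.Bundle"]["entry"]
        assert compiled.get("entry")[0].type_ref == expected_type
        assert compiled == interpreted

    def test_arity_mismatch_is_a_compile_error(self, models):
        text = HEADER + ("group G(source cda : ClinicalDocument, target b : Bundle) "
                         "{ cda -> b.type = copy(); }")
        with pytest.raises(CompileError, match="copy"):
            compile_map(parse_fml(text), models)

    def test_unknown_cast_kind_is_a_compile_error(self, models):
        text = HEADER + ("group G(source cda : ClinicalDocument, target b : Bundle) "
                         "{ cda.id as i -> b.type = cast(i, 'complex'); }")
        with pytest.raises(CompileError, match="cast"):
            compile_map(parse_fml(text), models)

    def test_variable_out_of_scope_is_a_compile_error(self, models):
        text = HEADER + ("group G(source cda : ClinicalDocument, target b : Bundle) "
                         "{ cda -> b.type = copy(ghost); }")
        with pytest.raises(CompileError, match="ghost"):
            compile_map(parse_fml(text), models)

    def test_unresolvable_dependent_group_is_a_compile_error(self, models):
        text = HEADER + ("group G(source cda : ClinicalDocument, target b : Bundle) "
                         "{ cda as c then Missing(c, b); }")
        with pytest.raises(CompileError, match="Missing"):
            compile_map(parse_fml(text), models)

    def test_translate_requires_a_known_conceptmap(self, models):
        text = HEADER + ("group G(source cda : ClinicalDocument, target b : Bundle) "
                         "{ cda.id as i -> b.type = translate(i, 'urn:nowhere', 'code'); }")
        with pytest.raises(CompileError, match="urn:nowhere"):
            compile_map(parse_fml(text), models)


TYPES_HEADER = HEADER + """
group Main(source cda : ClinicalDocument, target b : Bundle) {}
"""


class TestResolveDependentGroup:
    def _ast(self, extra=""):
        return parse_fml(TYPES_HEADER + extra)

    def test_explicit_call_wins(self):
        ast = self._ast()
        assert resolve_dependent_group(("Main", ("a", "b")), ast).name == "Main"

    def test_unknown_explicit_name(self):
        with pytest.raises(CompileError, match="Ghost"):
            resolve_dependent_group(("Ghost", ("a",)), self._ast())

    def test_single_types_mode_match(self):
        ast = self._ast(
            "group ById(source p : PatientRole, target pat : Patient) <<types>> {}")
        assert resolve_dependent_group(("PatientRole", "Patient"), ast).name == "ById"

    def test_zero_matches(self):
        with pytest.raises(CompileError, match="no types-mode group"):
            resolve_dependent_group(("PatientRole", "Patient"), self._ast())

    def test_ambiguity_lists_candidates(self):
        ast = self._ast(
            "group A1(source p : PatientRole, target pat : Patient) <<types>> {}\n"
            "group A2(source p : PatientRole, target pat : Patient) <<types>> {}")
        with pytest.raises(AmbiguityError, match="A1"):
            resolve_dependent_group(("PatientRole", "Patient"), ast)


class TestGeneratedProgramContract:
    def test_program_runs_standalone_via_main(self, models, tmp_path, lab_ast):
        prog = compile_map(lab_ast, models)
        src_file = tmp_path / "doc.xml"
        src_file.write_text(mini_cda_document(GeneratorConfig(3, 1)))
        out_file = tmp_path / "bundle.json"
        ns = exec_program(prog.source_text)
        code = ns["main"](["-s", str(src_file), "-t", str(out_file),
                           "--seed", "1", "--now", NOW])
        assert code == 0 and out_file.exists()
        assert '"resourceType": "Bundle"' in out_file.read_text()

    def test_program_reports_format_errors(self, models, tmp_path, lab_ast):
        ns = exec_program(compile_map(lab_ast, models).source_text)
        bad = tmp_path / "doc.txt"
        bad.write_text("x")
        assert ns["main"](["-s", str(bad), "-t", str(tmp_path / "o.json")]) == 4

    def test_required_models_and_conceptmaps_recorded(self, lab_ast, models):
        prog = compile_map(lab_ast, models)
        assert prog.required_models == ["mini-cda", "mini-fhir"]
        assert set(prog.required_conceptmaps) == {
            "http://example.org/conceptmaps/lab-codes",
            "http://example.org/conceptmaps/gender"}
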