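import pytest

from fmlc import compile_map, parse_fml, runtime as rt
from fmlc.fixtures import (
    GeneratorConfig,
    example_map,
    fixture_manifest,
    fixture_models,
    mini_activity_definition,
    mini_cda_document,
)
from fmlc.schema_models import read_fhir_json, read_xml

#: fixed execution timestamp so engine outputs diff cleanly
NOW = "2024-03-01T08:00:00+00:00"


@pytest.fixture(scope="session")
def models():
    return fixture_models()


@pytest.fixture(scope="session")
def manifest():
    return fixture_manifest()


@pytest.fixture(scope="session", params=["noop", "cda_lab_bundle", "activity_supply"])
def any_map_ast(request):
    return parse_fml(example_map(request.param))


@pytest.fixture(scope="session")
def lab_ast():
    return parse_fml(example_map("cda_lab_bundle"))


@pytest.fixture(scope="session")
def activity_ast():
    return parse_fml(example_map("activity_supply"))


@pytest.fixture(scope="session")
def noop_ast():
    return parse_fml(example_map("noop"))


def exec_program(source_text: str) -> dict:
    """Execute generated program text and return its namespace."""
    ns: dict = {"__name__": "fmlc_generated_test"}
    exec(compile(source_text, "<generated>", "exec"), ns)
    return ns


def run_compiled(ast, models, src, seed=0, now=NOW):
    """Compile a map and execute it over a source node."""
    ns = exec_program(compile_map(ast, models).source_text)
    ctx = rt.ExecutionContext(models=models, conceptmaps=ns["CONCEPTMAPS"],
                              seed=seed, now=now)
    return ns["transform"](ctx, src)


def source_for(map_name: str, models, seed: int, n_observations: int = 3):
    """Parsed source instance appropriate for a fixture map."""
    if map_name == "activity_supply":
        return read_fhir_json(mini_activity_definition(seed), models,
                              "minifhir.ActivityDefinition")
    doc = mini_cda_document(GeneratorConfig(n_observations=n_observations,
                                            seed=seed))
    return read_xml(doc, models)
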