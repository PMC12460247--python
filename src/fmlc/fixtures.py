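"""Bundled fixtures and seeded synthetic-data generators.

The mini-CDA document generator emulates the shape of a national laboratory
report at parameterized size: a patient block plus ``n`` observation entries
whose codes are drawn from a committed 10-entry local-code table that matches
the bundled lab-codes ConceptMap, so code translation is exercised on every
generated document.  The same module provides a seeded ActivityDefinition
generator, loaders for the bundled example maps / schemas / FHIRPath case
suite, and a seeded random-expression generator over the supported FHIRPath
grammar.
"""
from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import dataclass, field
from importlib.resources import files

from . import runtime as rt
from .errors import FmlcError
from .schema_models import InstanceNode, ModelSet, write_fhir_json, write_xml

#: local lab code -> (LOINC-style code, display, unit) — kept in sync with
#: the lab-codes ConceptMap fixture
CODE_TABLE = [
    ("L01", "718-7", "Hemoglobin", "g/dL"),
    ("L02", "787-2", "MCV", "fL"),
    ("L03", "6690-2", "Leukocytes", "10*3/uL"),
    ("L04", "777-3", "Platelets", "10*3/uL"),
    ("L05", "2345-7", "Glucose", "mg/dL"),
    ("L06", "2160-0", "Creatinine", "mg/dL"),
    ("L07", "3094-0", "Urea nitrogen", "mg/dL"),
    ("L08", "1751-7", "Albumin", "g/dL"),
    ("L09", "2951-2", "Sodium", "mmol/L"),
    ("L10", "2823-3", "Potassium", "mmol/L"),
]

_GIVEN = ["Anna", "Max", "Lena", "Paul", "Mia", "Jonas", "Eva", "Felix"]
_FAMILY = ["Muster", "Huber", "Gruber", "Bauer", "Wagner", "Steiner"]
_TEXT_VALUES = ["negative", "positive", "borderline", "inconclusive"]

_MAP_NAMES = ("activity_supply", "cda_lab_bundle", "noop")


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic mini-CDA laboratory report."""

    n_observations: int = 10
    seed: int = 0
    patient_fields: frozenset = frozenset({"name", "birth_date", "id"})


def _read_data(relpath: str) -> str:
    return (files("fmlc") / "data" / relpath).read_text()


_MODELS_CACHE: dict = {}


def fixture_models() -> ModelSet:
    """The bundled mini-CDA + mini-FHIR model set (cached)."""
    if "models" not in _MODELS_CACHE:
        _MODELS_CACHE["models"] = rt.load_models(["mini-cda", "mini-fhir"])
    return _MODELS_CACHE["models"]


def example_map(name: str) -> str:
    """FML text of a bundled example map: activity_supply, cda_lab_bundle
    or noop."""
    if name not in _MAP_NAMES:
        raise FmlcError(f"unknown example map {name!r} (choose from {_MAP_NAMES})")
    return _read_data(f"maps/{name}.map")


def conceptmap_fixture(fmt: str = "json") -> str:
    """The standalone lab-codes ConceptMap resource (json or xml)."""
    if fmt not in ("json", "xml"):
        raise FmlcError(f"unknown format {fmt!r}")
    return _read_data(f"conceptmaps/lab-codes.{fmt}")


def fixture_manifest() -> dict:
    """Hand-written manifest of the fixture schemas (test oracle)."""
    return json.loads(_read_data("manifests/fixture_manifest.json"))


# ---------------------------------------------------------------------------
# mini-CDA laboratory report generator
# ---------------------------------------------------------------------------

def _decimal_text(rng: random.Random, lo: int = 1, hi: int = 200) -> str:
    return f"{rng.randrange(lo, hi)}.{rng.randrange(0, 10)}"


def mini_cda_document(cfg: GeneratorConfig) -> str:
    """A seeded synthetic mini-CDA laboratory report as XML text.

    Same config -> byte-identical document; exactly ``cfg.n_observations``
    observation entries with code/value/unit/effective-time drawn from
    seeded tables.
    """
    models = fixture_models()
    rng = random.Random(cfg.seed)
    doc = InstanceNode("minicda.ClinicalDocument")

    doc_id = InstanceNode("minicda.II")
    doc_id.add("root", "1.2.40.0.34.99")
    doc_id.add("extension", f"DOC-{rng.randrange(10_000, 100_000)}")
    doc.add("id", doc_id)
    doc.add("code", _ce(models, "11502-2", "2.16.840.1.113883.6.1",
                        "Laboratory report"))
    eff = InstanceNode("minicda.TS")
    eff.add("value", "2024-03-01T08:00:00")
    doc.add("effectiveTime", eff)

    record = InstanceNode("minicda.RecordTarget")
    role = InstanceNode("minicda.PatientRole")
    if "id" in cfg.patient_fields:
        pid = InstanceNode("minicda.II")
        pid.add("root", "1.2.40.0.34.3.1")
        pid.add("extension", f"PAT-{rng.randrange(1000, 10_000)}")
        role.add("id", pid)
    patient = InstanceNode("minicda.Patient")
    if "name" in cfg.patient_fields:
        pn = InstanceNode("minicda.PN")
        given = InstanceNode("minicda.ENXP")
        given.add("_text", rng.choice(_GIVEN))
        family = InstanceNode("minicda.ENXP")
        family.add("_text", rng.choice(_FAMILY))
        pn.add("given", given)
        pn.add("family", family)
        patient.add("name", pn)
    gender = InstanceNode("minicda.CE")
    gender.add("code", rng.choice(["M", "F", "U"]))
    gender.add("codeSystem", "urn:example:gender")
    patient.add("administrativeGenderCode", gender)
    if "birth_date" in cfg.patient_fields:
        birth = _dt.date(1950, 1, 1) + _dt.timedelta(days=rng.randrange(0, 20_000))
        bt = InstanceNode("minicda.TS")
        bt.add("value", birth.isoformat() + "T00:00:00")
        patient.add("birthTime", bt)
    role.add("patient", patient)
    record.add("patientRole", role)
    doc.add("recordTarget", record)

    component = InstanceNode("minicda.Component")
    base_time = _dt.datetime(2024, 3, 1, 8, 0, 0)
    for i in range(cfg.n_observations):
        local, _loinc, display, unit = rng.choice(CODE_TABLE)
        obs = InstanceNode("minicda.Observation")
        obs.add("code", _ce(models, local, "urn:example:labcodes", display))
        status = InstanceNode("minicda.CE")
        status.add("code", "completed")
        obs.add("statusCode", status)
        ts = InstanceNode("minicda.TS")
        ts.add("value", (base_time + _dt.timedelta(minutes=30 * i)).isoformat())
        obs.add("effectiveTime", ts)
        if rng.random() < 0.8:
            pq = InstanceNode("minicda.PQ")
            pq.add("value", _decimal_text(rng))
            pq.add("unit", unit)
            obs.add("valuePQ", pq)
        else:
            st = InstanceNode("minicda.ENXP")
            st.add("_text", rng.choice(_TEXT_VALUES))
            obs.add("valueST", st)
        component.add("observation", obs)
    doc.add("component", component)
    return write_xml(doc, models)


def _ce(models: ModelSet, code: str, system: str, display: str) -> InstanceNode:
    ce = InstanceNode("minicda.CE")
    ce.add("code", code)
    ce.add("codeSystem", system)
    ce.add("displayName", display)
    return ce


def mini_activity_definition(seed: int = 0, fmt: str = "json") -> str:
    """A seeded synthetic ActivityDefinition instance.

    Cycles through three item variants so every branch of the bundled
    ActivityDefinition map is exercised across seeds: a fully coded concept,
    a text-only concept (no coding), and a bare name.
    """
    models = fixture_models()
    rng = random.Random(seed)
    ad = InstanceNode("minifhir.ActivityDefinition", resource_kind="ActivityDefinition")
    ad_id = InstanceNode("minifhir.id")
    ad_id.add("value", f"ad-{rng.randrange(1000, 10_000)}")
    ad.add("id", ad_id)
    status = InstanceNode("minifhir.code")
    status.add("value", rng.choice(["active", "draft", "retired"]))
    ad.add("status", status)
    variant = seed % 3
    if variant == 0:  # coded concept
        cc = InstanceNode("minifhir.CodeableConcept")
        coding = InstanceNode("minifhir.Coding")
        for elem, val in (("system", "urn:example:supply"),
                          ("code", f"SUP{rng.randrange(1, 50):02d}"),
                          ("display", "Supply item")):
            prim = InstanceNode("minifhir.uri" if elem == "system" else
                                ("minifhir.code" if elem == "code" else
                                 "minifhir.string"))
            prim.add("value", val)
            coding.add(elem, prim)
        cc.add("coding", coding)
        ad.add("code", cc)
    elif variant == 1:  # text-only concept (exercises the generic-coding rule)
        cc = InstanceNode("minifhir.CodeableConcept")
        text = InstanceNode("minifhir.string")
        text.add("value", rng.choice(["Bandage", "Syringe", "Gauze"]))
        cc.add("text", text)
        ad.add("code", cc)
    else:  # bare name (exercises the cc() rule)
        name = InstanceNode("minifhir.string")
        name.add("value", rng.choice(["BloodPressureCuff", "Thermometer"]))
        ad.add("name", name)
    qty = InstanceNode("minifhir.Quantity")
    qval = InstanceNode("minifhir.decimal")
    qval.add("value", str(rng.randrange(1, 20)))
    qunit = InstanceNode("minifhir.string")
    qunit.add("value", "units")
    qty.add("value", qval)
    qty.add("unit", qunit)
    ad.add("quantity", qty)
    if fmt == "json":
        return write_fhir_json(ad, models)
    return write_xml(ad, models)


# ---------------------------------------------------------------------------
# FHIRPath case suite
# ---------------------------------------------------------------------------

def fhirpath_case_suite() -> tuple[dict, list[dict]]:
    """(shared input document, case list) of the bundled FHIRPath suite."""
    data = json.loads(_read_data("fhirpath/cases.json"),
                      parse_float=lambda s: __import__("decimal").Decimal(s))
    return data["input"], data["cases"]


# ---------------------------------------------------------------------------
# Seeded random FHIRPath expressions (grammar-restricted, type-safe)
# ---------------------------------------------------------------------------

#: the document random expressions are evaluated against
SAMPLE_DOC = {
    "name": [
        {"use": "official", "given": ["Anna", "Maria"], "family": "Muster"},
        {"use": "nickname", "given": ["Ami"], "family": "M"},
    ],
    "birthDate": "1980-04-02",
    "active": True,
    "score": 7,
    "items": [{"value": 3}, {"value": 7}, {"value": 9}],
}

_INT_PATHS = ["score", "items.value.first()", "items.value.last()",
              "name.count()", "items.count()", "name.given.count()"]
_STR_PATHS = ["birthDate", "name.first().family", "name[0].use",
              "name.last().use"]
_COLL_PATHS = ["name.given", "items.value", "name.family", "missing"]


def _int_expr(rng: random.Random, depth: int) -> str:
    if depth >= 2 or rng.random() < 0.4:
        return rng.choice(_INT_PATHS + [str(rng.randrange(0, 20))])
    op = rng.choice(["+", "-", "*", "div", "mod"])
    left = _int_expr(rng, depth + 1)
    right = (str(rng.randrange(1, 9)) if op in ("div", "mod")
             else _int_expr(rng, depth + 1))
    return f"({left} {op} {right})"


def _str_expr(rng: random.Random, depth: int) -> str:
    if depth >= 2 or rng.random() < 0.5:
        return rng.choice(_STR_PATHS + ["'alpha'", "'beta'", "'x-1'"])
    kind = rng.randrange(3)
    if kind == 0:
        return f"({_str_expr(rng, depth + 1)} & {_str_expr(rng, depth + 1)})"
    if kind == 1:
        return f"{_str_expr(rng, depth + 1)}.substring(0, {rng.randrange(1, 5)})"
    return f"{_int_expr(rng, depth + 1)}.toString()"


def _bool_expr(rng: random.Random, depth: int) -> str:
    if depth >= 2:
        return rng.choice(["true", "false", "active"])
    kind = rng.randrange(6)
    if kind == 0:
        op = rng.choice(["=", "!=", "<", "<=", ">", ">="])
        return f"({_int_expr(rng, depth + 1)} {op} {_int_expr(rng, depth + 1)})"
    if kind == 1:
        return f"({_str_expr(rng, depth + 1)} = {_str_expr(rng, depth + 1)})"
    if kind == 2:
        return f"{rng.choice(_COLL_PATHS)}.exists()"
    if kind == 3:
        return f"{rng.choice(_COLL_PATHS)}.empty()"
    if kind == 4:
        op = rng.choice(["and", "or", "xor", "implies"])
        return f"({_bool_expr(rng, depth + 1)} {op} {_bool_expr(rng, depth + 1)})"
    return f"{_bool_expr(rng, depth + 1)}.not()"


def _coll_expr(rng: random.Random, depth: int) -> str:
    base = rng.choice(_COLL_PATHS)
    kind = rng.randrange(5)
    if kind == 0:
        return f"items.where(value > {rng.randrange(0, 12)}).value"
    if kind == 1:
        return f"{base}.first()"
    if kind == 2:
        return f"{base} | {rng.choice(_COLL_PATHS)}"
    if kind == 3:
        return f"items.select(value + {rng.randrange(0, 5)})"
    return base


def random_expression(rng: random.Random) -> str:
    """A random expression from the supported grammar, type-safe over
    :data:`SAMPLE_DOC` by construction."""
    kind = rng.randrange(4)
    if kind == 0:
        return _int_expr(rng, 0)
    if kind == 1:
        return _str_expr(rng, 0)
    if kind == 2:
        return _bool_expr(rng, 0)
    return _coll_expr(rng, 0)
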