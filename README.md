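# fmlc — a FHIR Mapping Language compiler

Clinical data rarely arrives in the format it is needed in: national
electronic-health-record systems still exchange HL7 CDA documents while
modern infrastructure expects FHIR resources, and even FHIR deployments mix
versions. HL7's **FHIR Mapping Language (FML)** describes such
structure-to-structure transformations declaratively — groups of rules with
source and target clauses, embedded FHIRPath expressions, and ConceptMap
code translations — but the engines that execute FML are interpreters, and
interpretation is slow at document scale.

`fmlc` takes the compilation route: it parses FML text (or StructureMap
resources in XML/JSON) and emits a **standalone, human-traceable Python
program** over typed data models derived from XML Schemas. The generated
program reads a source document (XML or FHIR JSON), executes the mapping,
and writes the target document. An in-package **reference interpreter**
executes the same mapping AST directly through the same runtime helpers;
compiled output is verified against it by canonical diff, with v4 UUIDs as
the only permitted difference class.

It is intended for health-data-interoperability engineers who maintain FML
mappings and need them to run fast, and who want to be able to *read* what
their mapping actually does in the generated code.

## The model

An FML map is a set of groups; each group `G(source s : S, target t : T)`
contains rules of the form

```
s.element as v where <FHIRPath> -> t.element = transform(...) "rule-name";
```

A rule iterates the source element's collection (optionally filtered by a
FHIRPath condition and restricted by a list mode such as `first` or
`only_one`), applies a transform — `copy`, `create`, `translate`, `append`,
`cast`, `truncate`, `evaluate`, `cc`, `c`, `uuid` — and routes the result
through cardinality-aware assignment into the target tree. Nested rules and
dependent-group calls give the language its recursive structure.

The compiler's contract, checked by the test suite:

* **Traceability** — the generated function for a group is named identically
  to the group (sanitization only); parameter and variable identifiers are
  preserved; rule names are deliberately excluded from the output.
* **Semantics by construction** — compiled programs and the reference
  interpreter share one runtime (assignment, ConceptMap translation, the
  execution-scoped `now()` timestamp, the seeded UUID source), so the two
  engines differ only in dispatch. Where the schema fixes a type at compile
  time, the compiler emits direct, specialized code; where it cannot, the
  generated code falls back to the runtime's dynamic dispatch.
* **Determinism** — equal inputs and seeds give byte-identical programs and
  byte-identical outputs; decimals keep their lexical form end to end.

## Worked example

Write a bundled example map and a synthetic input, compile, and run:

```python
from fmlc.fixtures import example_map, mini_activity_definition
open("ActivityToSupply.map", "w").write(example_map("activity_supply"))
open("activity.json", "w").write(mini_activity_definition(1))
```

```
$ fmlc compile -m ActivityToSupply.map -co activityToSupply.py
$ python activityToSupply.py -s activity.json -t supply.json \
      --seed 42 --now 2026-09-25T10:00:00+02:00
```

The input was an ActivityDefinition whose item is described only by a
text-only concept (`"text": "Bandage"`, no coding). `supply.json` then
contains:

```json
{
  "resourceType": "SupplyRequest",
  "identifier": [
    {"system": "urn:example:activity-ids", "value": "ad-3201"},
    {"system": "urn:ietf:rfc:3986",
     "value": "bdd640fb-0667-41ad-91c8-317fa3b1799d"}
  ],
  "status": "draft",
  "priority": "routine",
  "itemCodeableConcept": {
    "coding": [{"system": "urn:example:supply", "code": "GEN",
                "display": "Generic supply"}],
    "text": "Bandage"
  },
  "quantity": {"value": 9, "unit": "units"},
  "occurrenceDateTime": "2026-09-25T10:00:00+02:00",
  "authoredOn": "2026-09-25T10:00:00+02:00"
}
```

Reading the values: the map copied the source id into an identifier and
added a second, UUID-valued identifier (reproducible because `--seed 42`
fixed the UUID stream); the literals `draft` and `routine` were embedded
directly; the `where coding.exists().not()` rule fired because the concept
had no coding, adding the generic coding; and both timestamps carry the
single execution-scoped `now()` value fixed by `--now`. The corresponding
generated function is named `ActivityDefinitionToSupplyRequest`, after the
FML group, with the variables `aid`, `iid`, `q`, `c`, `icc`, `nm` preserved
— open `activityToSupply.py` and read it.

The same CLI transforms documents in one step (`fmlc transform -m <map>
-s <source> -t <target>`, with `--interpret` switching to the reference
interpreter) and benchmarks both engines (`fmlc benchmark`).

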