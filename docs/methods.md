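# Methods

This note documents the models, algorithms and design choices behind
`fmlc`: what the compiler and its reference interpreter actually compute,
what the bundled synthetic data does and does not emulate, and where the
design was genuinely open.

## Typed models from a restricted XSD dialect

`schema_models` parses a deliberately restricted XML-Schema dialect —
`complexType` with `sequence`/`choice`/`attribute`, `complexContent`
extension, `simpleContent` over builtin simple types, and top-level element
declarations — into `ModelDescriptor` sets. Substitution groups, `xs:any`,
`ref=` and `redefine` are rejected with errors naming the construct and
source line; the dialect covers the bundled mini schemas, and anything a
real deployment needs beyond it should fail loudly rather than silently.

Conventions that the rest of the system relies on:

* Type names are qualified `family.Local` (`minicda.Observation`,
  `minifhir.Observation`); families correspond to schema documents, so the
  two `Observation`s never collide. Group-input type names written without
  qualification are disambiguated by the mode (source/target) families
  declared in the map's `uses` clauses.
* FHIR-style primitives are complex types with a single `value` attribute;
  the XSD type of that attribute decides the JSON rendering (string,
  boolean, number). `simpleContent` text lives under the reserved element
  name `_text`. One serializer pair therefore covers both model families.
* A type is a *resource* when its base chain reaches a type named
  `Resource`; a type whose elements form one choice of resource types is a
  *resource container* (`Bundle.entry.resource`), rendered transparently in
  JSON via `resourceType` and as a wrapper element in XML.
* Decimals are lexical strings end to end. They are validated, never
  converted through binary floating point, so serialization is byte-exact
  (`7.20` stays `7.20`).

Canonical XML output is UTF-8 with LF newlines, two-space indentation,
attributes and children in schema declaration order, and self-closed empty
elements; namespace prefixes are assigned deterministically (`ns1, ns2, …`
in family declaration order, first family as the default namespace). The
JSON writer emits keys in schema order with `resourceType` first. FHIR JSON
itself leaves key order and decimal rendering open; these canonical choices
are ours and exist so that equality of documents is equality of bytes.

## FML front end

The FML parser is a hand-written recursive-descent parser over a shared
token stream; embedded FHIRPath conditions (`where`, `check`, unquoted
`evaluate` arguments) are parsed *in place* by handing the same token
stream to the FHIRPath parser, which naturally stops at tokens that cannot
extend an expression (`->`, `;`, `then`, …). FHIRPath text is parsed
eagerly and the original text retained for re-serialization.

Supported grammar subset: map header, `uses`/`imports`, `conceptmap`
blocks, groups with `extends` and `<<types>>`/`<<type+>>` modes, rules with
one source clause (a deliberate restriction), nested rules, dependent-group
calls, and the ten transforms `copy, create, translate, append, cast,
truncate, evaluate, cc, c, uuid`. Other transforms are rejected at parse
time with their name. Quoted identifiers make keywords usable as element
names; strings support `\n \t \r \f \\ \' \"` escapes. Comments are
discarded: AST equality, not source fidelity, is the round-trip contract.
Rules without names get internal ids (`g<k>_r<j>`) for diagnostics only;
these are excluded from AST equality and never emitted.

The same AST is produced from StructureMap resources in XML or JSON, and
serialized back deterministically; transform parameters map to
`valueId`/`valueString`/`valueInteger`/`valueDecimal`/`valueBoolean`, and
concept-map relationship codes are kept as the internal vocabulary
`equivalent | wider | narrower | related` (FML operators `==`, `<=`, `>=`,
`-`). `load_imports` resolves a local URI→text mapping transitively,
accepting FML, StructureMap and ConceptMap texts, and reports cycles with
the offending chain.

## FHIRPath engine

The supported subset: literals (string, integer, decimal, boolean,
date/datetime), path navigation, 0-based indexing (out of range yields
empty), the functions `where exists empty first last count select iif not
contains startsWith substring toString toInteger now today`, the operators
`= != < <= > >= and or xor implies + - * / div mod & |`, and `is`/`as`.
Unsupported functions fail at parse time.

Evaluation follows collection semantics: every result is a collection,
empty propagates through operators, comparisons coerce singletons, and
three-valued logic treats empty as unknown. Primitive-model nodes unwrap to
their lexical strings; a lexical string meeting a number or boolean in a
comparison is coerced (this is what makes `value > 5` work against
attribute-carried CDA values). Arithmetic is exact-decimal. A `where`
condition evaluating to empty counts as false — the specification-following
reading of boolean conversion; the alternative (propagating empty) would
make filters undecidable.

Emission is a single traversal producing a Python expression per AST node,
referencing only the runtime helper namespace (`rt.*`), the execution
context (`ctx`) and local variables. String literals embed verbatim (a
literal emits as `['routine']` — collection-valued like every emitted
expression, with no helper call); `now()` emits as `[ctx.shared_now]`, a
reference to the single execution-scoped timestamp, never a clock read. The
evaluator and the emitted code call the *same* collection helpers, so the
two execution paths share one semantics by construction; their agreement is
still tested over the committed case suite and 200 seeded random
expressions drawn from the supported grammar (generator in
`fmlc.fixtures`, seed recorded in the tests).

`simplify` applies a fixed, idempotent catalogue of semantics-preserving
rewrites: constant folding of literal arithmetic/boolean operators,
`X.exists().not()` → `X.empty()`, `X.where(true)` → `X`, and `X.first()` →
`X` when the model proves the path is a singleton (skipped when the static
type is unknown). Simplification runs before emission.

## Compilation

`compile_map` emits one Python function per group, named after the group by
sanitization only (characters outside `[A-Za-z0-9_]` become `_`, leading
digits get a `_` prefix; collisions after sanitization are compile errors
rather than silent renames). Parameters follow FML input order after the
execution context; `extends` compiles to a leading call of the parent's
function. Rules become flat procedural statements — iteration over the
source element's collection with list-mode slicing (`only_one` guarded by a
runtime cardinality check), `where` conditions as emitted-expression
filters, `check` as runtime assertions, nested rules as lexically nested
blocks, dependent calls as calls to the generated group functions.
Duplicated conditionals are deliberately not factored out; the generated
code should read like the map. The original FML can be embedded as comments
behind a compiler flag (default off); rule names stay excluded either way.

Static type information drives specialization, which is the point of
compiling: where the model resolves a (context type, element) pair at
compile time, the generated code accesses and assigns the values dictionary
directly, constructs primitive and container nodes with their types inlined,
and replaces `translate` calls with constant lookup tables baked into the
program (ConceptMaps are compile-time constants; unmapped and ambiguous
codes keep their runtime error behavior). Where a type cannot be
determined, the generated code calls the runtime's dynamic dispatch
(`rt.assign`, `rt.iter_items`, `rt.create_for`), which resolves elements
through the models at run time — the fallback path and the interpreter's
only path.

Cast semantics are a fixed, documented table: `string ↔ integer`,
`string ↔ decimal` (lexically preserved), `string ↔ boolean`, and
date/dateTime widening by truncation; anything else is an error, at compile
time when statically known.

Generated programs depend only on `fmlc.runtime` and the model schemas
(referenced by registry name or `family:path` origin). Their CLI contract is
`-s <source> -t <target>` plus `--seed` (UUID stream) and `--now`
(timestamp), with formats inferred from file extensions; exit code 0 on
success, 4 with a diagnostic on mapping errors.

## Runtime and reference interpreter

The runtime holds the per-execution state: one timestamp captured at start
(host-local offset, ISO-8601 — the "evaluated once per execution" contract),
a UUID source that is OS-random by default and reproducible when seeded,
and registered ConceptMaps. Assignment is cardinality-aware — singletons
replace (documented, not an error), repeating elements append in order,
scalars are wrapped into primitive-model nodes, resources are wrapped into
containers (the bound variable is the resource, not the wrapper). Unmatched
ConceptMap codes raise rather than pass through: silent pass-through hides
mapping gaps. Relationship codes are recorded but not filtered on.

The reference interpreter walks the same AST directly, resolving groups,
types and elements dynamically on every step, and shares the runtime's
assignment/translation/timestamp/UUID helpers, so the engines differ only
in dispatch. Compiler/interpreter equivalence over the full fixture matrix
(maps × seeded inputs × output formats) is the package's core test; the
canonical diff normalizes v4-UUID tokens and whitespace and nothing else.
The interpreter is the semantic baseline, not a fast engine; performance is
an explicit non-goal for it.

## Synthetic data

The mini-CDA generator emulates the *shape* of a national laboratory
report, not any real template: a patient block (name, birth time,
identifier, gender) and `n` observation entries whose codes come from a
committed 10-entry local-code table matched by the bundled lab-codes
ConceptMap, with seeded decimal values and units (80 % quantitative
results, 20 % textual — so both choice branches of the observation value
are exercised), and ISO timestamps. Same configuration, same bytes. The
ActivityDefinition generator cycles three item variants (coded concept,
text-only concept, bare name) so every branch of the example map runs
across seeds. Default sizes: 10 observations for general use; the
conformance matrix varies 0–6; the benchmark uses n=1000.

What this does **not** emulate: real CDA nesting depth and section
narrative, null flavors, templated identifiers, realistic value
distributions, or FHIR primitive extensions. Passing tests show the
transformation machinery is exact on models of this shape; they say nothing
about coverage of full CDA/FHIR schemas, which are out of scope.

## Benchmark design

The benchmark follows a warm-up (5 cycles) plus test phase (50 cycles)
protocol and reports mean/min/max/median/std per engine and example,
together with overhead-adjusted means: example mean minus the mean of the
zero-rule no-op mapping, per engine. Design choices:

* The source document is parsed once, outside the timed region; a cycle is
  context setup plus mapping execution. The no-op baseline therefore
  captures the per-cycle fixed costs, and the adjusted value isolates
  mapping execution — the only quantity on which the engines differ.
  Parsing and serialization are byte-identical between engines.
* Cycles are interleaved across the four engine × example combinations so
  machine-load drift affects all means equally and cancels in the
  adjustment.
* The cyclic garbage collector is paused (and existing objects frozen)
  during the timed phase: transformation garbage is acyclic and
  reference-counted, and collector sweeps over the parsed source tree would
  otherwise land on arbitrary cycles.

On the n=1000 synthetic laboratory report, adjusted compiled execution is
around 8 ms versus around 46 ms interpreted (≈ 5–6×) on the development
machine; absolute numbers are hardware-dependent and the test suite asserts
only the relative property.

## Known limitations

* The XSD, FML and FHIRPath subsets are fixed and closed; unsupported
  constructs fail with named errors instead of approximating.
* Inputs are assumed valid; readers reject unknown elements and keys, and
  translation failures are errors, but there is no schema validation pass
  or recovery behavior for malformed mappings.
* One host language (Python) and one internal mapping dialect; R4/R5
  StructureMap dialect differences, FHIR primitive-extension JSON
  (`_element` siblings), and unit-conversion FHIRPath functions are out of
  scope.
* Relationship-based ConceptMap filtering (e.g. excluding `narrower`
  matches) is recorded but not applied; a future configuration hook could
  filter.
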