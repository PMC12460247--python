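// Minimal mapping without transformation instructions: baseline for
// overhead estimation.  Reads a ClinicalDocument, emits an empty Bundle.
map "http://example.org/maps/Noop" = "Noop"

uses "http://example.org/models/minicda/ClinicalDocument" alias ClinicalDocument as source
uses "http://example.org/models/minifhir/Bundle" alias Bundle as target

group Noop(source cda : ClinicalDocument, target bundle : Bundle) {
}
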