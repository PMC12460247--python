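// ActivityDefinition -> SupplyRequest example mapping (mini-FHIR scale).
// Exercises copy of literals and complex nodes, cc/c construction,
// conditional sources, evaluate with now(), append and uuid.
map "http://example.org/maps/ActivityToSupply" = "ActivityToSupply"

uses "http://example.org/models/minifhir/ActivityDefinition" alias ActivityDefinition as source
uses "http://example.org/models/minifhir/SupplyRequest" alias SupplyRequest as target

group ActivityDefinitionToSupplyRequest(source src : ActivityDefinition, target tgt : SupplyRequest) {
  src.id as aid -> tgt.identifier as iid, iid.system = 'urn:example:activity-ids', iid.value = copy(aid) "RuleSourceIdentifier";
  src -> tgt.identifier as uid, uid.system = 'urn:ietf:rfc:3986', uid.value = uuid() "RuleUuidIdentifier";
  src -> tgt.status = 'draft' "RuleStatus";
  src -> tgt.priority = 'routine' "RulePriority";
  src.quantity as q -> tgt.quantity = copy(q) "RuleQuantity";
  src.code as c -> tgt.itemCodeableConcept = copy(c) "RuleItem";
  src.code as c2 where coding.exists().not() -> tgt.itemCodeableConcept as icc, icc.coding = c('urn:example:supply', 'GEN', 'Generic supply') "RuleGenericCoding";
  src.name as nm -> tgt.itemCodeableConcept = cc(nm) "RuleItemFromName";
  src -> tgt.occurrenceDateTime = evaluate(src, now()) "RuleWhen";
  src -> tgt.authoredOn = evaluate(src, 'now()') "RuleAuthored";
}
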