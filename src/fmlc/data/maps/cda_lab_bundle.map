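/* Laboratory report conversion: mini-CDA ClinicalDocument -> mini-FHIR
   Bundle.  Exercises iteration over repeating elements, nested rules,
   dependent group calls, translate through embedded concept maps, cast,
   truncate, append, uuid and choice elements on both sides. */
map "http://example.org/maps/CdaLabToBundle" = "CdaLabToBundle"

uses "http://example.org/models/minicda/ClinicalDocument" alias ClinicalDocument as source
uses "http://example.org/models/minifhir/Bundle" alias Bundle as target

conceptmap "http://example.org/conceptmaps/lab-codes" {
  prefix s = "urn:example:labcodes"
  prefix t = "http://loinc.org"

  s:L01 == t:"718-7"
  s:L02 == t:"787-2"
  s:L03 == t:"6690-2"
  s:L04 == t:"777-3"
  s:L05 == t:"2345-7"
  s:L06 == t:"2160-0"
  s:L07 == t:"3094-0"
  s:L08 == t:"1751-7"
  s:L09 == t:"2951-2"
  s:L10 == t:"2823-3"
}

conceptmap "http://example.org/conceptmaps/gender" {
  prefix g = "urn:example:gender"
  prefix a = "http://hl7.org/fhir/administrative-gender"

  g:M == a:male
  g:F == a:female
  g:U == a:unknown
}

group CdaToBundle(source cda : ClinicalDocument, target bundle : Bundle) {
  cda -> bundle.type = 'collection' "RuleBundleType";
  cda -> bundle.timestamp = evaluate(cda, now()) "RuleTimestamp";
  cda.recordTarget as rec -> bundle.entry as pe then {
    rec -> pe.fullUrl = uuid() "RulePatientUrl";
    rec.patientRole as pr -> pe.resource = create('Patient') as pat then PatientRoleToPatient(pr, pat) "RulePatientResource";
  } "RulePatientEntry";
  cda.component as comp then {
    comp.observation as obs -> bundle.entry as oe then {
      obs -> oe.fullUrl = uuid() "RuleObsUrl";
      obs -> oe.resource = create('Observation') as fobs then ObservationToFhir(obs, fobs) "RuleObsResource";
    } "RuleObsEntry";
  } "RuleComponent";
}

group PatientRoleToPatient(source pr : PatientRole, target pat : Patient) {
  pr.id as cid -> pat.identifier as pid then {
    cid.root as idroot -> pid.system = append('urn:oid:', idroot) "RuleIdSystem";
    cid.extension as idext -> pid.value = copy(idext) "RuleIdValue";
  } "RuleIdentifiers";
  pr.patient as p then PatientToFhir(p, pat) "RulePatient";
}

group PatientToFhir(source p : Patient, target pat : Patient) {
  p.name as n -> pat.name as hn then {
    n -> hn.use = 'official' "RuleNameUse";
    n.given first as giv -> hn.given = copy(giv) "RuleGiven";
    n.family first as fam -> hn.family = copy(fam) "RuleFamily";
  } "RuleName";
  p.birthTime as bt then {
    bt.value as bv -> pat.birthDate = truncate(bv, 10) "RuleBirthDate";
  } "RuleBirthTime";
  p.administrativeGenderCode as gc then {
    gc.code as gcode -> pat.gender = translate(gcode, 'http://example.org/conceptmaps/gender', 'code') "RuleGenderCode";
  } "RuleGender";
}

group ObservationToFhir(source o : Observation, target fo : Observation) {
  o -> fo.status = 'final' "RuleObsStatus";
  o.code as oc then {
    oc.code as occode -> fo.code as fcc, fcc.coding = translate(occode, 'http://example.org/conceptmaps/lab-codes', 'Coding') "RuleCodeTranslate";
    oc.displayName as disp -> fo.code as fcc2, fcc2.text = copy(disp) "RuleCodeText";
  } "RuleCode";
  o.effectiveTime as oet then {
    oet.value as oev -> fo.effectiveDateTime = copy(oev) "RuleEffective";
  } "RuleEffectiveTime";
  o.valuePQ as pq -> fo.valueQuantity as qty then {
    pq.value as pqv -> qty.value = cast(pqv, 'decimal') "RuleQuantityValue";
    pq.unit as pqu -> qty.unit = copy(pqu) "RuleQuantityUnit";
  } "RuleValueQuantity";
  o.valueST as vst -> fo.valueString = copy(vst) "RuleValueString";
}
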