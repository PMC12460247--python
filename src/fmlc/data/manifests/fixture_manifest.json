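{
  "_comment": "Hand-written manifest of the bundled fixture schemas, maintained alongside the XSD files. Used by the tests as an independent oracle for schema parsing and element-type resolution.",
  "types": {
    "minifhir": [
      "string", "code", "uri", "id", "boolean", "integer", "decimal",
      "date", "dateTime", "Resource", "Coding", "CodeableConcept",
      "Quantity", "Identifier", "HumanName", "Reference", "Patient",
      "Observation", "ActivityDefinition", "SupplyRequest",
      "ResourceContainer", "BundleEntry", "Bundle"
    ],
    "minicda": [
      "II", "TS", "CE", "PQ", "ENXP", "PN", "Patient", "PatientRole",
      "RecordTarget", "Observation", "Component", "ClinicalDocument"
    ]
  },
  "element_types": {
    "minifhir.string": {"value": "xs:string"},
    "minifhir.code": {"value": "xs:string"},
    "minifhir.uri": {"value": "xs:string"},
    "minifhir.id": {"value": "xs:string"},
    "minifhir.boolean": {"value": "xs:boolean"},
    "minifhir.integer": {"value": "xs:integer"},
    "minifhir.decimal": {"value": "xs:decimal"},
    "minifhir.date": {"value": "xs:date"},
    "minifhir.dateTime": {"value": "xs:dateTime"},
    "minifhir.Resource": {"id": "minifhir.id"},
    "minifhir.Coding": {
      "system": "minifhir.uri",
      "code": "minifhir.code",
      "display": "minifhir.string"
    },
    "minifhir.CodeableConcept": {
      "coding": "minifhir.Coding",
      "text": "minifhir.string"
    },
    "minifhir.Quantity": {
      "value": "minifhir.decimal",
      "unit": "minifhir.string",
      "system": "minifhir.uri",
      "code": "minifhir.code"
    },
    "minifhir.Identifier": {
      "system": "minifhir.uri",
      "value": "minifhir.string"
    },
    "minifhir.HumanName": {
      "use": "minifhir.code",
      "family": "minifhir.string",
      "given": "minifhir.string"
    },
    "minifhir.Reference": {
      "reference": "minifhir.string",
      "display": "minifhir.string"
    },
    "minifhir.Patient": {
      "id": "minifhir.id",
      "identifier": "minifhir.Identifier",
      "name": "minifhir.HumanName",
      "gender": "minifhir.code",
      "birthDate": "minifhir.date"
    },
    "minifhir.Observation": {
      "id": "minifhir.id",
      "identifier": "minifhir.Identifier",
      "status": "minifhir.code",
      "code": "minifhir.CodeableConcept",
      "subject": "minifhir.Reference",
      "effectiveDateTime": "minifhir.dateTime",
      "valueQuantity": "minifhir.Quantity",
      "valueString": "minifhir.string",
      "valueCodeableConcept": "minifhir.CodeableConcept"
    },
    "minifhir.ActivityDefinition": {
      "id": "minifhir.id",
      "name": "minifhir.string",
      "status": "minifhir.code",
      "code": "minifhir.CodeableConcept",
      "quantity": "minifhir.Quantity"
    },
    "minifhir.SupplyRequest": {
      "id": "minifhir.id",
      "identifier": "minifhir.Identifier",
      "status": "minifhir.code",
      "priority": "minifhir.code",
      "itemCodeableConcept": "minifhir.CodeableConcept",
      "itemReference": "minifhir.Reference",
      "quantity": "minifhir.Quantity",
      "occurrenceDateTime": "minifhir.dateTime",
      "authoredOn": "minifhir.dateTime"
    },
    "minifhir.ResourceContainer": {
      "Patient": "minifhir.Patient",
      "Observation": "minifhir.Observation",
      "ActivityDefinition": "minifhir.ActivityDefinition",
      "SupplyRequest": "minifhir.SupplyRequest"
    },
    "minifhir.BundleEntry": {
      "fullUrl": "minifhir.uri",
      "resource": "minifhir.ResourceContainer"
    },
    "minifhir.Bundle": {
      "id": "minifhir.id",
      "type": "minifhir.code",
      "timestamp": "minifhir.dateTime",
      "entry": "minifhir.BundleEntry"
    },
    "minicda.II": {"root": "xs:string", "extension": "xs:string"},
    "minicda.TS": {"value": "xs:string"},
    "minicda.CE": {
      "code": "xs:string",
      "codeSystem": "xs:string",
      "displayName": "xs:string"
    },
    "minicda.PQ": {"value": "xs:string", "unit": "xs:string"},
    "minicda.ENXP": {"qualifier": "xs:string"},
    "minicda.PN": {"given": "minicda.ENXP", "family": "minicda.ENXP"},
    "minicda.Patient": {
      "name": "minicda.PN",
      "administrativeGenderCode": "minicda.CE",
      "birthTime": "minicda.TS"
    },
    "minicda.PatientRole": {
      "id": "minicda.II",
      "patient": "minicda.Patient"
    },
    "minicda.RecordTarget": {"patientRole": "minicda.PatientRole"},
    "minicda.Observation": {
      "code": "minicda.CE",
      "statusCode": "minicda.CE",
      "effectiveTime": "minicda.TS",
      "valuePQ": "minicda.PQ",
      "valueST": "minicda.ENXP"
    },
    "minicda.Component": {"observation": "minicda.Observation"},
    "minicda.ClinicalDocument": {
      "id": "minicda.II",
      "code": "minicda.CE",
      "effectiveTime": "minicda.TS",
      "recordTarget": "minicda.RecordTarget",
      "component": "minicda.Component"
    }
  }
}
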