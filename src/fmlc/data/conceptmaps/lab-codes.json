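{
  "resourceType": "ConceptMap",
  "url": "http://example.org/conceptmaps/lab-codes",
  "group": [
    {
      "source": "urn:example:labcodes",
      "target": "http://loinc.org",
      "element": [
        {"code": "L01", "target": [{"code": "718-7", "relationship": "equivalent"}]},
        {"code": "L02", "target": [{"code": "787-2", "relationship": "equivalent"}]},
        {"code": "L03", "target": [{"code": "6690-2", "relationship": "equivalent"}]},
        {"code": "L04", "target": [{"code": "777-3", "relationship": "equivalent"}]},
        {"code": "L05", "target": [{"code": "2345-7", "relationship": "equivalent"}]},
        {"code": "L06", "target": [{"code": "2160-0", "relationship": "equivalent"}]},
        {"code": "L07", "target": [{"code": "3094-0", "relationship": "equivalent"}]},
        {"code": "L08", "target": [{"code": "1751-7", "relationship": "equivalent"}]},
        {"code": "L09", "target": [{"code": "2951-2", "relationship": "equivalent"}]},
        {"code": "L10", "target": [{"code": "2823-3", "relationship": "equivalent"}]}
      ]
    }
  ]
}
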