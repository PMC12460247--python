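<?xml version="1.0" encoding="UTF-8"?>
<ConceptMap xmlns="http://hl7.org/fhir">
  <url value="http://example.org/conceptmaps/lab-codes"/>
  <group>
    <source value="urn:example:labcodes"/>
    <target value="http://loinc.org"/>
    <element>
      <code value="L01"/>
      <target><code value="718-7"/><relationship value="equivalent"/></target>
    </element>
    <element>
      <code value="L02"/>
      <target><code value="787-2"/><relationship value="equivalent"/></target>
    </element>
    <element>
      <code value="L03"/>
      <target><code value="6690-2"/><relationship value="equivalent"/></target>
    </element>
    <element>
      <code value="L04"/>
      <target><code value="777-3"/><relationship value="equivalent"/></target>
    </element>
    <element>
      <code value="L05"/>
      <target><code value="2345-7"/><relationship value="equivalent"/></target>
    </element>
    <element>
      <code value="L06"/>
      <target><code value="2160-0"/><relationship value="equivalent"/></target>
    </element>
    <element>
      <code value="L07"/>
      <target><code value="3094-0"/><relationship value="equivalent"/></target>
    </element>
    <element>
      <code value="L08"/>
      <target><code value="1751-7"/><relationship value="equivalent"/></target>
    </element>
    <element>
      <code value="L09"/>
      <target><code value="2951-2"/><relationship value="equivalent"/></target>
    </element>
    <element>
      <code value="L10"/>
      <target><code value="2823-3"/><relationship value="equivalent"/></target>
    </element>
  </group>
</ConceptMap>
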