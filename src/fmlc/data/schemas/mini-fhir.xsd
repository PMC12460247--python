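<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns="http://hl7.org/fhir"
           targetNamespace="http://hl7.org/fhir"
           elementFormDefault="qualified">

  <!-- mini-FHIR: a deliberately small FHIR-shaped model family.
       Primitive types follow the FHIR XML convention: a complex type
       carrying a single `value` attribute. -->

  <xs:complexType name="string">
    <xs:attribute name="value" type="xs:string" use="required"/>
  </xs:complexType>
  <xs:complexType name="code">
    <xs:attribute name="value" type="xs:string" use="required"/>
  </xs:complexType>
  <xs:complexType name="uri">
    <xs:attribute name="value" type="xs:string" use="required"/>
  </xs:complexType>
  <xs:complexType name="id">
    <xs:attribute name="value" type="xs:string" use="required"/>
  </xs:complexType>
  <xs:complexType name="boolean">
    <xs:attribute name="value" type="xs:boolean" use="required"/>
  </xs:complexType>
  <xs:complexType name="integer">
    <xs:attribute name="value" type="xs:integer" use="required"/>
  </xs:complexType>
  <xs:complexType name="decimal">
    <xs:attribute name="value" type="xs:decimal" use="required"/>
  </xs:complexType>
  <xs:complexType name="date">
    <xs:attribute name="value" type="xs:date" use="required"/>
  </xs:complexType>
  <xs:complexType name="dateTime">
    <xs:attribute name="value" type="xs:dateTime" use="required"/>
  </xs:complexType>

  <xs:complexType name="Resource">
    <xs:sequence>
      <xs:element name="id" type="id" minOccurs="0" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Coding">
    <xs:sequence>
      <xs:element name="system" type="uri" minOccurs="0" maxOccurs="1"/>
      <xs:element name="code" type="code" minOccurs="0" maxOccurs="1"/>
      <xs:element name="display" type="string" minOccurs="0" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="CodeableConcept">
    <xs:sequence>
      <xs:element name="coding" type="Coding" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="text" type="string" minOccurs="0" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Quantity">
    <xs:sequence>
      <xs:element name="value" type="decimal" minOccurs="0" maxOccurs="1"/>
      <xs:element name="unit" type="string" minOccurs="0" maxOccurs="1"/>
      <xs:element name="system" type="uri" minOccurs="0" maxOccurs="1"/>
      <xs:element name="code" type="code" minOccurs="0" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Identifier">
    <xs:sequence>
      <xs:element name="system" type="uri" minOccurs="0" maxOccurs="1"/>
      <xs:element name="value" type="string" minOccurs="0" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="HumanName">
    <xs:sequence>
      <xs:element name="use" type="code" minOccurs="0" maxOccurs="1"/>
      <xs:element name="family" type="string" minOccurs="0" maxOccurs="1"/>
      <xs:element name="given" type="string" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Reference">
    <xs:sequence>
      <xs:element name="reference" type="string" minOccurs="0" maxOccurs="1"/>
      <xs:element name="display" type="string" minOccurs="0" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Patient">
    <xs:complexContent>
      <xs:extension base="Resource">
        <xs:sequence>
          <xs:element name="identifier" type="Identifier" minOccurs="0" maxOccurs="unbounded"/>
          <xs:element name="name" type="HumanName" minOccurs="0" maxOccurs="unbounded"/>
          <xs:element name="gender" type="code" minOccurs="0" maxOccurs="1"/>
          <xs:element name="birthDate" type="date" minOccurs="0" maxOccurs="1"/>
        </xs:sequence>
      </xs:extension>
    </xs:complexContent>
  </xs:complexType>

  <xs:complexType name="Observation">
    <xs:complexContent>
      <xs:extension base="Resource">
        <xs:sequence>
          <xs:element name="identifier" type="Identifier" minOccurs="0" maxOccurs="unbounded"/>
          <xs:element name="status" type="code" minOccurs="0" maxOccurs="1"/>
          <xs:element name="code" type="CodeableConcept" minOccurs="0" maxOccurs="1"/>
          <xs:element name="subject" type="Reference" minOccurs="0" maxOccurs="1"/>
          <xs:element name="effectiveDateTime" type="dateTime" minOccurs="0" maxOccurs="1"/>
          <xs:choice minOccurs="0">
            <xs:element name="valueQuantity" type="Quantity" minOccurs="0" maxOccurs="1"/>
            <xs:element name="valueString" type="string" minOccurs="0" maxOccurs="1"/>
            <xs:element name="valueCodeableConcept" type="CodeableConcept" minOccurs="0" maxOccurs="1"/>
          </xs:choice>
        </xs:sequence>
      </xs:extension>
    </xs:complexContent>
  </xs:complexType>

  <xs:complexType name="ActivityDefinition">
    <xs:complexContent>
      <xs:extension base="Resource">
        <xs:sequence>
          <xs:element name="name" type="string" minOccurs="0" maxOccurs="1"/>
          <xs:element name="status" type="code" minOccurs="0" maxOccurs="1"/>
          <xs:element name="code" type="CodeableConcept" minOccurs="0" maxOccurs="1"/>
          <xs:element name="quantity" type="Quantity" minOccurs="0" maxOccurs="1"/>
        </xs:sequence>
      </xs:extension>
    </xs:complexContent>
  </xs:complexType>

  <xs:complexType name="SupplyRequest">
    <xs:complexContent>
      <xs:extension base="Resource">
        <xs:sequence>
          <xs:element name="identifier" type="Identifier" minOccurs="0" maxOccurs="unbounded"/>
          <xs:element name="status" type="code" minOccurs="0" maxOccurs="1"/>
          <xs:element name="priority" type="code" minOccurs="0" maxOccurs="1"/>
          <xs:choice minOccurs="0">
            <xs:element name="itemCodeableConcept" type="CodeableConcept" minOccurs="0" maxOccurs="1"/>
            <xs:element name="itemReference" type="Reference" minOccurs="0" maxOccurs="1"/>
          </xs:choice>
          <xs:element name="quantity" type="Quantity" minOccurs="0" maxOccurs="1"/>
          <xs:element name="occurrenceDateTime" type="dateTime" minOccurs="0" maxOccurs="1"/>
          <xs:element name="authoredOn" type="dateTime" minOccurs="0" maxOccurs="1"/>
        </xs:sequence>
      </xs:extension>
    </xs:complexContent>
  </xs:complexType>

  <xs:complexType name="ResourceContainer">
    <xs:choice minOccurs="0">
      <xs:element name="Patient" type="Patient" minOccurs="0" maxOccurs="1"/>
      <xs:element name="Observation" type="Observation" minOccurs="0" maxOccurs="1"/>
      <xs:element name="ActivityDefinition" type="ActivityDefinition" minOccurs="0" maxOccurs="1"/>
      <xs:element name="SupplyRequest" type="SupplyRequest" minOccurs="0" maxOccurs="1"/>
    </xs:choice>
  </xs:complexType>

  <xs:complexType name="BundleEntry">
    <xs:sequence>
      <xs:element name="fullUrl" type="uri" minOccurs="0" maxOccurs="1"/>
      <xs:element name="resource" type="ResourceContainer" minOccurs="0" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Bundle">
    <xs:complexContent>
      <xs:extension base="Resource">
        <xs:sequence>
          <xs:element name="type" type="code" minOccurs="0" maxOccurs="1"/>
          <xs:element name="timestamp" type="dateTime" minOccurs="0" maxOccurs="1"/>
          <xs:element name="entry" type="BundleEntry" minOccurs="0" maxOccurs="unbounded"/>
        </xs:sequence>
      </xs:extension>
    </xs:complexContent>
  </xs:complexType>

  <xs:element name="Bundle" type="Bundle"/>
  <xs:element name="Patient" type="Patient"/>
  <xs:element name="Observation" type="Observation"/>
  <xs:element name="ActivityDefinition" type="ActivityDefinition"/>
  <xs:element name="SupplyRequest" type="SupplyRequest"/>

</xs:schema>
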