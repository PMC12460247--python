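<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns="urn:example:minicda"
           targetNamespace="urn:example:minicda"
           elementFormDefault="qualified">

  <!-- mini-CDA: a deliberately small CDA-shaped document model.
       Data types follow HL7 v3 conventions: values carried in attributes,
       name parts as mixed simpleContent. -->

  <xs:complexType name="II">
    <xs:attribute name="root" type="xs:string" use="required"/>
    <xs:attribute name="extension" type="xs:string" use="optional"/>
  </xs:complexType>

  <xs:complexType name="TS">
    <xs:attribute name="value" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="CE">
    <xs:attribute name="code" type="xs:string" use="optional"/>
    <xs:attribute name="codeSystem" type="xs:string" use="optional"/>
    <xs:attribute name="displayName" type="xs:string" use="optional"/>
  </xs:complexType>

  <xs:complexType name="PQ">
    <xs:attribute name="value" type="xs:string" use="optional"/>
    <xs:attribute name="unit" type="xs:string" use="optional"/>
  </xs:complexType>

  <xs:complexType name="ENXP">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="qualifier" type="xs:string" use="optional"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:complexType name="PN">
    <xs:sequence>
      <xs:element name="given" type="ENXP" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="family" type="ENXP" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Patient">
    <xs:sequence>
      <xs:element name="name" type="PN" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="administrativeGenderCode" type="CE" minOccurs="0" maxOccurs="1"/>
      <xs:element name="birthTime" type="TS" minOccurs="0" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="PatientRole">
    <xs:sequence>
      <xs:element name="id" type="II" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="patient" type="Patient" minOccurs="0" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="RecordTarget">
    <xs:sequence>
      <xs:element name="patientRole" type="PatientRole" minOccurs="1" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Observation">
    <xs:sequence>
      <xs:element name="code" type="CE" minOccurs="0" maxOccurs="1"/>
      <xs:element name="statusCode" type="CE" minOccurs="0" maxOccurs="1"/>
      <xs:element name="effectiveTime" type="TS" minOccurs="0" maxOccurs="1"/>
      <xs:choice minOccurs="0">
        <xs:element name="valuePQ" type="PQ" minOccurs="0" maxOccurs="1"/>
        <xs:element name="valueST" type="ENXP" minOccurs="0" maxOccurs="1"/>
      </xs:choice>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Component">
    <xs:sequence>
      <xs:element name="observation" type="Observation" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="ClinicalDocument">
    <xs:sequence>
      <xs:element name="id" type="II" minOccurs="0" maxOccurs="1"/>
      <xs:element name="code" type="CE" minOccurs="0" maxOccurs="1"/>
      <xs:element name="effectiveTime" type="TS" minOccurs="0" maxOccurs="1"/>
      <xs:element name="recordTarget" type="RecordTarget" minOccurs="0" maxOccurs="1"/>
      <xs:element name="component" type="Component" minOccurs="0" maxOccurs="1"/>
    </xs:sequence>
  </xs:complexType>

  <xs:element name="ClinicalDocument" type="ClinicalDocument"/>

</xs:schema>
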