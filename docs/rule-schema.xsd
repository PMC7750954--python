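<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for the ruleprop rule XML dialect.

     A <rules> document holds <rule> elements.  Each rule declares:
       - conditionSets: the common conditions, an OR over <conditionSet>
         elements, each of which is an AND over <condition> elements;
       - annotations: the base annotations propagated to every record
         meeting the common conditions;
       - specialCases: extra condition-set/annotation pairs for subgroups;
       - positionalFeatures: a template sequence and residue patterns whose
         alignment-mapped matches yield sequence-feature annotations.

     All coordinates are 1-based inclusive. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="ruleId">
    <xs:restriction base="xs:string">
      <xs:pattern value="UR[0-9]{9}"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="conditionKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="signature"/>
      <xs:enumeration value="taxon"/>
      <xs:enumeration value="sequence_length"/>
      <xs:enumeration value="gene_tree"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="annotationCategory">
    <xs:restriction base="xs:string">
      <xs:enumeration value="protein_name"/>
      <xs:enumeration value="comment"/>
      <xs:enumeration value="keyword"/>
      <xs:enumeration value="go_term"/>
      <xs:enumeration value="subcellular_location"/>
      <xs:enumeration value="catalytic_activity"/>
      <xs:enumeration value="pathway"/>
      <xs:enumeration value="sequence_feature"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="condition">
    <xs:attribute name="kind" type="conditionKind" use="required"/>
    <xs:attribute name="negated" type="xs:boolean" default="false"/>
    <!-- signature kind -->
    <xs:attribute name="signature" type="xs:string"/>
    <!-- taxon kind: a label and/or a numeric taxonomy id -->
    <xs:attribute name="taxon" type="xs:string"/>
    <xs:attribute name="taxonId" type="xs:positiveInteger"/>
    <!-- sequence_length kind: inclusive bounds -->
    <xs:attribute name="min" type="xs:positiveInteger"/>
    <xs:attribute name="max" type="xs:positiveInteger"/>
    <!-- gene_tree kind -->
    <xs:attribute name="tree" type="xs:string"/>
  </xs:complexType>

  <xs:complexType name="conditionSet">
    <xs:sequence>
      <xs:element name="condition" type="condition" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="annotation">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="category" type="annotationCategory" use="required"/>
        <xs:attribute name="subtype" type="xs:string"/>
        <xs:attribute name="positionStart" type="xs:positiveInteger"/>
        <xs:attribute name="positionEnd" type="xs:positiveInteger"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:complexType name="annotations">
    <xs:sequence>
      <xs:element name="annotation" type="annotation" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="case">
    <xs:sequence>
      <xs:element name="conditionSet" type="conditionSet"/>
      <xs:element name="annotations" type="annotations"/>
    </xs:sequence>
  </xs:complexType>

  <!-- A PROSITE-style pattern anchored to template positions start..end;
       subtype/value describe the sequence-feature annotation emitted when
       the pattern matches at the alignment-mapped target positions. -->
  <xs:complexType name="pattern">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="start" type="xs:positiveInteger" use="required"/>
        <xs:attribute name="end" type="xs:positiveInteger" use="required"/>
        <xs:attribute name="subtype" type="xs:string"/>
        <xs:attribute name="value" type="xs:string"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:complexType name="positionalFeatures">
    <xs:sequence>
      <xs:element name="pattern" type="pattern" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="template" type="xs:string" use="required"/>
    <xs:attribute name="sequence" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:element name="rules">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="rule" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="conditionSets">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="conditionSet" type="conditionSet" maxOccurs="unbounded"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="annotations" type="annotations" minOccurs="0"/>
              <xs:element name="specialCases" minOccurs="0">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="case" type="case" maxOccurs="unbounded"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="positionalFeatures" type="positionalFeatures" minOccurs="0"/>
            </xs:sequence>
            <xs:attribute name="id" type="ruleId" use="required"/>
            <xs:attribute name="author" type="xs:string"/>
            <xs:attribute name="created" type="xs:string"/>
            <xs:attribute name="modified" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

</xs:schema>
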