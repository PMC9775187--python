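<?xml version="1.0" encoding="UTF-8"?>
<!--
  Schema for the AEP recording dialect read and written by aepannot.

  One recording per file.  Raw samples are whitespace-separated decimal
  text; wave positions are 0-based sample indices into the buffers.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="SubtypeType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="ABR"/>
      <xs:enumeration value="AMLR"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="EarType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="left"/>
      <xs:enumeration value="right"/>
      <xs:enumeration value="unknown"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="SampleList">
    <!-- whitespace-separated decimal values, one per sample -->
    <xs:list itemType="xs:double"/>
  </xs:simpleType>

  <xs:simpleType name="WaveLabel">
    <xs:restriction base="xs:string">
      <xs:enumeration value="I"/>
      <xs:enumeration value="II"/>
      <xs:enumeration value="III"/>
      <xs:enumeration value="IV"/>
      <xs:enumeration value="V"/>
      <xs:enumeration value="Na"/>
      <xs:enumeration value="Pa"/>
      <xs:enumeration value="Nb"/>
      <xs:enumeration value="Pb"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="AEPRecording">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Subtype" type="SubtypeType"/>
        <xs:element name="PatientID" type="xs:string"/>
        <xs:element name="Ear" type="EarType"/>
        <xs:element name="Intensity" type="xs:double" minOccurs="0"/>
        <xs:element name="SampleRate" type="xs:double"/>
        <xs:element name="PrestimulusSamples" type="xs:nonNegativeInteger"/>
        <xs:element name="RawToMicrovolt" type="xs:double"/>
        <xs:element name="IPSI_A_RAW" type="SampleList"/>
        <xs:element name="IPSI_B_RAW" type="SampleList"/>
        <xs:element name="Jewetts" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="Jewett" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="Wave" type="WaveLabel" use="required"/>
                  <xs:attribute name="Sample" type="xs:nonNegativeInteger" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

</xs:schema>
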