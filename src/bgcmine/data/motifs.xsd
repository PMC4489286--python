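<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="motifs">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="motif" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="description" type="xs:string"/>
              <xs:element name="positions" type="positionList"/>
              <xs:element name="pattern" type="xs:string" minOccurs="0"/>
              <xs:element name="outcomes" minOccurs="0">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="outcome" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="pattern" type="xs:string"
                                      use="required"/>
                        <xs:attribute name="label" type="xs:string"
                                      use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="target" type="xs:string" use="required"/>
            <xs:attribute name="annotation_key" type="xs:string"/>
            <xs:attribute name="required" type="xs:boolean"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string"/>
    </xs:complexType>
  </xs:element>
  <xs:simpleType name="positionList">
    <xs:restriction base="xs:string">
      <xs:pattern value="[1-9][0-9]*(,[1-9][0-9]*)*"/>
    </xs:restriction>
  </xs:simpleType>
</xs:schema>
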