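"""CDA reading, writing and structural validation."""

import pytest
from lxml import etree

from odmcda import (
    CdaDocument,
    CdaEntry,
    CdaHeader,
    CdaSection,
    FixtureSpec,
    InvariantViolation,
    SemanticCode,
    StructureError,
    generate_cda_fixture,
    inject_defect,
    odm_to_cda,
    read_cda,
    validate_cda_structure,
    write_cda,
)
from odmcda._xml import canonical

CDA_NS = "urn:hl7-org:v3"

# the shape of a discharge-summary extract: LOINC document code, TS
# effective time, patient name, first body section "Brieftext"
DISCHARGE_SUMMARY = f"""<?xml version="1.0" encoding="UTF-8"?>
<ClinicalDocument xmlns="{CDA_NS}">
 <typeId root="2.16.840.1.113883.1.3" extension="POCD_HD000040"/>
 <id root="1.2.40.0.10" extension="ELGA-001"/>
 <code code="11490-0" codeSystem="2.16.840.1.113883.6.1"
       displayName="Physician Discharge summary"/>
 <title>Entlassungsbrief</title>
 <effectiveTime value="20130324082015+0100"/>
 <confidentialityCode code="N" codeSystem="2.16.840.1.113883.5.25"/>
 <languageCode code="de-AT"/>
 <recordTarget><patientRole><id extension="123"/>
  <telecom value="mailto:mustermann@mail.de"/>
  <patient><name><given>Herbert</given><family>Mustermann</family></name></patient>
 </patientRole></recordTarget>
 <author><time value="20130324082015+0100"/><assignedAuthor><id extension="a"/>
  <assignedPerson><name>Dr. Beispiel</name></assignedPerson></assignedAuthor></author>
 <custodian><assignedCustodian><representedCustodianOrganization><id extension="c"/>
  <name>LKH Graz</name></representedCustodianOrganization>
 </assignedCustodian></custodian>
 <component><structuredBody>
  <component><section>
   <title>Brieftext</title>
   <text>Sehr geehrte Kollegin, sehr geehrter Kollege ...</text>
  </section></component>
 </structuredBody></component>
</ClinicalDocument>
"""


def minimal_doc(**header_overrides):
    header = CdaHeader(
        document_id="D1",
        document_code=SemanticCode("2.16.840.1.113883.6.1", "51848-0"),
        title="t",
        effective_time="20200101000000+0000",
    )
    for k, v in header_overrides.items():
        setattr(header, k, v)
    return CdaDocument(header=header)


class TestRead:
    def test_discharge_summary_header_and_sections(self):
        doc = read_cda(DISCHARGE_SUMMARY.encode())
        assert doc.header.document_code.code == "11490-0"
        assert doc.header.effective_time == "20130324082015+0100"
        assert doc.header.patient_given == ["Herbert"]
        assert doc.header.patient_family == "Mustermann"
        assert doc.header.custodian_name == "LKH Graz"
        assert doc.sections[0].title == "Brieftext"
        assert doc.raw_tree is not None

    def test_empty_structured_body(self):
        xml = f"""<ClinicalDocument xmlns="{CDA_NS}"><id extension="x"/>
                  <effectiveTime value="20200101"/>
                  <component><structuredBody/></component></ClinicalDocument>"""
        assert read_cda(xml.encode()).sections == []

    def test_missing_optional_header_fields_become_empty(self):
        xml = f'<ClinicalDocument xmlns="{CDA_NS}"/>'
        doc = read_cda(xml.encode())
        assert doc.header.document_id == "" and doc.header.document_code is None
        assert doc.sections == []

    def test_wrong_root_element(self):
        with pytest.raises(StructureError, match="ClinicalDocument"):
            read_cda(f'<Document xmlns="{CDA_NS}"/>'.encode())

    @pytest.mark.parametrize("seed", range(10))
    def test_raw_tree_reserializes_canonically_equal(self, seed):
        spec = FixtureSpec(seed=seed, cda_depth=(4, 5), cda_fanout=(1, 3))
        doc = generate_cda_fixture(spec)
        source = etree.tostring(doc.raw_tree)
        assert canonical(read_cda(source).raw_tree) == canonical(source)


class TestWrite:
    def test_entry_code_and_display_name(self):
        doc = minimal_doc()
        doc.sections.append(
            CdaSection(
                title="Assessment",
                narrative_text="Date of Birth",
                entries=[
                    CdaEntry(
                        act_class="observation",
                        code=SemanticCode(
                            "2.16.840.1.113883.6.86", "C0421451", "Date of Birth"
                        ),
                        value_type="TS",
                    )
                ],
            )
        )
        xml = write_cda(doc).decode()
        assert 'code="C0421451"' in xml and 'displayName="Date of Birth"' in xml

    def test_zero_sections_valid_document(self):
        xml = write_cda(minimal_doc()).decode()
        assert "structuredBody" in xml
        assert read_cda(xml.encode()).sections == []

    def test_missing_header_field_rejected(self):
        with pytest.raises(InvariantViolation, match="effectiveTime"):
            write_cda(minimal_doc(effective_time=""))

    def test_narrative_synthesized_when_absent(self):
        doc = minimal_doc()
        doc.sections.append(
            CdaSection(
                entries=[
                    CdaEntry(
                        act_class="observation",
                        code=SemanticCode("x", "c1", "Heart Rate"),
                        value_type="INT",
                    )
                ]
            )
        )
        reread = read_cda(write_cda(doc))
        assert "Heart Rate" in reread.sections[0].narrative_text

    @pytest.mark.parametrize("seed", range(15))
    def test_write_read_reproduces_header_and_entry_codes(self, seed):
        from odmcda import generate_odm_fixture

        study = generate_odm_fixture(FixtureSpec(seed=seed, n_forms=2))
        for doc in odm_to_cda(study):
            reread = read_cda(write_cda(doc))
            assert reread.header.document_id == doc.header.document_id
            assert reread.header.title == doc.header.title
            assert reread.header.effective_time == doc.header.effective_time
            original_codes = [
                (e.code.system, e.code.code, e.code.display_name, e.value_type)
                for s in doc.sections
                for e in s.entries
            ]
            reread_codes = [
                (e.code.system, e.code.code, e.code.display_name, e.value_type)
                for s in reread.sections
                for e in s.entries
            ]
            assert reread_codes == original_codes
            assert write_cda(doc) == write_cda(doc)  # deterministic


class TestValidate:
    def test_missing_effective_time_finding(self):
        doc = minimal_doc(effective_time="")
        findings = validate_cda_structure(doc)
        assert [(f.kind, f.subject) for f in findings] == [
            ("missing-header-field", "effectiveTime")
        ]

    def test_unknown_value_type_finding(self, cda_doc):
        mutant = inject_defect(cda_doc, "unknown-value-type")
        assert any(
            f.kind == "unknown-value-type" for f in validate_cda_structure(mutant)
        )

    def test_pristine_fixtures_clean(self, cda_family):
        for doc in cda_family(10):
            assert validate_cda_structure(doc) == []
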