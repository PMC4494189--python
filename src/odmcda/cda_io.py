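"""Read, write and structurally validate HL7 CDA R2 documents.

Fidelity is scoped to what the metadata crosswalk needs: the header fields
a converted form must carry (id, document code, title, effective time,
confidentiality, language, patient/author/custodian names) and a body of
sections holding narrative text plus structured entries. Everything else in
a *read* document survives in ``CdaDocument.raw_tree``, which the reverse
mapping flattens and the loss report diffs against.

Outputs are valid CDA structures, not HL7-registered templates: no
templateId is emitted unless the caller supplies some.
"""

from __future__ import annotations

import logging
from typing import Optional

from lxml import etree

from . import _xml
from .errors import InvariantViolation, StructureError
from .model import (
    CDA_VALUE_TYPES,
    CdaDocument,
    CdaEntry,
    CdaHeader,
    CdaSection,
    Finding,
    SemanticCode,
)

log = logging.getLogger(__name__)

CDA_NS = "urn:hl7-org:v3"
XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"
XSI_TYPE = f"{{{XSI_NS}}}type"

#: act-class element name -> RIM classCode
_CLASS_CODES = {
    "observation": "OBS",
    "act": "ACT",
    "procedure": "PROC",
    "encounter": "ENC",
    "organizer": "CLUSTER",
}

#: value types whose payload is element text rather than a value attribute
_TEXTUAL_TYPES = {"ST", "ED"}

_ID_ROOT = "2.16.840.1.113883.19.5"


def _q(tag: str) -> str:
    return f"{{{CDA_NS}}}{tag}"


def _code_of(el: Optional[etree._Element]) -> Optional[SemanticCode]:
    if el is None:
        return None
    code = el.get("code")
    if not code:
        return None
    return SemanticCode(
        system=el.get("codeSystem") or "unknown",
        code=code,
        display_name=el.get("displayName"),
    )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_cda(source: bytes) -> CdaDocument:
    """Parse a ClinicalDocument into :class:`CdaDocument`, keeping the raw tree.

    Missing optional header fields become empty strings; a document without
    a structuredBody yields zero sections (logged).
    """
    root = _xml.parse_bytes(source)
    if _xml.local_name(root) != "ClinicalDocument" or not str(root.tag).startswith(
        f"{{{CDA_NS}}}"
    ):
        raise StructureError(
            f"root element is {root.tag!r}, expected ClinicalDocument in namespace {CDA_NS}"
        )

    header = CdaHeader(
        document_id=_read_id(root.find(_q("id"))),
        document_code=_code_of(root.find(_q("code"))),
        title=_text(root.find(_q("title"))),
        effective_time=_attr(root.find(_q("effectiveTime")), "value"),
        confidentiality_code=_attr(root.find(_q("confidentialityCode")), "code"),
        language_code=_attr(root.find(_q("languageCode")), "code"),
    )
    patient = root.find(f"{_q('recordTarget')}/{_q('patientRole')}/{_q('patient')}")
    if patient is not None:
        name = patient.find(_q("name"))
        if name is not None:
            header.patient_given = [_text(g) for g in name.findall(_q("given"))]
            header.patient_family = _text(name.find(_q("family")))
    header.author_name = _text(
        root.find(
            f"{_q('author')}/{_q('assignedAuthor')}/{_q('assignedPerson')}/{_q('name')}"
        )
    )
    header.custodian_name = _text(
        root.find(
            f"{_q('custodian')}/{_q('assignedCustodian')}"
            f"/{_q('representedCustodianOrganization')}/{_q('name')}"
        )
    )

    doc = CdaDocument(header=header, raw_tree=root)
    body = root.find(f"{_q('component')}/{_q('structuredBody')}")
    if body is None:
        log.info("document %s has no structuredBody; zero sections", header.document_id)
        return doc
    for comp in body.findall(_q("component")):
        section = comp.find(_q("section"))
        if section is not None:
            doc.sections.append(_read_section(section))
    return doc


def _read_id(el: Optional[etree._Element]) -> str:
    if el is None:
        return ""
    return el.get("extension") or el.get("root") or ""


def _text(el: Optional[etree._Element]) -> str:
    if el is None:
        return ""
    return "".join(el.itertext()).strip()


def _attr(el: Optional[etree._Element], attr: str) -> str:
    return el.get(attr, "") if el is not None else ""


def _read_section(el: etree._Element) -> CdaSection:
    section = CdaSection(
        title=_text(el.find(_q("title"))),
        section_code=_code_of(el.find(_q("code"))),
        narrative_text=_text(el.find(_q("text"))),
    )
    for entry_el in el.findall(_q("entry")):
        for act_el in entry_el:
            if isinstance(act_el.tag, str):
                section.entries.append(_read_entry(act_el))
                break
    return section


def _read_entry(act_el: etree._Element) -> CdaEntry:
    code_el = act_el.find(_q("code"))
    code = _code_of(code_el) or SemanticCode(system="unknown", code="unknown")
    translations = []
    if code_el is not None:
        for tr in code_el.findall(_q("translation")):
            tr_code = _code_of(tr)
            if tr_code is not None:
                translations.append(tr_code)

    values = act_el.findall(_q("value"))
    value_type = "ST"
    value: Optional[str] = None
    code_list_values: Optional[list[tuple[str, str]]] = None
    if values:
        raw_type = values[0].get(XSI_TYPE, "ST")
        value_type = raw_type.split(":")[-1]
        if value_type == "CD":
            code_list_values = [
                (v.get("code", ""), v.get("displayName", "")) for v in values
            ]
        else:
            first = values[0]
            if first.get("nullFlavor") is None:
                value = first.text if value_type in _TEXTUAL_TYPES else first.get("value")

    return CdaEntry(
        act_class=_xml.local_name(act_el),
        mood=act_el.get("moodCode", "EVN"),
        code=code,
        value_type=value_type,
        value=value,
        code_list_values=code_list_values,
        translations=translations,
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_cda(doc: CdaDocument, template_ids: Optional[list[str]] = None) -> bytes:
    """Serialize to a ClinicalDocument with the mandatory header skeleton.

    Deterministic for equal inputs. A section with entries but no narrative
    gets a synthesized text block listing entry display names, since CDA
    requires human-readable text. Raises
    :class:`~odmcda.errors.InvariantViolation` before emitting anything when
    header invariants (id, code, effectiveTime) are unmet.
    """
    h = doc.header
    missing = [
        name
        for name, ok in (
            ("id", bool(h.document_id)),
            ("code", h.document_code is not None),
            ("effectiveTime", bool(h.effective_time)),
        )
        if not ok
    ]
    if missing:
        raise InvariantViolation(f"header missing mandatory field(s): {', '.join(missing)}")

    root = etree.Element(_q("ClinicalDocument"), nsmap={None: CDA_NS, "xsi": XSI_NS})
    etree.SubElement(root, _q("typeId"), root="2.16.840.1.113883.1.3", extension="POCD_HD000040")
    for tid in template_ids or []:
        etree.SubElement(root, _q("templateId"), root=tid)
    etree.SubElement(root, _q("id"), root=_ID_ROOT, extension=h.document_id)
    _write_code(root, "code", h.document_code)
    etree.SubElement(root, _q("title")).text = h.title
    etree.SubElement(root, _q("effectiveTime"), value=h.effective_time)
    etree.SubElement(root, _q("confidentialityCode"),
                     code=h.confidentiality_code or "N",
                     codeSystem="2.16.840.1.113883.5.25")
    etree.SubElement(root, _q("languageCode"), code=h.language_code or "en")

    rt = etree.SubElement(root, _q("recordTarget"))
    role = etree.SubElement(rt, _q("patientRole"))
    etree.SubElement(role, _q("id"), nullFlavor="NA")
    patient = etree.SubElement(role, _q("patient"))
    name = etree.SubElement(patient, _q("name"))
    if h.patient_given or h.patient_family:
        for given in h.patient_given:
            etree.SubElement(name, _q("given")).text = given
        if h.patient_family:
            etree.SubElement(name, _q("family")).text = h.patient_family
    else:
        name.set("nullFlavor", "NA")

    author = etree.SubElement(root, _q("author"))
    etree.SubElement(author, _q("time"), value=h.effective_time)
    assigned = etree.SubElement(author, _q("assignedAuthor"))
    etree.SubElement(assigned, _q("id"), nullFlavor="NA")
    person = etree.SubElement(assigned, _q("assignedPerson"))
    _write_name(person, h.author_name)

    custodian = etree.SubElement(root, _q("custodian"))
    ac = etree.SubElement(custodian, _q("assignedCustodian"))
    org = etree.SubElement(ac, _q("representedCustodianOrganization"))
    etree.SubElement(org, _q("id"), nullFlavor="NA")
    _write_name(org, h.custodian_name)

    body_comp = etree.SubElement(root, _q("component"))
    body = etree.SubElement(body_comp, _q("structuredBody"))
    for section in doc.sections:
        comp = etree.SubElement(body, _q("component"))
        _write_section(comp, section)

    return _xml.serialize(root)


def _write_name(parent: etree._Element, text: str) -> None:
    el = etree.SubElement(parent, _q("name"))
    if text:
        el.text = text
    else:
        el.set("nullFlavor", "NA")


def _write_code(parent: etree._Element, tag: str, code: Optional[SemanticCode]) -> etree._Element:
    el = etree.SubElement(parent, _q(tag))
    if code is None:
        el.set("nullFlavor", "NA")
        return el
    el.set("code", code.code)
    el.set("codeSystem", code.system)
    if code.display_name:
        el.set("displayName", code.display_name)
    return el


def _write_section(comp: etree._Element, section: CdaSection) -> None:
    el = etree.SubElement(comp, _q("section"))
    if section.section_code is not None:
        _write_code(el, "code", section.section_code)
    etree.SubElement(el, _q("title")).text = section.title
    narrative = section.narrative_text or _synthesize_narrative(section)
    etree.SubElement(el, _q("text")).text = narrative
    for entry in section.entries:
        _write_entry(el, entry)


def _synthesize_narrative(section: CdaSection) -> str:
    if not section.entries:
        return "This section is empty."
    names = [e.code.display_name or e.code.code for e in section.entries]
    return "Data elements: " + "; ".join(names)


def _write_entry(section_el: etree._Element, entry: CdaEntry) -> None:
    entry_el = etree.SubElement(section_el, _q("entry"))
    act_el = etree.SubElement(
        entry_el,
        _q(entry.act_class),
        classCode=_CLASS_CODES.get(entry.act_class, "ACT"),
        moodCode=entry.mood,
    )
    code_el = _write_code(act_el, "code", entry.code)
    for tr in entry.translations:
        tr_el = etree.SubElement(code_el, _q("translation"))
        tr_el.set("code", tr.code)
        tr_el.set("codeSystem", tr.system)
        if tr.display_name:
            tr_el.set("displayName", tr.display_name)

    if entry.value_type == "CD" and entry.code_list_values:
        for code, label in entry.code_list_values:
            v = etree.SubElement(act_el, _q("value"))
            v.set(XSI_TYPE, "CD")
            v.set("code", code)
            if label:
                v.set("displayName", label)
    else:
        v = etree.SubElement(act_el, _q("value"))
        v.set(XSI_TYPE, entry.value_type)
        if entry.value is None:
            v.set("nullFlavor", "NI")
        elif entry.value_type in _TEXTUAL_TYPES:
            v.text = entry.value
        else:
            v.set("value", entry.value)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_cda_structure(
    doc: CdaDocument, xsd_path: Optional[str] = None
) -> list[Finding]:
    """Self-contained structural checks; empty list iff conformant.

    With ``xsd_path`` (a public CDA R2 schema, user-supplied), full schema
    validation of the serialized document is appended.
    """
    findings: list[Finding] = []
    h = doc.header
    for field_name, ok in (
        ("id", bool(h.document_id)),
        ("code", h.document_code is not None),
        ("effectiveTime", bool(h.effective_time)),
    ):
        if not ok:
            findings.append(
                Finding("missing-header-field", field_name, f"header lacks {field_name}")
            )

    for s_idx, section in enumerate(doc.sections):
        where = section.title or f"section[{s_idx}]"
        if section.entries and not section.narrative_text:
            findings.append(
                Finding("missing-narrative", where, "section has entries but no narrative text")
            )
        for entry in section.entries:
            if entry.value_type not in CDA_VALUE_TYPES:
                findings.append(
                    Finding(
                        "unknown-value-type",
                        entry.code.code,
                        f"entry {entry.code.code!r} has value type {entry.value_type!r}",
                    )
                )
            if entry.value_type == "CD" and entry.code_list_values is not None:
                if len(entry.code_list_values) < 1:
                    findings.append(
                        Finding("empty-code-list", entry.code.code, "CD entry with no pairs")
                    )

    if xsd_path is not None and not findings:
        if doc.raw_tree is not None:
            xml_bytes = etree.tostring(doc.raw_tree)
        else:
            xml_bytes = write_cda(doc)
        for msg in _xml.validate_against_xsd(xml_bytes, xsd_path):
            findings.append(Finding("schema-violation", h.document_id, msg))

    return findings
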