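"""Read, write and structurally validate CDISC ODM 1.3.2 study metadata.

The scope is metadata only: a study is parsed down to its FormDefs,
ItemGroupDefs, ItemDefs and CodeLists. Patient-level ``ClinicalData``
subtrees are ignored with a logged notice, as are AdminData, ReferenceData
and vendor extension elements.

Semantic annotations ride on ODM ``Alias`` elements (``Context`` holds the
vocabulary name, ``Name`` the code), the conventional ODM carrier for
external concept codes. ``Alias`` has no display-name slot; the display
name is reconstructed from the item name on the CDA side.
"""

from __future__ import annotations

import logging
from typing import Optional

from lxml import etree

from . import _xml
from .errors import InvariantViolation, ReferenceResolutionError, StructureError
from .model import (
    ODM_DATA_TYPES,
    CodeList,
    Finding,
    FormDefinition,
    ItemDefinition,
    ItemGroupDefinition,
    SemanticCode,
    StudyMetadata,
)

log = logging.getLogger(__name__)

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"
ODM_VERSION = "1.3.2"
XML_LANG = "{http://www.w3.org/XML/1998/namespace}lang"

#: fixed timestamp so identical studies serialize byte-identically
DEFAULT_CREATION_DATETIME = "1970-01-01T00:00:00"


def _q(tag: str) -> str:
    return f"{{{ODM_NS}}}{tag}"


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_odm(source: bytes) -> StudyMetadata:
    """Parse ODM XML into :class:`StudyMetadata`.

    Raises :class:`~odmcda.errors.XmlParseError` for malformed XML,
    :class:`~odmcda.errors.StructureError` when Study/MetaDataVersion are
    missing, and :class:`~odmcda.errors.ReferenceResolutionError` for
    dangling OID references.
    """
    root = _xml.parse_bytes(source)
    if _xml.local_name(root) != "ODM" or not str(root.tag).startswith(f"{{{ODM_NS}}}"):
        raise StructureError(
            f"root element is {root.tag!r}, expected ODM in namespace {ODM_NS}"
        )
    version = root.get("ODMVersion")
    if version and version != ODM_VERSION:
        log.info("reading ODM version %s (will always write %s)", version, ODM_VERSION)

    clinical = root.findall(_q("ClinicalData"))
    if clinical:
        log.info("ignoring %d ClinicalData element(s): metadata-only scope", len(clinical))

    study = root.find(_q("Study"))
    if study is None:
        raise StructureError("ODM document has no Study element")
    mdv = study.find(_q("MetaDataVersion"))
    if mdv is None:
        raise StructureError("Study has no MetaDataVersion element")

    name_el = study.find(f"{_q('GlobalVariables')}/{_q('StudyName')}")
    result = StudyMetadata(
        study_oid=study.get("OID", ""),
        study_name=(name_el.text or "") if name_el is not None else "",
        metadata_version_oid=mdv.get("OID", ""),
    )

    for el in mdv.findall(_q("FormDef")):
        refs = [
            (r.get("ItemGroupOID", ""), _xml.parse_yes_no(r.get("Mandatory"), True))
            for r in el.findall(_q("ItemGroupRef"))
        ]
        result.forms.append(
            FormDefinition(oid=el.get("OID", ""), name=el.get("Name", ""), itemgroup_refs=refs)
        )

    for el in mdv.findall(_q("ItemGroupDef")):
        refs = [
            (r.get("ItemOID", ""), _xml.parse_yes_no(r.get("Mandatory"), True))
            for r in el.findall(_q("ItemRef"))
        ]
        result.item_groups.append(
            ItemGroupDefinition(
                oid=el.get("OID", ""),
                name=el.get("Name", ""),
                repeating=_xml.parse_yes_no(el.get("Repeating"), False),
                item_refs=refs,
            )
        )

    for el in mdv.findall(_q("ItemDef")):
        result.items.append(_read_item_def(el))

    for el in mdv.findall(_q("CodeList")):
        entries = []
        for cli in el.findall(_q("CodeListItem")):
            decode = _read_translated_map(cli.find(_q("Decode")))
            entries.append((cli.get("CodedValue", ""), decode))
        result.code_lists.append(
            CodeList(
                oid=el.get("OID", ""),
                data_type=el.get("DataType", "text"),
                entries=entries,
                name=el.get("Name", ""),
            )
        )

    _check_references(result)
    return result


def _read_item_def(el: etree._Element) -> ItemDefinition:
    clref = el.find(_q("CodeListRef"))
    codes = [
        SemanticCode(system=a.get("Context", ""), code=a.get("Name", ""))
        for a in el.findall(_q("Alias"))
        if a.get("Context") and a.get("Name")
    ]
    data_type = el.get("DataType", "text")
    if data_type not in ODM_DATA_TYPES:
        log.warning("item %s: unsupported DataType %r read as 'text'", el.get("OID"), data_type)
        data_type = "text"
    return ItemDefinition(
        oid=el.get("OID", ""),
        name=el.get("Name", ""),
        data_type=data_type,
        code_list_oid=clref.get("CodeListOID") if clref is not None else None,
        question_text=_read_translated_map(el.find(_q("Question"))),
        semantic_codes=codes,
    )


def _read_translated_map(parent: Optional[etree._Element]) -> dict[str, str]:
    if parent is None:
        return {}
    out: dict[str, str] = {}
    for tt in parent.findall(_q("TranslatedText")):
        out[tt.get(XML_LANG, "en")] = tt.text or ""
    return out


def _check_references(study: StudyMetadata) -> None:
    dangling = [f for f in validate_odm_structure(study) if f.kind == "dangling-reference"]
    if dangling:
        oids = ", ".join(f.subject for f in dangling)
        raise ReferenceResolutionError(f"dangling OID reference(s): {oids}")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_odm(
    study: StudyMetadata, creation_datetime: str = DEFAULT_CREATION_DATETIME
) -> bytes:
    """Serialize a study to namespace-correct ODM 1.3.2 XML.

    Output is deterministic for equal inputs; ``creation_datetime`` defaults
    to a fixed epoch timestamp for that reason. Raises
    :class:`~odmcda.errors.InvariantViolation` (before emitting anything)
    when the study fails structural validation.
    """
    findings = validate_odm_structure(study)
    if findings:
        raise InvariantViolation(
            "study fails structural validation: " + "; ".join(map(str, findings))
        )

    root = etree.Element(
        _q("ODM"),
        nsmap={None: ODM_NS},
        FileOID=study.study_oid or "ODM.FILE",
        FileType="Snapshot",
        Granularity="Metadata",
        CreationDateTime=creation_datetime,
        ODMVersion=ODM_VERSION,
    )
    study_el = etree.SubElement(root, _q("Study"), OID=study.study_oid)
    gv = etree.SubElement(study_el, _q("GlobalVariables"))
    etree.SubElement(gv, _q("StudyName")).text = study.study_name
    etree.SubElement(gv, _q("StudyDescription")).text = study.study_name
    etree.SubElement(gv, _q("ProtocolName")).text = study.study_name
    mdv = etree.SubElement(
        study_el, _q("MetaDataVersion"), OID=study.metadata_version_oid, Name="Metadata"
    )

    for form in study.forms:
        f_el = etree.SubElement(mdv, _q("FormDef"), OID=form.oid, Name=form.name, Repeating="No")
        for order, (ig_oid, mandatory) in enumerate(form.itemgroup_refs, start=1):
            etree.SubElement(
                f_el,
                _q("ItemGroupRef"),
                ItemGroupOID=ig_oid,
                Mandatory=_xml.yes_no(mandatory),
                OrderNumber=str(order),
            )

    for ig in study.item_groups:
        ig_el = etree.SubElement(
            mdv,
            _q("ItemGroupDef"),
            OID=ig.oid,
            Name=ig.name,
            Repeating=_xml.yes_no(ig.repeating),
        )
        for order, (item_oid, mandatory) in enumerate(ig.item_refs, start=1):
            etree.SubElement(
                ig_el,
                _q("ItemRef"),
                ItemOID=item_oid,
                Mandatory=_xml.yes_no(mandatory),
                OrderNumber=str(order),
            )

    for item in study.items:
        i_el = etree.SubElement(
            mdv, _q("ItemDef"), OID=item.oid, Name=item.name, DataType=item.data_type
        )
        if item.question_text:
            q_el = etree.SubElement(i_el, _q("Question"))
            for lang in sorted(item.question_text):
                tt = etree.SubElement(q_el, _q("TranslatedText"))
                tt.set(XML_LANG, lang)
                tt.text = item.question_text[lang]
        if item.code_list_oid:
            etree.SubElement(i_el, _q("CodeListRef"), CodeListOID=item.code_list_oid)
        for code in item.semantic_codes:
            etree.SubElement(i_el, _q("Alias"), Context=code.system, Name=code.code)

    for cl in study.code_lists:
        cl_el = etree.SubElement(
            mdv, _q("CodeList"), OID=cl.oid, Name=cl.name or cl.oid, DataType=cl.data_type
        )
        for coded_value, decode in cl.entries:
            cli = etree.SubElement(cl_el, _q("CodeListItem"), CodedValue=coded_value)
            if decode:
                d_el = etree.SubElement(cli, _q("Decode"))
                for lang in sorted(decode):
                    tt = etree.SubElement(d_el, _q("TranslatedText"))
                    tt.set(XML_LANG, lang)
                    tt.text = decode[lang]

    return _xml.serialize(root)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_odm_structure(
    study: StudyMetadata, xsd_path: Optional[str] = None
) -> list[Finding]:
    """Self-contained structural checks; empty list iff all invariants hold.

    When ``xsd_path`` points at the official ODM 1.3.2 schema (not bundled),
    the serialized study is additionally schema-validated and violations
    appended as ``schema-violation`` findings.
    """
    findings: list[Finding] = []

    for kind, collection in (
        ("form", study.forms),
        ("itemgroup", study.item_groups),
        ("item", study.items),
        ("codelist", study.code_lists),
    ):
        seen: set[str] = set()
        for obj in collection:
            if not obj.oid:
                findings.append(Finding("empty-oid", f"<{kind}>", f"{kind} with empty OID"))
            elif obj.oid in seen:
                findings.append(
                    Finding("duplicate-oid", obj.oid, f"duplicate {kind} OID {obj.oid!r}")
                )
            else:
                seen.add(obj.oid)

    ig_oids = {ig.oid for ig in study.item_groups}
    item_oids = {i.oid for i in study.items}
    cl_oids = {c.oid for c in study.code_lists}

    for form in study.forms:
        for ig_oid, _ in form.itemgroup_refs:
            if ig_oid not in ig_oids:
                findings.append(
                    Finding(
                        "dangling-reference",
                        ig_oid,
                        f"form {form.oid!r} references missing itemgroup {ig_oid!r}",
                    )
                )
    for ig in study.item_groups:
        for item_oid, _ in ig.item_refs:
            if item_oid not in item_oids:
                findings.append(
                    Finding(
                        "dangling-reference",
                        item_oid,
                        f"itemgroup {ig.oid!r} references missing item {item_oid!r}",
                    )
                )
    for item in study.items:
        if item.code_list_oid is not None and item.code_list_oid not in cl_oids:
            findings.append(
                Finding(
                    "dangling-reference",
                    item.code_list_oid,
                    f"item {item.oid!r} references missing code list {item.code_list_oid!r}",
                )
            )
        if item.data_type not in ODM_DATA_TYPES:
            findings.append(
                Finding(
                    "unknown-datatype",
                    item.oid,
                    f"item {item.oid!r} has unsupported data type {item.data_type!r}",
                )
            )

    for cl in study.code_lists:
        coded = [v for v, _ in cl.entries]
        if len(coded) != len(set(coded)):
            findings.append(
                Finding(
                    "duplicate-coded-value",
                    cl.oid,
                    f"code list {cl.oid!r} repeats a coded value",
                )
            )

    if xsd_path is not None and not findings:
        for msg in _xml.validate_against_xsd(write_odm(study), xsd_path):
            findings.append(Finding("schema-violation", study.study_oid, msg))

    return findings
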