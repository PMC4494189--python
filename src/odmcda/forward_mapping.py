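"""ODM-to-CDA direction: one clinical document per CRF.

A case report form is a patient assessment, so each ODM form becomes a CDA
document whose single *assessment section* holds one structured entry per
item reachable through the form's item groups, in document order. Item
group boundaries are not representable in this layout and are dropped — a
known, reported loss. ODM carries no act classes, so every entry is
generated with a configurable act class (observation, in event mood, by
default).

Semantic annotations travel with each item: the first concept code becomes
the entry code (its vocabulary name mapped to a code-system OID), further
codes become CDA ``translation`` codes, and items without any annotation
get a deterministic locally minted code so repeated runs are reproducible.
"""

from __future__ import annotations

import hashlib
import logging

from .errors import ReferenceResolutionError
from .model import (
    LOCAL_CODE_SYSTEM_OID,
    LOINC_OID,
    CdaDocument,
    CdaEntry,
    CdaHeader,
    CdaSection,
    ForwardMappingConfig,
    ItemDefinition,
    LossRecord,
    SemanticCode,
    StudyMetadata,
)

log = logging.getLogger(__name__)

#: LOINC code of the generic assessment ("evaluation note") section/document
ASSESSMENT_CODE = SemanticCode(
    system=LOINC_OID, code="51848-0", display_name="Assessment note"
)

#: fixed timestamp so converted metadata documents are byte-reproducible
DEFAULT_EFFECTIVE_TIME = "19700101000000+0000"

_TYPE_MAP = {
    "integer": "INT",
    "float": "REAL",
    "text": "ST",
    "string": "ST",
    "date": "TS",
    "datetime": "TS",
    "time": "TS",
    "boolean": "BL",
}


def map_item_datatype(data_type: str, has_code_list: bool = False) -> str:
    """Total, deterministic ODM-to-CDA type mapping.

    integer→INT, float→REAL, text/string→ST, date/datetime/time→TS,
    boolean→BL; an attached code list overrides the base type to CD.
    """
    if has_code_list:
        return "CD"
    return _TYPE_MAP[data_type]


def generated_code(study_oid: str, item_oid: str) -> SemanticCode:
    """Deterministic local code for an item without semantic annotation."""
    digest = hashlib.sha256(f"{study_oid}/{item_oid}".encode("utf-8")).hexdigest()
    return SemanticCode(
        system=LOCAL_CODE_SYSTEM_OID, code=f"X{digest[:10].upper()}", display_name=None
    )


def _map_code(
    code: SemanticCode, item_name: str, config: ForwardMappingConfig
) -> SemanticCode:
    oid = config.code_system_map.get(code.system)
    if oid is None:
        log.warning(
            "vocabulary %r not in code_system_map; using local OID arc", code.system
        )
        oid = LOCAL_CODE_SYSTEM_OID
    return SemanticCode(
        system=oid, code=code.code, display_name=code.display_name or item_name
    )


def _item_to_entry(
    study: StudyMetadata, item: ItemDefinition, config: ForwardMappingConfig
) -> CdaEntry:
    if item.semantic_codes:
        code = _map_code(item.semantic_codes[0], item.name, config)
        translations = [
            _map_code(c, item.name, config) for c in item.semantic_codes[1:]
        ]
    else:
        base = generated_code(study.study_oid, item.oid)
        code = SemanticCode(system=base.system, code=base.code, display_name=item.name)
        translations = []

    has_code_list = item.code_list_oid is not None
    value_type = map_item_datatype(item.data_type, has_code_list)
    code_list_values = None
    if has_code_list:
        pairs = []
        for coded_value, decode in study.code_list(item.code_list_oid).entries:
            label = decode.get(config.language) or next(iter(decode.values()), "")
            pairs.append((coded_value, label))
        code_list_values = pairs

    return CdaEntry(
        act_class=config.default_act_class,
        mood="EVN",
        code=code,
        value_type=value_type,
        code_list_values=code_list_values,
        translations=translations,
    )


def odm_form_to_cda(
    study: StudyMetadata,
    form_oid: str,
    config: ForwardMappingConfig | None = None,
) -> CdaDocument:
    """Convert one form into a document with a single assessment section."""
    config = config or ForwardMappingConfig()
    try:
        form = study.form(form_oid)
    except KeyError as exc:
        raise ReferenceResolutionError(str(exc)) from exc

    if len(form.itemgroup_refs) >= 2:
        log.info(
            "form %s: %d itemgroup boundaries are not represented in CDA",
            form.oid,
            len(form.itemgroup_refs),
        )

    entries = [
        _item_to_entry(study, item, config) for item in study.items_of_form(form_oid)
    ]
    item_names = [study.item(oid).name
                  for ig, _ in form.itemgroup_refs
                  for oid, _ in study.item_group(ig).item_refs]
    narrative = (
        "Data elements: " + "; ".join(item_names) if item_names
        else "This form defines no data elements."
    )
    section = CdaSection(
        title=form.name,
        section_code=ASSESSMENT_CODE,
        narrative_text=narrative,
        entries=entries,
    )

    header = CdaHeader(
        document_id=f"{study.study_oid}.{form.oid}",
        document_code=ASSESSMENT_CODE,
        title=form.name,
        effective_time=DEFAULT_EFFECTIVE_TIME,
        confidentiality_code="N",
        language_code=config.language,
        custodian_name=study.study_name or "Study metadata custodian",
        author_name="Automated metadata converter",
    )
    for field_name, value in config.header_overrides.items():
        if not hasattr(header, field_name):
            raise ValueError(f"unknown header field {field_name!r}")
        setattr(header, field_name, value)

    return CdaDocument(header=header, sections=[section])


def odm_to_cda(
    study: StudyMetadata, config: ForwardMappingConfig | None = None
) -> list[CdaDocument]:
    """Convert every form of a study; one document per form, in study order.

    A failing form aborts the batch with its OID named.
    """
    config = config or ForwardMappingConfig()
    docs = []
    for form in study.forms:
        try:
            docs.append(odm_form_to_cda(study, form.oid, config))
        except Exception as exc:
            raise type(exc)(f"conversion of form {form.oid!r} failed: {exc}") from exc
    return docs


def forward_loss_report(study: StudyMetadata, form_oid: str) -> LossRecord:
    """What the forward direction loses for one form.

    The only structural loss is the item-group partition: with two or more
    item groups the flat assessment section retains no recoverable grouping.
    One ``itemgroup_lost`` path is recorded per dissolved group.
    """
    form = study.form(form_oid)
    record = LossRecord()
    if len(form.itemgroup_refs) >= 2:
        for ig_oid, _ in form.itemgroup_refs:
            ig = study.item_group(ig_oid)
            record.itemgroup_lost.append(f"{form.oid}.{ig.oid}")
    return record
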