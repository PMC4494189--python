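"""CDA-to-ODM direction: flatten the document hierarchy into named items.

CDA nests its data (``<patient><name><given>…``) and stores it both in
element text and in attributes, so the number of items cannot be read off
the node count. Unique item names are built by concatenating local element
names with dots — ``patient.name.given`` — and attribute-borne data gets an
``.attributes.<name>`` suffix, e.g. ``telecom.attributes.value``. Leaf
names repeat in CDA; repeated names are disambiguated with an ordinal
suffix (``.2``, ``.3``, …) on second and later occurrences, so the first
occurrence keeps the plain concatenated name.

Structured ``entry`` elements inside sections are, by default, recovered as
proper items (name from the entry code's display name, data type inverted
from the value type) rather than flattened; narrative text blocks that
yield no structured item are ignored, with a logged count. Every produced
item is marked Mandatory="Yes" and Repeating="No": a CDA instance cannot
say which of its elements are optional or repeatable.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from typing import Optional

from lxml import etree

from . import _xml, cda_io
from .errors import StateError
from .model import (
    CdaDocument,
    CdaEntry,
    CodeList,
    FlattenedItem,
    FormDefinition,
    ItemDefinition,
    ItemGroupDefinition,
    LossRecord,
    ReverseMappingConfig,
    STRUCTURAL_ATTRIBUTES,
    StudyMetadata,
)

log = logging.getLogger(__name__)

XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"

#: CDA header elements (direct children of ClinicalDocument outside the body)
HEADER_ELEMENTS = frozenset(
    {
        "realmCode", "typeId", "templateId", "id", "code", "title",
        "effectiveTime", "confidentialityCode", "languageCode", "setId",
        "versionNumber", "copyTime", "recordTarget", "author", "dataEnterer",
        "informant", "custodian", "informationRecipient", "legalAuthenticator",
        "authenticator", "participant", "inFulfillmentOf", "documentationOf",
        "relatedDocument", "authorization", "componentOf",
    }
)


# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------


def make_item_name(
    path: list[str] | tuple[str, ...],
    attribute: Optional[str] = None,
    occurrence: int = 1,
) -> str:
    """Pure name-mangling function: dot-join a path, suffix attribute/ordinal.

    >>> make_item_name(["patient", "name", "family"])
    'patient.name.family'
    >>> make_item_name(["telecom"], attribute="value")
    'telecom.attributes.value'
    >>> make_item_name(["telecom"], attribute="value", occurrence=2)
    'telecom.attributes.value.2'
    """
    if not path:
        raise ValueError("path must be non-empty")
    if occurrence < 1:
        raise ValueError("occurrence must be >= 1")
    name = ".".join(path)
    if attribute is not None:
        name += f".attributes.{attribute}"
    if occurrence > 1:
        name += f".{occurrence}"
    return name


# ---------------------------------------------------------------------------
# Type inference
# ---------------------------------------------------------------------------

_INT_RE = re.compile(r"^[+-]?\d+$")
_FLOAT_RE = re.compile(r"^[+-]?(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?$")
_DATE_RE = re.compile(r"^(\d{8}|\d{4}-\d{2}-\d{2})$")
_DATETIME_RE = re.compile(
    r"^(\d{10,14}([+-]\d{4})?|\d{4}-\d{2}-\d{2}T\d{2}:\d{2}(:\d{2})?)$"
)


def infer_datatype(values: list[str]) -> str:
    """Infer an ODM data type from observed value strings.

    Checked in order: integer, float, date, datetime (CDA TS literals),
    boolean; anything mixed or unmatched falls back to string. Deterministic
    and order-independent (every value must match the chosen class).
    """
    if not values:
        raise ValueError("values must be non-empty")
    if all(_INT_RE.match(v) for v in values):
        return "integer"
    if all(_FLOAT_RE.match(v) for v in values):
        return "float"
    if all(_DATE_RE.match(v) for v in values):
        return "date"
    if all(_DATETIME_RE.match(v) for v in values):
        return "datetime"
    if all(v in ("true", "false") for v in values):
        return "boolean"
    return "string"


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------


class _NameRegistry:
    """Hands out unique names by counting base-name occurrences."""

    def __init__(self) -> None:
        self._counts: Counter[str] = Counter()
        self._taken: set[str] = set()

    def claim(self, path: tuple[str, ...], attribute: Optional[str]) -> str:
        base = make_item_name(path, attribute)
        self._counts[base] += 1
        name = make_item_name(path, attribute, self._counts[base])
        while name in self._taken:  # collision with a literal ".N" path
            self._counts[base] += 1
            name = make_item_name(path, attribute, self._counts[base])
        self._taken.add(name)
        return name


def _own_text(el: etree._Element) -> str:
    """Concatenated direct text of an element (mixed content included)."""
    parts = [el.text or ""]
    for child in el:
        parts.append(child.tail or "")
    return "".join(parts).strip()


def _retained_attributes(
    el: etree._Element, config: ReverseMappingConfig
) -> list[tuple[str, str]]:
    out = []
    for qname, value in el.attrib.items():
        if qname.startswith(f"{{{XSI_NS}}}"):
            continue  # schema plumbing, never data
        local = qname.rsplit("}", 1)[-1]
        if local in config.skip_attributes:
            continue
        if config.skip_structural_attributes and local in STRUCTURAL_ATTRIBUTES:
            continue
        out.append((local, value))
    return out


def flatten_cda(
    tree, config: ReverseMappingConfig | None = None
) -> list[FlattenedItem]:
    """Depth-first, document-order flattening of a parsed CDA tree.

    The root element itself contributes no path component. Every element
    with non-whitespace direct text yields one ``node_text`` item; every
    retained attribute yields one ``attribute`` item (attributes before
    text, both before descent). Deterministic for identical tree + config.
    """
    if isinstance(tree, CdaDocument):
        if tree.raw_tree is None:
            raise StateError("document has no raw tree; read it from XML first")
        tree = tree.raw_tree
    config = config or ReverseMappingConfig()

    items: list[FlattenedItem] = []
    registry = _NameRegistry()
    skipped_depth = 0

    def visit(el: etree._Element, path: tuple[str, ...]) -> None:
        nonlocal skipped_depth
        for child in el:
            if not isinstance(child.tag, str):
                continue
            local = _xml.local_name(child)
            if local in config.skip_elements:
                continue
            child_path = path + (local,)
            if len(child_path) > config.max_path_depth:
                skipped_depth += 1
                continue
            for attr_name, attr_value in _retained_attributes(child, config):
                items.append(
                    FlattenedItem(
                        name=registry.claim(child_path, attr_name),
                        source_kind="attribute",
                        source_path=child_path,
                        attribute_name=attr_name,
                        example_value=attr_value,
                        inferred_type=infer_datatype([attr_value]),
                    )
                )
            text = _own_text(child)
            if text:
                items.append(
                    FlattenedItem(
                        name=registry.claim(child_path, None),
                        source_kind="node_text",
                        source_path=child_path,
                        example_value=text,
                        inferred_type=infer_datatype([text]),
                    )
                )
            visit(child, child_path)

    visit(tree, ())
    if skipped_depth:
        log.info("skipped %d element(s) beyond max_path_depth", skipped_depth)
    return items


# ---------------------------------------------------------------------------
# CDA -> ODM conversion
# ---------------------------------------------------------------------------

_INVERSE_TYPE_MAP = {
    "INT": "integer",
    "REAL": "float",
    "ST": "string",
    "TS": "datetime",
    "BL": "boolean",
    "CD": "string",
    "ED": "text",
}


def _is_narrative(path: tuple[str, ...]) -> bool:
    return any(
        path[i] == "section" and i + 1 < len(path) and path[i + 1] == "text"
        for i in range(len(path))
    )


def _entry_to_item(
    entry: CdaEntry,
    oid: str,
    name: str,
    config: ReverseMappingConfig,
    study: StudyMetadata,
) -> ItemDefinition:
    from .model import SemanticCode  # local import to avoid clutter above

    codes = []
    for code in [entry.code, *entry.translations]:
        system = config.code_system_names.get(code.system, code.system)
        codes.append(SemanticCode(system=system, code=code.code))

    code_list_oid = None
    if entry.value_type == "CD" and entry.code_list_values:
        code_list_oid = f"CL.{len(study.code_lists) + 1}"
        coded = [c for c, _ in entry.code_list_values]
        study.code_lists.append(
            CodeList(
                oid=code_list_oid,
                data_type=infer_datatype(coded) if coded else "text",
                entries=[(c, {"en": label}) for c, label in entry.code_list_values],
                name=f"{name} codes",
            )
        )
        data_type = study.code_lists[-1].data_type
        if data_type not in ("integer", "string", "text", "float"):
            data_type = "string"
    else:
        data_type = _INVERSE_TYPE_MAP.get(entry.value_type, "string")

    return ItemDefinition(
        oid=oid,
        name=name,
        data_type=data_type,
        code_list_oid=code_list_oid,
        question_text={"en": entry.code.display_name or name},
        semantic_codes=codes,
        mandatory=True,
        repeating=False,
    )


def cda_to_odm(
    doc: CdaDocument, config: ReverseMappingConfig | None = None
) -> StudyMetadata:
    """Convert one read CDA document into an ODM study with one form.

    Flattened items are partitioned into item groups by the first
    ``group_by_depth`` path components (first-appearance order). With
    ``recover_entries`` (the default) section ``entry`` subtrees become
    proper items grouped per section instead of being flattened. Every item
    gets mandatory=True and repeating=False.
    """
    if doc.raw_tree is None:
        raise StateError(
            "document has no raw tree; use read_cda on the source XML first"
        )
    config = config or ReverseMappingConfig()

    title = doc.header.title or "Converted CDA document"
    study = StudyMetadata(
        study_oid=f"S.{doc.header.document_id or 'CDA'}",
        study_name=title,
        metadata_version_oid="MDV.1",
    )
    form = FormDefinition(oid="F.1", name=title)
    study.forms.append(form)

    flatten_config = config
    if config.recover_entries:
        flatten_config = ReverseMappingConfig(
            skip_attributes=config.skip_attributes,
            skip_elements=config.skip_elements | {"entry"},
            max_path_depth=config.max_path_depth,
            group_by_depth=config.group_by_depth,
            skip_structural_attributes=config.skip_structural_attributes,
            recover_entries=config.recover_entries,
            code_system_names=config.code_system_names,
        )

    flattened = flatten_cda(doc.raw_tree, flatten_config)
    narrative_dropped = sum(1 for f in flattened if _is_narrative(f.source_path))
    if narrative_dropped:
        log.info(
            "%d narrative text item(s) ignored (no structured assignment)",
            narrative_dropped,
        )
    flattened = [f for f in flattened if not _is_narrative(f.source_path)]

    groups: dict[str, ItemGroupDefinition] = {}
    names = _NameRegistry()
    for fl in flattened:  # entry-derived names must not collide with path names
        names._taken.add(fl.name)

    def group_for(key: str, display: str) -> ItemGroupDefinition:
        if key not in groups:
            ig = ItemGroupDefinition(
                oid=f"IG.{len(groups) + 1}", name=display, repeating=False
            )
            groups[key] = ig
            study.item_groups.append(ig)
            form.itemgroup_refs.append((ig.oid, True))
        return groups[key]

    counter = 0
    for fl in flattened:
        counter += 1
        item = ItemDefinition(
            oid=f"I.{counter}",
            name=fl.name,
            data_type=fl.inferred_type,
            question_text={"en": fl.example_value},
            mandatory=True,
            repeating=False,
        )
        study.items.append(item)
        prefix = ".".join(fl.source_path[: config.group_by_depth])
        group_for(f"path:{prefix}", prefix).item_refs.append((item.oid, True))

    if config.recover_entries:
        for s_idx, section in enumerate(doc.sections, start=1):
            if not section.entries:
                continue
            ig = group_for(
                f"section:{s_idx}", section.title or f"Section {s_idx}"
            )
            for entry in section.entries:
                counter += 1
                base_name = (
                    entry.code.display_name or entry.code.code or f"entry.{counter}"
                )
                name = names.claim((base_name,), None)
                item = _entry_to_item(entry, f"I.{counter}", name, config, study)
                study.items.append(item)
                ig.item_refs.append((item.oid, True))

    return study


# ---------------------------------------------------------------------------
# Loss reporting
# ---------------------------------------------------------------------------


def _paths_of(doc: CdaDocument) -> Counter:
    if doc.raw_tree is not None:
        root = doc.raw_tree
    else:
        root = _xml.parse_bytes(cda_io.write_cda(doc))
    return Counter(_xml.element_paths(root))


def loss_report(original: CdaDocument, roundtripped: CdaDocument) -> LossRecord:
    """Diff the element-path multisets of two documents and classify losses.

    Paths present in the original but not the round-tripped document are
    classified as header-dropped (header subtrees), narrative-ignored
    (section text) or hierarchy-flattened (everything else in the body);
    paths only in the round-tripped document are listed as introduced. The
    record is empty only for an identity round trip. Item-group loss is a
    property of the forward direction and is reported by
    :func:`odmcda.forward_mapping.forward_loss_report`.
    """
    original_paths = _paths_of(original)
    new_paths = _paths_of(roundtripped)

    record = LossRecord()
    for path, count in sorted((original_paths - new_paths).items()):
        components = tuple(path.split("."))
        if components[0] in HEADER_ELEMENTS:
            bucket = record.header_dropped
        elif "text" in components:
            bucket = record.narrative_ignored
        else:
            bucket = record.hierarchy_flattened
        bucket.extend([path] * count)
    for path, count in sorted((new_paths - original_paths).items()):
        record.introduced_paths.extend([path] * count)
    return record
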