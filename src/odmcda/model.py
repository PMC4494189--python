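"""Domain model for the ODM/CDA metadata crosswalk.

Two families of value objects live here: the CDISC ODM side (a study is a
list of forms; a form references item groups; an item group references
items; an item has a name, a data type and optionally a code list and
semantic annotations) and the HL7 CDA side (a clinical document is a header
plus a body of sections; a section holds narrative text and structured
entries). ``FlattenedItem`` is the product of collapsing a CDA XML
hierarchy into uniquely named, dot-joined paths.

All types are plain frozen-ish dataclasses with no XML awareness; parsing
and serialization live in :mod:`odmcda.odm_io` and :mod:`odmcda.cda_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ODM_DATA_TYPES",
    "CDA_VALUE_TYPES",
    "SemanticCode",
    "CodeList",
    "ItemDefinition",
    "ItemGroupDefinition",
    "FormDefinition",
    "StudyMetadata",
    "CdaHeader",
    "CdaEntry",
    "CdaSection",
    "CdaDocument",
    "FlattenedItem",
    "Finding",
    "ForwardMappingConfig",
    "ReverseMappingConfig",
    "LossRecord",
]

#: Closed set of ODM item data types handled by the converter.
ODM_DATA_TYPES = frozenset(
    {"text", "string", "integer", "float", "date", "datetime", "time", "boolean"}
)

#: Closed set of CDA entry value types emitted by the forward mapping.
CDA_VALUE_TYPES = frozenset({"INT", "REAL", "ST", "TS", "BL", "CD", "ED"})


@dataclass(frozen=True)
class SemanticCode:
    """A concept code from a named vocabulary (e.g. UMLS ``C0421451``)."""

    system: str
    code: str
    display_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.system or not self.code:
            raise ValueError("SemanticCode requires non-empty system and code")


@dataclass
class CodeList:
    """An enumerated value domain: ordered (coded value, decode-by-language) pairs."""

    oid: str
    data_type: str
    entries: list[tuple[str, dict[str, str]]] = field(default_factory=list)
    name: str = ""


@dataclass
class ItemDefinition:
    """One CRF data element: a name and a data type, optionally coded.

    ``mandatory``/``repeating`` are always materialized; ODM itself carries
    the mandatory flag on references and repetition on item groups, so these
    fields hold the converter's defaults (the CDA-to-ODM direction always
    assigns Mandatory="Yes" and Repeating="No").
    """

    oid: str
    name: str
    data_type: str
    code_list_oid: Optional[str] = None
    question_text: dict[str, str] = field(default_factory=dict)
    semantic_codes: list[SemanticCode] = field(default_factory=list)
    mandatory: bool = True
    repeating: bool = False

    def __post_init__(self) -> None:
        if self.data_type not in ODM_DATA_TYPES:
            raise ValueError(f"unknown ODM data type: {self.data_type!r}")


@dataclass
class ItemGroupDefinition:
    oid: str
    name: str
    repeating: bool = False
    #: ordered (item OID, mandatory) pairs
    item_refs: list[tuple[str, bool]] = field(default_factory=list)


@dataclass
class FormDefinition:
    oid: str
    name: str
    #: ordered (itemgroup OID, mandatory) pairs
    itemgroup_refs: list[tuple[str, bool]] = field(default_factory=list)


@dataclass
class StudyMetadata:
    """Root of the ODM side: forms, item groups, items and code lists, keyed by OID."""

    study_oid: str
    study_name: str
    metadata_version_oid: str
    forms: list[FormDefinition] = field(default_factory=list)
    item_groups: list[ItemGroupDefinition] = field(default_factory=list)
    items: list[ItemDefinition] = field(default_factory=list)
    code_lists: list[CodeList] = field(default_factory=list)

    # -- OID lookups -------------------------------------------------
    def form(self, oid: str) -> FormDefinition:
        return _lookup(self.forms, oid, "form")

    def item_group(self, oid: str) -> ItemGroupDefinition:
        return _lookup(self.item_groups, oid, "item group")

    def item(self, oid: str) -> ItemDefinition:
        return _lookup(self.items, oid, "item")

    def code_list(self, oid: str) -> CodeList:
        return _lookup(self.code_lists, oid, "code list")

    def items_of_form(self, form_oid: str) -> list[ItemDefinition]:
        """Items reachable from a form via its item groups, in document order."""
        out: list[ItemDefinition] = []
        for ig_oid, _ in self.form(form_oid).itemgroup_refs:
            for item_oid, _ in self.item_group(ig_oid).item_refs:
                out.append(self.item(item_oid))
        return out


def _lookup(collection, oid: str, kind: str):
    for obj in collection:
        if obj.oid == oid:
            return obj
    raise KeyError(f"no {kind} with OID {oid!r}")


# ---------------------------------------------------------------------------
# CDA side
# ---------------------------------------------------------------------------


@dataclass
class CdaHeader:
    """Descriptive metadata of a clinical document.

    ``effective_time`` uses the CDA TS literal form (``YYYYMMDDhhmmss±zzzz``).
    """

    document_id: str = ""
    document_code: Optional[SemanticCode] = None
    title: str = ""
    effective_time: str = ""
    confidentiality_code: str = "N"
    language_code: str = "en"
    patient_given: list[str] = field(default_factory=list)
    patient_family: str = ""
    custodian_name: str = ""
    author_name: str = ""


@dataclass
class CdaEntry:
    """One structured data point: an act-class element with a code and a typed value."""

    act_class: str
    code: SemanticCode
    value_type: str
    mood: str = "EVN"
    value: Optional[str] = None
    #: permissible (code, label) pairs for CD-typed entries derived from a code list
    code_list_values: Optional[list[tuple[str, str]]] = None
    #: additional concept codes carried as <translation> children of the code
    translations: list[SemanticCode] = field(default_factory=list)


@dataclass
class CdaSection:
    title: str = ""
    section_code: Optional[SemanticCode] = None
    narrative_text: str = ""
    entries: list[CdaEntry] = field(default_factory=list)


@dataclass
class CdaDocument:
    header: CdaHeader = field(default_factory=CdaHeader)
    sections: list[CdaSection] = field(default_factory=list)
    #: parsed XML tree of the source; present only for documents that were read
    raw_tree: object = None


# ---------------------------------------------------------------------------
# Reverse-mapping products and configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlattenedItem:
    """One product of flattening a CDA tree.

    ``name`` is the dot-joined element path (root element excluded), with
    ``.attributes.<attr>`` appended for attribute-borne data and an ordinal
    suffix appended when the same name would otherwise repeat.
    """

    name: str
    source_kind: str  # "node_text" | "attribute"
    source_path: tuple[str, ...]
    example_value: str
    inferred_type: str
    attribute_name: Optional[str] = None


@dataclass(frozen=True)
class Finding:
    """One structural-validation finding. ``kind`` is a stable machine key."""

    kind: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.subject}: {self.message}"


#: UMLS code-system OID (HL7 OID registry).
UMLS_OID = "2.16.840.1.113883.6.86"
#: LOINC code-system OID, used for section/document codes.
LOINC_OID = "2.16.840.1.113883.6.1"
#: Local arc used for deterministically generated codes of unannotated items.
LOCAL_CODE_SYSTEM_OID = "2.16.840.1.113883.19"


@dataclass
class ForwardMappingConfig:
    """Tunables of the ODM-to-CDA direction."""

    code_system_map: dict[str, str] = field(
        default_factory=lambda: {"UMLS": UMLS_OID, "LOINC": LOINC_OID}
    )
    default_act_class: str = "observation"
    language: str = "en"
    header_overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.default_act_class:
            raise ValueError("default_act_class must be non-empty")


@dataclass
class ReverseMappingConfig:
    """Tunables of the CDA-to-ODM flattening direction.

    ``group_by_depth`` is the path-prefix length that defines item-group
    assignment (depth 1 puts all ``patient.*`` items in one group).
    Structural attributes (classCode, moodCode, typeCode) are retained by
    default because CDA stores data in attributes; set
    ``skip_structural_attributes`` to exclude them.
    """

    #: extra attribute local names never converted; namespace declarations and
    #: xsi:* schema plumbing are always skipped regardless of this set
    skip_attributes: frozenset[str] = frozenset()
    skip_elements: frozenset[str] = frozenset()
    max_path_depth: int = 32
    group_by_depth: int = 1
    skip_structural_attributes: bool = False
    #: recover section <entry> subtrees as proper items instead of flattening them
    recover_entries: bool = True
    #: OID -> vocabulary name, inverse of the forward code_system_map
    code_system_names: dict[str, str] = field(
        default_factory=lambda: {UMLS_OID: "UMLS", LOINC_OID: "LOINC"}
    )

    def __post_init__(self) -> None:
        if self.max_path_depth < 1:
            raise ValueError("max_path_depth must be >= 1")
        if self.group_by_depth < 1:
            raise ValueError("group_by_depth must be >= 1")


STRUCTURAL_ATTRIBUTES = frozenset({"classCode", "moodCode", "typeCode"})


@dataclass
class LossRecord:
    """What a round trip lost, by class.

    Each loss list holds dot-joined element paths (original document side);
    ``introduced_paths`` holds paths present only in the re-generated
    document. ``is_empty`` is true only for an identity round trip.
    """

    header_dropped: list[str] = field(default_factory=list)
    hierarchy_flattened: list[str] = field(default_factory=list)
    narrative_ignored: list[str] = field(default_factory=list)
    itemgroup_lost: list[str] = field(default_factory=list)
    introduced_paths: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (
            self.header_dropped
            or self.hierarchy_flattened
            or self.narrative_ignored
            or self.itemgroup_lost
            or self.introduced_paths
        )

    def to_dict(self) -> dict:
        return {
            "header_dropped": list(self.header_dropped),
            "hierarchy_flattened": list(self.hierarchy_flattened),
            "narrative_ignored": list(self.narrative_ignored),
            "itemgroup_lost": list(self.itemgroup_lost),
            "introduced_paths": list(self.introduced_paths),
            "empty": self.is_empty,
        }
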