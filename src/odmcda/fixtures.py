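"""Seeded synthetic generators for ODM studies and CDA documents.

The evaluation corpora the conversion method is usually exercised on —
public CRF collections and national EHR discharge letters — cannot be
bundled, so these generators emulate their shape offline: ODM studies with
configurable numbers of forms, item groups and items covering every data
type, code lists and UMLS-style aliases; CDA trees with configurable depth
and fanout, mixed node-text/attribute data, repeated siblings and narrative
sections. Real evaluation documents reach roughly 11–107 items per CRF and
up to ~3000 flattened items per CDA file; specs can be sized to match.

Everything is a pure function of the :class:`FixtureSpec` (full seed
determinism), and every generator output passes its structural validator.
``inject_defect`` produces copies with exactly one named defect, for
mutation-based validator tests.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field, replace

from lxml import etree

from .cda_io import CDA_NS, XSI_TYPE, read_cda
from .model import (
    UMLS_OID,
    CdaDocument,
    CodeList,
    FormDefinition,
    ItemDefinition,
    ItemGroupDefinition,
    SemanticCode,
    StudyMetadata,
)

DEFECT_KINDS = (
    "dangling-reference",
    "duplicate-oid",
    "missing-header-field",
    "unknown-value-type",
)

_DATA_TYPES = ("text", "string", "integer", "float", "date", "datetime", "time", "boolean")

_ITEM_NAMES = [
    "Patient Weight", "Patient Height", "Heart Rate", "Blood Pressure Systolic",
    "Blood Pressure Diastolic", "Body Temperature", "Date of Birth", "Sex",
    "Adverse Event Term", "Event Onset Date", "Event Severity", "Serious Event",
    "Hemoglobin", "Leukocyte Count", "Platelet Count", "Creatinine",
    "Smoking Status", "Alcohol Use", "Visit Date", "Informed Consent",
    "Tumor Stage", "ECOG Performance Status", "Medication Name", "Dose",
]

_FORM_NAMES = [
    "Vital Signs", "Adverse Event", "Eligibility", "Follow Up",
    "Medical History", "Laboratory Findings", "Baseline Documentation",
    "Review of Systems", "Concomitant Medication", "Registry Core Data",
]

_GROUP_NAMES = [
    "Demographics", "Measurements", "Assessment", "Laboratory",
    "Medication", "History", "Outcome", "Administrative",
]

_CDA_ELEMENT_NAMES = [
    "observation", "organizer", "value", "code", "city", "telecom", "name",
    "given", "family", "addr", "streetAddressLine", "birthTime", "quantity",
    "interpretationCode", "device", "specimen", "effectiveTime", "statusCode",
]

_CDA_ATTR_NAMES = ["value", "code", "unit", "use", "root", "extension"]

_GIVEN_NAMES = ["Herbert", "Anna", "Maria", "Josef", "Eva", "Karl"]
_FAMILY_NAMES = ["Mustermann", "Musterfrau", "Beispiel", "Probst", "Muster"]
_CITIES = ["Vienna", "Graz", "Linz", "Salzburg", "Innsbruck"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study or document; identical spec → identical fixture."""

    seed: int = 0
    n_forms: int = 3
    n_itemgroups_per_form: tuple[int, int] = (1, 4)
    n_items_per_group: tuple[int, int] = (2, 8)
    datatype_weights: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 / len(_DATA_TYPES) for t in _DATA_TYPES}
    )
    codelist_probability: float = 0.25
    umls_probability: float = 0.3
    cda_depth: tuple[int, int] = (3, 6)
    cda_fanout: tuple[int, int] = (1, 4)
    attribute_probability: float = 0.4
    repeated_sibling_probability: float = 0.2
    max_cda_nodes: int = 600

    def __post_init__(self) -> None:
        for name in (
            "codelist_probability",
            "umls_probability",
            "attribute_probability",
            "repeated_sibling_probability",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        total = sum(self.datatype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"datatype_weights must sum to 1, got {total}")
        unknown = set(self.datatype_weights) - set(_DATA_TYPES)
        if unknown:
            raise ValueError(f"unknown data types in weights: {sorted(unknown)}")
        for name in ("n_forms", "max_cda_nodes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def with_seed(spec: FixtureSpec, seed: int) -> FixtureSpec:
    """Copy of ``spec`` with a different seed (for fixture families)."""
    return replace(spec, seed=seed)


# ---------------------------------------------------------------------------
# ODM fixtures
# ---------------------------------------------------------------------------


def generate_odm_fixture(spec: FixtureSpec) -> StudyMetadata:
    """A valid synthetic study; every data type is exercised once the item
    count reaches eight (the first items cycle through the full type set)."""
    rng = random.Random(spec.seed)
    study = StudyMetadata(
        study_oid=f"S.FIX.{spec.seed}",
        study_name=f"Synthetic study {spec.seed}",
        metadata_version_oid="MDV.1",
    )
    types = list(spec.datatype_weights)
    weights = [spec.datatype_weights[t] for t in types]
    item_counter = 0

    for f_idx in range(1, spec.n_forms + 1):
        form = FormDefinition(
            oid=f"F.{f_idx}",
            name=f"{_FORM_NAMES[(f_idx - 1) % len(_FORM_NAMES)]} {f_idx}",
        )
        study.forms.append(form)
        n_groups = rng.randint(*spec.n_itemgroups_per_form)
        for g_idx in range(1, n_groups + 1):
            ig = ItemGroupDefinition(
                oid=f"IG.{f_idx}.{g_idx}",
                name=f"{_GROUP_NAMES[(g_idx - 1) % len(_GROUP_NAMES)]} {f_idx}.{g_idx}",
                repeating=rng.random() < 0.1,
            )
            study.item_groups.append(ig)
            form.itemgroup_refs.append((ig.oid, rng.random() < 0.9))
            for _ in range(rng.randint(*spec.n_items_per_group)):
                item_counter += 1
                item = _make_item(study, spec, rng, item_counter, types, weights)
                study.items.append(item)
                ig.item_refs.append((item.oid, rng.random() < 0.8))
    return study


def _make_item(study, spec, rng, counter, types, weights) -> ItemDefinition:
    # first pass through the type set is deterministic round-robin so every
    # data type appears in any reasonably sized study
    if counter <= len(_DATA_TYPES):
        data_type = _DATA_TYPES[counter - 1]
    else:
        data_type = rng.choices(types, weights=weights, k=1)[0]
    name = f"{_ITEM_NAMES[(counter - 1) % len(_ITEM_NAMES)]}"
    if counter > len(_ITEM_NAMES):
        name = f"{name} {counter}"

    code_list_oid = None
    if rng.random() < spec.codelist_probability:
        code_list_oid = f"CL.{counter}"
        n_entries = rng.randint(2, 5)
        study.code_lists.append(
            CodeList(
                oid=code_list_oid,
                data_type="string",
                entries=[
                    (f"V{k}", {"en": f"Choice {k} for {name}"})
                    for k in range(1, n_entries + 1)
                ],
                name=f"{name} codes",
            )
        )

    codes = []
    if rng.random() < spec.umls_probability:
        # Alias elements cannot carry a display name, so none is set here
        codes.append(SemanticCode(system="UMLS", code=f"C{rng.randrange(10**7):07d}"))
        if rng.random() < 0.2:
            codes.append(SemanticCode(system="UMLS", code=f"C{rng.randrange(10**7):07d}"))

    return ItemDefinition(
        oid=f"I.{counter}",
        name=name,
        data_type=data_type,
        code_list_oid=code_list_oid,
        question_text={"en": f"Please record: {name}"},
        semantic_codes=codes,
    )


# ---------------------------------------------------------------------------
# CDA fixtures
# ---------------------------------------------------------------------------


def _q(tag: str) -> str:
    return f"{{{CDA_NS}}}{tag}"


def generate_cda_fixture(spec: FixtureSpec) -> CdaDocument:
    """A structurally valid synthetic clinical document.

    The header always contains a patient/name/given+family subtree (the
    canonical flattening example) and a telecom element whose data lives in
    an attribute; the body mixes narrative sections, at least one structured
    entry, and randomly nested elements with text leaves, attributes and
    repeated siblings. Returned via :func:`read_cda`, so ``raw_tree`` is set.
    """
    rng = random.Random(spec.seed ^ 0x5CDA)
    root = etree.Element(
        _q("ClinicalDocument"),
        nsmap={None: CDA_NS, "xsi": "http://www.w3.org/2001/XMLSchema-instance"},
    )
    etree.SubElement(root, _q("typeId"), root="2.16.840.1.113883.1.3",
                     extension="POCD_HD000040")
    etree.SubElement(root, _q("id"), root="2.16.840.1.113883.19.5",
                     extension=f"DOC.FIX.{spec.seed}")
    etree.SubElement(root, _q("code"), code="11490-0",
                     codeSystem="2.16.840.1.113883.6.1",
                     displayName="Physician Discharge summary")
    etree.SubElement(root, _q("title")).text = f"Synthetic discharge summary {spec.seed}"
    stamp = (
        f"{rng.randint(2010, 2020)}{rng.randint(1, 12):02d}{rng.randint(1, 28):02d}"
        f"{rng.randint(0, 23):02d}{rng.randint(0, 59):02d}{rng.randint(0, 59):02d}+0100"
    )
    etree.SubElement(root, _q("effectiveTime"), value=stamp)
    etree.SubElement(root, _q("confidentialityCode"), code="N",
                     codeSystem="2.16.840.1.113883.5.25")
    etree.SubElement(root, _q("languageCode"), code="de-AT")

    given = rng.choice(_GIVEN_NAMES)
    family = rng.choice(_FAMILY_NAMES)
    rt = etree.SubElement(root, _q("recordTarget"))
    role = etree.SubElement(rt, _q("patientRole"))
    etree.SubElement(role, _q("id"), root="1.2.40.0.10.1.4.3.1",
                     extension=f"PAT{rng.randrange(10**6):06d}")
    etree.SubElement(role, _q("telecom"),
                     value=f"mailto:{family.lower()}@mail.example")
    addr = etree.SubElement(role, _q("addr"))
    etree.SubElement(addr, _q("city")).text = rng.choice(_CITIES)
    patient = etree.SubElement(role, _q("patient"))
    name = etree.SubElement(patient, _q("name"))
    etree.SubElement(name, _q("given")).text = given
    etree.SubElement(name, _q("family")).text = family

    author = etree.SubElement(root, _q("author"))
    etree.SubElement(author, _q("time"), value=stamp)
    assigned = etree.SubElement(author, _q("assignedAuthor"))
    etree.SubElement(assigned, _q("id"), nullFlavor="NA")
    person = etree.SubElement(assigned, _q("assignedPerson"))
    etree.SubElement(person, _q("name")).text = f"Dr. {rng.choice(_FAMILY_NAMES)}"

    custodian = etree.SubElement(root, _q("custodian"))
    ac = etree.SubElement(custodian, _q("assignedCustodian"))
    org = etree.SubElement(ac, _q("representedCustodianOrganization"))
    etree.SubElement(org, _q("id"), nullFlavor="NA")
    etree.SubElement(org, _q("name")).text = f"{rng.choice(_CITIES)} General Hospital"

    comp = etree.SubElement(root, _q("component"))
    body = etree.SubElement(comp, _q("structuredBody"))
    budget = [spec.max_cda_nodes]
    for s_idx in range(rng.randint(1, 3)):
        s_comp = etree.SubElement(body, _q("component"))
        section = etree.SubElement(s_comp, _q("section"))
        etree.SubElement(section, _q("code"), code=f"{rng.randrange(10000, 99999)}-{rng.randrange(10)}",
                         codeSystem="2.16.840.1.113883.6.1")
        etree.SubElement(section, _q("title")).text = (
            "Brieftext" if s_idx == 0 else f"Befund {s_idx + 1}"
        )
        etree.SubElement(section, _q("text")).text = (
            f"Narrative free text of section {s_idx + 1}, not structured."
        )
        if s_idx == 0:
            _add_structured_entry(section, rng)
        depth = rng.randint(*spec.cda_depth)
        _grow(section, rng, spec, depth, budget)

    return read_cda(etree.tostring(root, xml_declaration=True, encoding="UTF-8"))


def _add_structured_entry(section: etree._Element, rng: random.Random) -> None:
    entry = etree.SubElement(section, _q("entry"))
    obs = etree.SubElement(entry, _q("observation"), classCode="OBS", moodCode="EVN")
    etree.SubElement(obs, _q("code"), code=f"C{rng.randrange(10**7):07d}",
                     codeSystem=UMLS_OID, displayName="Body Weight")
    value = etree.SubElement(obs, _q("value"))
    value.set(XSI_TYPE, "REAL")
    value.set("value", f"{rng.uniform(40, 120):.1f}")


def _leaf_text(rng: random.Random) -> str:
    kind = rng.randrange(4)
    if kind == 0:
        return str(rng.randrange(1000))
    if kind == 1:
        return f"{rng.uniform(0, 100):.2f}"
    if kind == 2:
        return (
            f"{rng.randint(2000, 2020)}{rng.randint(1, 12):02d}"
            f"{rng.randint(1, 28):02d}{rng.randint(0, 23):02d}"
            f"{rng.randint(0, 59):02d}{rng.randint(0, 59):02d}+0100"
        )
    return rng.choice(["normal", "elevated", "reduced", "unknown", "o.B."])


def _grow(parent, rng, spec: FixtureSpec, depth: int, budget: list[int]) -> None:
    """Grow a random subtree: text leaves, attributes, repeated siblings."""
    if depth <= 0 or budget[0] <= 0:
        return
    n_children = rng.randint(*spec.cda_fanout)
    children = []
    for _ in range(n_children):
        if budget[0] <= 0:
            break
        budget[0] -= 1
        tag = rng.choice(_CDA_ELEMENT_NAMES)
        el = etree.SubElement(parent, _q(tag))
        if rng.random() < spec.attribute_probability:
            el.set(rng.choice(_CDA_ATTR_NAMES), _leaf_text(rng))
        children.append(el)
    for el in children:
        if depth == 1 or rng.random() < 0.3:
            el.text = _leaf_text(rng)
        else:
            _grow(el, rng, spec, depth - 1, budget)
            if len(el) == 0 and el.text is None:
                el.text = _leaf_text(rng)
    # repeated siblings: duplicate one child (deep copy) to exercise the
    # ordinal-suffix disambiguation rule
    if children and rng.random() < spec.repeated_sibling_probability and budget[0] > 0:
        dup = copy.deepcopy(rng.choice(children))
        budget[0] -= 1
        parent.append(dup)


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------


def inject_defect(study_or_doc, defect_kind: str):
    """Copy of the input with exactly one defect of the named kind.

    ODM kinds: ``dangling-reference``, ``duplicate-oid``. CDA kinds:
    ``missing-header-field``, ``unknown-value-type``.
    """
    if defect_kind not in DEFECT_KINDS:
        raise ValueError(
            f"unknown defect kind {defect_kind!r}; expected one of {DEFECT_KINDS}"
        )
    mutant = copy.deepcopy(study_or_doc)

    if isinstance(mutant, StudyMetadata):
        if defect_kind == "dangling-reference":
            if not mutant.item_groups:
                raise ValueError("study has no item groups to mutate")
            mutant.item_groups[0].item_refs.append(("I.DOES.NOT.EXIST", True))
        elif defect_kind == "duplicate-oid":
            if len(mutant.items) >= 2:
                mutant.items[1].oid = mutant.items[0].oid
            elif mutant.items:
                dup = copy.deepcopy(mutant.items[0])
                mutant.items.append(dup)
            else:
                raise ValueError("study has no items to mutate")
        else:
            raise ValueError(f"{defect_kind!r} applies to CDA documents, not studies")
        return mutant

    if isinstance(mutant, CdaDocument):
        if defect_kind == "missing-header-field":
            mutant.header.effective_time = ""
        elif defect_kind == "unknown-value-type":
            for section in mutant.sections:
                if section.entries:
                    section.entries[0].value_type = "XX"
                    break
            else:
                raise ValueError("document has no entries to mutate")
        else:
            raise ValueError(f"{defect_kind!r} applies to ODM studies, not documents")
        return mutant

    raise TypeError(f"cannot inject defects into {type(study_or_doc).__name__}")
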