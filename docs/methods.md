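# Methods

This note documents the conversion model, the defaults and tunables, the
synthetic-data generators the test suite runs on, and the numerical and
design choices made where the two standards leave the mapping open.

## Scope and assumptions

The converter operates on *metadata*: the list of named, typed data items
that defines a documentation form. Patient-level content (ODM
`ClinicalData`, the values inside a CDA instance beyond what is needed as
type-inference examples) is out of scope. ODM is handled at version 1.3.2
(namespace `http://www.cdisc.org/ns/odm/v1.3`); other 1.3.x inputs are
read with a logged notice and always written back as 1.3.2. CDA is handled
at R2 (`urn:hl7-org:v3`) at the fidelity the crosswalk needs: a typed
header plus sections with narrative and structured entries; everything
else in a read document survives in the retained parse tree. Outputs are
valid CDA *structures*, not HL7-registered templates; no `templateId` is
emitted unless supplied.

## Forward direction (ODM → CDA)

One document per form — a CDA instance is a single clinical document, so a
multi-form study yields a batch. All items reachable through the form's
item groups become entries of a single assessment section (LOINC 51848-0),
in document order. Choices where ODM is silent or CDA demands more than
ODM provides:

- **Act class.** ODM has no act classification; entries default to
  `observation` in event mood (`classCode="OBS" moodCode="EVN"`),
  overridable via `ForwardMappingConfig.default_act_class`.
- **Type map.** integer→INT, float→REAL, text/string→ST,
  date/datetime/time→TS, boolean→BL; an attached code list overrides to
  CD, with the enumerated (coded value, decoded label) pairs carried as
  multiple `value` elements on the entry. No external value-set OIDs are
  minted, keeping the output self-contained.
- **Semantic codes.** The item's first code becomes the entry code, the
  rest become `translation` children (CDA's code/translation idiom).
  Vocabulary names map to code-system OIDs via
  `ForwardMappingConfig.code_system_map` (UMLS →
  `2.16.840.1.113883.6.86`, LOINC → `2.16.840.1.113883.6.1`); unmapped
  vocabularies fall back to a local arc with a logged warning. The display
  name falls back to the item name when the annotation carries none.
- **Generated codes.** Items without annotation get a code derived by
  hashing study OID + item OID (SHA-256, first 10 hex digits), placed in
  the demonstration OID arc `2.16.840.1.113883.19` — deterministic across
  runs by construction.
- **Header placeholders.** CDA requires recordTarget/author/custodian;
  ODM has none of them. Fixed placeholders are written (patient name as
  `nullFlavor="NA"`, a generic author, the study name as custodian), all
  overridable through `header_overrides`. `effectiveTime` uses the CDA TS
  literal form and defaults to a fixed epoch stamp so that equal inputs
  serialize byte-identically.
- **Narrative.** CDA requires human-readable text per section; a text
  block listing the item names is synthesized when the caller provides
  none.
- **Loss.** Item-group boundaries are not representable in the flat
  section; `forward_loss_report` records one `itemgroup-lost` entry per
  dissolved group whenever a form has two or more.

## Reverse direction (CDA → ODM)

Flattening is a depth-first, document-order walk. Per element (the root
contributes no path component): retained attributes first, then the
element's own concatenated non-whitespace text, then descent. Naming is
`make_item_name`: dot-joined local names, `.attributes.<name>` for
attribute items, and an ordinal suffix from the second occurrence of a
base name onward — the first occurrence keeps the plain name, so the
canonical examples (`patient.name.given`, `telecom.attributes.value`)
appear unsuffixed. Choices:

- **Attributes as data.** CDA stores data in attributes, so attributes are
  converted by default, including the structural `classCode` /
  `moodCode` / `typeCode` trio (excludable via
  `skip_structural_attributes`). Namespace declarations and `xsi:*`
  schema plumbing are never converted.
- **Type inference.** Checked in order over all observed values: integer,
  float, date (`YYYYMMDD` literals are caught by the integer rule first,
  ISO dates by the date rule), datetime (CDA TS with optional UTC
  offset), boolean (`true`/`false`), else string. Order-independent.
- **Grouping.** Items are partitioned into item groups by the first
  `group_by_depth` (default 1) path components, in first-appearance
  order — the smallest rule that yields valid, navigable ODM.
- **Entry recovery.** Section `entry` subtrees are structured data
  elements, not incidental hierarchy; by default they are recovered as
  proper items (name from the code's display name, data type inverted
  from the value type, codes mapped back from OIDs to vocabulary names
  via `code_system_names`, CD values restored as a code list), grouped
  per section. `recover_entries=False` restores pure flattening.
- **Narrative.** Section narrative blocks yield no structured item; they
  are dropped with a logged count and appear in the loss report as
  `narrative-ignored`.
- **Defaults law.** Every produced item materializes
  `Mandatory="Yes"` / `Repeating="No"`: an instance document cannot
  reveal optionality or repetition. ODM itself carries the mandatory flag
  on references and repetition on item groups, so the item-level fields
  in this package are these materialized converter defaults; the
  reference-level flags are what serialization round-trips.
- **Example values** are captured into the item's question text (key
  `"en"`), keeping the metadata self-describing without emitting any
  `ClinicalData`.
- `max_path_depth` (default 32, effectively unbounded for real documents)
  prunes pathological nesting; pruned elements are counted and logged.

## Loss reporting

`loss_report(original, roundtripped)` diffs the element-path multisets of
the two documents and classifies paths missing from the regenerated one:
subtrees under header elements → `header-dropped`; paths through section
narrative → `narrative-ignored`; remaining body paths →
`hierarchy-flattened`; paths only in the regenerated document are listed
as `introduced`. Item-group loss is observable only on the ODM side and
is reported by `forward_loss_report`. The record is empty exactly for an
identity round trip; any document with a non-trivial header produces a
non-empty record, which the test suite asserts as the non-invertibility
property of the reverse direction.

## Synthetic data

No public CRF or discharge-letter corpus is bundled; seeded generators
emulate their shape (`FixtureSpec`, full seed determinism):

- **ODM studies**: configurable forms / item groups / items (defaults 3
  forms, 1–4 groups of 2–8 items), all eight data types guaranteed by a
  deterministic first pass, code lists at rate 0.25, UMLS-style aliases at
  rate 0.3 — most real public forms are sparsely annotated, so annotation
  is the minority case. Real evaluation CRFs run 11–107 items; specs can
  be sized to match (the suite exercises a 14-item single-form study and
  the acceptance script 10-form batches).
- **CDA documents**: a fixed conformant header that always contains the
  `patient/name/given+family` subtree and an attribute-carrying
  `telecom`, one guaranteed structured entry, then randomly grown body
  subtrees (depth 3–6, fanout 1–4, attribute rate 0.4, repeated-sibling
  rate 0.2, capped at 600 elements by default). The largest evaluated
  scale (~3000 flattened items) is reached by raising depth/fanout/cap;
  the acceptance script and suite convert such a document and time it.
- **Defect injection** produces copies with exactly one defect
  (`dangling-reference`, `duplicate-oid`, `missing-header-field`,
  `unknown-value-type`) for mutation-kill tests of the validators.

What the generators do **not** emulate: clinically meaningful content,
template-conformant national CDA profiles (ELGA and friends), vendor
extensions, and non-XML encodings. Passing tests therefore demonstrate
structural and semantic-code correctness of the crosswalk, not fitness of
any particular national template.

## Validation

Structural validation is self-contained (OID uniqueness and resolution,
closed type sets, mandatory header fields, narrative presence) and
returns findings as data, never exceptions. The official ODM/CDA XSD
files are not bundled for licensing reasons; when the caller supplies a
schema path, full `lxml` XSD validation is appended to the findings.
Parsing is hardened: external entities and network access are disabled.

## Numerical and degenerate-input choices

- Serialization is deterministic: fixed creation/effective timestamps by
  default, stable element order, sorted language keys.
- Empty forms convert to a document with one empty section and a
  placeholder narrative; empty studies to a formless ODM file; documents
  with an empty `structuredBody` to zero sections.
- Whitespace-only text never produces items; mixed content contributes
  its concatenated non-whitespace direct text.
- Name collisions between entry-derived items and flattened path names
  are resolved by the same ordinal rule, with flattened names claimed
  first.

## Known limitations

- Reconstructing an original CDA from converted ODM is impossible by
  design and not attempted.
- Only the generic assessment-section layout is generated forward; no
  mapping into specialized CDA sections.
- ODM item-level mandatory/repeating flags other than the converter
  defaults do not survive a write/read cycle (ODM has no item-level
  carrier for them; the normative flags live on refs).
- Alias-borne semantic codes cannot carry display names in ODM; display
  names are reconstructed from item names on the CDA side.
- Free-text narrative is never parsed for structure (no NLP).
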