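# odmcda

Bidirectional conversion of **documentation-form metadata** between the two
XML standards that dominate clinical data capture: **CDISC ODM 1.3.2**
(Electronic Data Capture / clinical research) and **HL7 CDA R2**
(Electronic Health Records / patient care).

Clinical trials and routine care document the same patients in separate
systems with different standards, which forces redundant data entry. A
first step toward reuse is translating the *structure* of documentation
forms — the list of named, typed data items — from one representation to
the other. That is exactly what this package does. The scope is metadata
only: "empty" forms, never patient-level values.

## The conversion model

**Forward (ODM → CDA).** An ODM study structures each case report form
(CRF) into item groups, and item groups into items, each with a name, a
data type and optionally a code list. A CRF is a patient assessment, so
each form becomes one CDA document whose single *assessment section*
(LOINC 51848-0) holds one structured `entry` per item, in document order:

| ODM | CDA |
|---|---|
| FormDef | ClinicalDocument with one assessment section |
| ItemDef name | entry `code/@displayName` |
| ItemDef data type | entry value type: integer→`INT`, float→`REAL`, text/string→`ST`, date/datetime/time→`TS`, boolean→`BL` |
| code list | `CD` value with the enumerated (code, label) pairs |
| Alias (e.g. UMLS `C0421451`) | entry `code` in the mapped code system (UMLS OID 2.16.840.1.113883.6.86) |
| item group boundaries | **not representable — reported as loss** |

ODM has no act classes, so entries are generated as `observation` acts in
event mood (configurable). Items without semantic annotation get
deterministic locally minted codes, so runs are reproducible.

**Reverse (CDA → ODM).** CDA nests its data and stores it in both element
text and attributes, so items are produced by *flattening*: every element
with text and every retained attribute becomes one item, named by
concatenating local element names with dots —

```
<patient><name><given>…   →  patient.name.given, patient.name.family
<telecom value="mailto:…> →  telecom.attributes.value
```

Repeated names get ordinal suffixes (`.2`, `.3`, …). Data types are
inferred from observed values (integer / float / date / datetime / boolean
/ string); items are grouped into item groups by the first path component;
and every item is assigned `Mandatory="Yes"` and `Repeating="No"`, because
a CDA instance cannot reveal which of its elements are optional or
repeatable. Structured section entries are recovered as proper items
(name, code and type) rather than flattened; narrative text that maps to
no structured element is ignored.

Both directions are **lossy by design**; `loss_report` /
`forward_loss_report` enumerate and classify every dropped path
(header-dropped, hierarchy-flattened, narrative-ignored, itemgroup-lost).

## Worked example

```bash
python examples/convert_crf_to_cda.py
```

```
document title : Vital Signs
section title  : Vital Signs  (the generic assessment section)
entries        : 4  (one per CRF item)
  Date of Birth    code=C0421451     type=TS
  Patient Weight   code=X1906272AC3  type=REAL
  Heart Rate       code=XD1A48B0985  type=INT
  Smoking Status   code=XE1FB67FF1A  type=BL
validation findings: 0 (0 = structurally conformant CDA)
```

The UMLS-annotated "Date of Birth" keeps its concept code `C0421451` with
a timestamp (`TS`) value type; the unannotated items carry deterministic
local codes; the resulting document passes structural validation. The
other examples (`flatten_cda_to_odm.py`, `roundtrip_loss_report.py`) show
the reverse direction and the classified round-trip loss.

The same conversions are available from the shell:

```bash
odmcda fixtures odm --seed 1 -o study.xml
odmcda odm2cda study.xml -o out/          # one CDA file per form + JSON run log
odmcda cda2odm doc.xml -o study.xml       # flattened ODM study + run log
odmcda validate out/F.1.cda.xml           # exit 0 clean / 1 findings / 2 errors
odmcda roundtrip-report doc.xml -o loss.json
```

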