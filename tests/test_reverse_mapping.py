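"""CDA flattening, naming, type inference, conversion and loss reporting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lxml import etree

from _oracle import brute_force_flatten
from odmcda import (
    FixtureSpec,
    ReverseMappingConfig,
    StateError,
    cda_to_odm,
    flatten_cda,
    generate_cda_fixture,
    infer_datatype,
    loss_report,
    make_item_name,
    odm_to_cda,
    read_cda,
    validate_odm_structure,
)
from odmcda.model import CdaDocument

CDA_NS = "urn:hl7-org:v3"


def fragment(body: str) -> etree._Element:
    return etree.fromstring(f'<ClinicalDocument xmlns="{CDA_NS}">{body}</ClinicalDocument>')


class TestNaming:
    def test_concatenated_path(self):
        assert make_item_name(["patient", "name", "family"]) == "patient.name.family"

    def test_attribute_suffix(self):
        assert make_item_name(["telecom"], attribute="value") == "telecom.attributes.value"

    def test_ordinal_only_from_second_occurrence(self):
        assert make_item_name(["telecom"], "value", occurrence=1) == "telecom.attributes.value"
        assert make_item_name(["telecom"], "value", occurrence=2) == "telecom.attributes.value.2"

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            make_item_name([])

    @settings(derandomize=True, max_examples=50)
    @given(
        path=st.lists(st.sampled_from(["patient", "name", "given", "code"]), min_size=1, max_size=5),
        attr=st.none() | st.sampled_from(["value", "use"]),
        occ=st.integers(min_value=1, max_value=9),
    )
    def test_name_decomposes_back_to_path(self, path, attr, occ):
        """Stripping attribute and ordinal suffixes recovers the joined path."""
        name = make_item_name(path, attr, occ)
        core = name
        if occ > 1:
            assert core.endswith(f".{occ}")
            core = core[: -len(f".{occ}")]
        if attr is not None:
            assert core.endswith(f".attributes.{attr}")
            core = core[: -len(f".attributes.{attr}")]
        assert core == ".".join(path)


class TestFlatten:
    def test_patient_name_example(self):
        tree = fragment(
            "<patient><name><given>Herbert</given><family>Mustermann</family></name></patient>"
        )
        names = [f.name for f in flatten_cda(tree)]
        assert names == ["patient.name.given", "patient.name.family"]

    def test_telecom_attribute_example(self):
        tree = fragment('<telecom value="mailto:mustermann@mail.de"/>')
        [item] = flatten_cda(tree)
        assert item.name == "telecom.attributes.value"
        assert item.source_kind == "attribute"
        assert item.example_value == "mailto:mustermann@mail.de"

    def test_repeated_siblings_get_ordinals(self):
        tree = fragment('<telecom value="a"/><telecom value="b"/><telecom value="c"/>')
        names = [f.name for f in flatten_cda(tree)]
        assert names == [
            "telecom.attributes.value",
            "telecom.attributes.value.2",
            "telecom.attributes.value.3",
        ]

    def test_mixed_content_concatenates_text(self):
        tree = fragment("<note>alpha<sub>x</sub> beta</note>")
        names = {f.name: f.example_value for f in flatten_cda(tree)}
        assert names["note"] == "alpha beta"
        assert names["note.sub"] == "x"

    def test_whitespace_only_text_ignored(self):
        tree = fragment("<a>\n   <b>x</b>\n</a>")
        assert [f.name for f in flatten_cda(tree)] == ["a.b"]

    def test_xsi_attributes_skipped(self):
        tree = etree.fromstring(
            f'<ClinicalDocument xmlns="{CDA_NS}" '
            'xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance">'
            '<value xsi:type="INT" value="4"/></ClinicalDocument>'
        )
        assert [f.name for f in flatten_cda(tree)] == ["value.attributes.value"]

    def test_structural_attributes_config_flag(self):
        tree = fragment('<observation classCode="OBS" moodCode="EVN">x</observation>')
        default = {f.name for f in flatten_cda(tree)}
        assert "observation.attributes.classCode" in default
        stripped = {
            f.name
            for f in flatten_cda(tree, ReverseMappingConfig(skip_structural_attributes=True))
        }
        assert stripped == {"observation"}

    def test_max_path_depth_prunes(self):
        tree = fragment("<a><b><c>deep</c></b><d>shallow</d></a>")
        names = [f.name for f in flatten_cda(tree, ReverseMappingConfig(max_path_depth=2))]
        assert names == ["a.d"]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        doc = generate_cda_fixture(FixtureSpec(seed=seed))
        items = flatten_cda(doc.raw_tree)
        expected = brute_force_flatten(doc.raw_tree)
        assert [f.name for f in items] == expected

    def test_determinism_and_uniqueness(self):
        doc = generate_cda_fixture(FixtureSpec(seed=99))
        a = flatten_cda(doc.raw_tree)
        b = flatten_cda(doc.raw_tree)
        assert a == b
        names = [f.name for f in a]
        assert len(names) == len(set(names))

    def test_name_prefix_law(self, cda_family):
        """Stripped of suffixes, every name is the join of its source path."""
        for doc in cda_family(10):
            for item in flatten_cda(doc.raw_tree):
                expected = ".".join(item.source_path)
                if item.attribute_name is not None:
                    expected += f".attributes.{item.attribute_name}"
                assert item.name == expected or item.name.rsplit(".", 1)[0] == expected


class TestInferDatatype:
    @pytest.mark.parametrize(
        "values,expected",
        [
            (["42"], "integer"),
            (["42", "-7"], "integer"),
            (["3.14"], "float"),
            (["42", "3.14"], "float"),
            (["20130324082015+0100"], "datetime"),
            (["20130324"], "integer"),  # all-digit dates read as integers
            (["2013-03-24"], "date"),
            (["true", "false"], "boolean"),
            (["42", "x"], "string"),
            (["o.B."], "string"),
        ],
    )
    def test_inference(self, values, expected):
        assert infer_datatype(values) == expected

    def test_order_independent(self):
        assert infer_datatype(["42", "x"]) == infer_datatype(["x", "42"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            infer_datatype([])


class TestCdaToOdm:
    def test_requires_raw_tree(self):
        with pytest.raises(StateError):
            cda_to_odm(CdaDocument())

    def test_defaults_law(self, cda_family):
        for doc in cda_family(10):
            study = cda_to_odm(doc)
            assert study.items
            assert all(i.mandatory and not i.repeating for i in study.items)

    def test_output_is_valid_odm(self, cda_family):
        for doc in cda_family(15):
            assert validate_odm_structure(cda_to_odm(doc)) == []

    def test_one_form_named_after_title(self, cda_doc):
        study = cda_to_odm(cda_doc)
        assert len(study.forms) == 1
        assert study.forms[0].name == cda_doc.header.title

    def test_grouping_by_path_prefix(self, cda_doc):
        study = cda_to_odm(cda_doc, ReverseMappingConfig(recover_entries=False))
        flattened = flatten_cda(cda_doc.raw_tree)
        expected_prefixes = []
        for item in flattened:
            p = item.source_path[0]
            if p not in expected_prefixes:
                expected_prefixes.append(p)
        # narrative-only prefixes never make it into the study
        group_names = [ig.name for ig in study.item_groups]
        assert set(group_names) <= set(expected_prefixes)
        assert group_names == sorted(group_names, key=expected_prefixes.index)

    def test_example_values_carried_as_question_text(self, cda_doc):
        study = cda_to_odm(cda_doc)
        flattened_names = {
            f.name: f.example_value
            for f in flatten_cda(cda_doc.raw_tree)
        }
        carried = 0
        for item in study.items:
            if item.name in flattened_names:
                assert item.question_text.get("en") == flattened_names[item.name]
                carried += 1
        assert carried > 0

    def test_narrative_text_not_converted(self, cda_doc):
        study = cda_to_odm(cda_doc)
        assert not any("section.text" in i.name for i in study.items)


class TestLossReport:
    def test_identity_roundtrip_is_empty(self, cda_doc):
        assert loss_report(cda_doc, cda_doc).is_empty

    def test_header_subtrees_reported_dropped(self, cda_doc):
        regenerated = odm_to_cda(cda_to_odm(cda_doc))[0]
        record = loss_report(cda_doc, regenerated)
        assert any(p.startswith("recordTarget") for p in record.header_dropped)
        assert not record.is_empty

    @pytest.mark.parametrize("seed", range(10))
    def test_hierarchy_flattened_matches_path_diff_oracle(self, seed):
        from collections import Counter

        from odmcda._xml import element_paths, parse_bytes
        from odmcda.cda_io import write_cda
        from odmcda.reverse_mapping import HEADER_ELEMENTS

        doc = generate_cda_fixture(FixtureSpec(seed=seed))
        regenerated = odm_to_cda(cda_to_odm(doc))[0]
        record = loss_report(doc, regenerated)

        original = Counter(element_paths(doc.raw_tree))
        new = Counter(element_paths(parse_bytes(write_cda(regenerated))))
        expected = Counter()
        for path, n in (original - new).items():
            parts = path.split(".")
            if parts[0] not in HEADER_ELEMENTS and "text" not in parts:
                expected[path] += n
        assert Counter(record.hierarchy_flattened) == expected
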