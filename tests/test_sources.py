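"""Source-schema integration and training-example construction."""

import pytest
from hypothesis import given, settings, strategies as st

from geomex.schema import ATTRIBUTE_NAMES, CISTROME_ATTRIBUTES, ENCODE_ATTRIBUTES, DEFAULT_SCHEMA
from geomex.sources import (
    SchemaError,
    SourceRecord,
    TrainingExample,
    build_fallback_text,
    format_training_string,
    map_cistrome,
    map_encode,
    merge_datasets,
    parse_training_string,
    split_into_training_examples,
)


def test_unified_schema_has_fifteen_unique_attributes():
    assert len(DEFAULT_SCHEMA) == 15
    assert len(set(DEFAULT_SCHEMA.names)) == 15
    assert DEFAULT_SCHEMA.task_keyword("Cell Line") == "cell line:"


class TestCistromeMapping:
    def test_full_record(self):
        record = SourceRecord(
            source="cistrome",
            attrs={
                "Cell Line": "k562",
                "Cell Type": "erythroblast",
                "Tissue Type": "blood",
                "Factor Name": "ctcf",
            },
        )
        unified = map_cistrome(record)
        assert unified["Cell Line"] == "k562"
        assert unified["Cell Type"] == "erythroblast"
        assert unified["Tissue"] == "blood"
        assert unified["Target"] == "ctcf"
        assert all(
            unified[a] is None
            for a in ATTRIBUTE_NAMES
            if a not in ("Cell Line", "Cell Type", "Tissue", "Target")
        )

    def test_empty_record_all_null(self):
        unified = map_cistrome(SourceRecord(source="cistrome", attrs={}))
        assert all(v is None for v in unified.values())

    def test_attributes_mapped_independently(self):
        record = SourceRecord(
            source="cistrome",
            attrs={"Cell Line": "k562", "Cell Type": "erythroblast", "Factor Name": "ctcf"},
        )
        unified = map_cistrome(record)
        assert unified["Tissue"] is None
        assert unified["Cell Line"] == "k562"

    def test_wrong_source_rejected(self):
        with pytest.raises(SchemaError):
            map_cistrome(SourceRecord(source="encode", attrs={}))
        with pytest.raises(SchemaError):
            SourceRecord(source="cistrome", attrs={"Assay Name": "chip-seq"})


class TestEncodeMapping:
    def test_cell_line_classification(self):
        record = SourceRecord(
            source="encode",
            attrs={"Classification": "cell line", "Biosample term name": "HeLa-S3"},
        )
        unified = map_encode(record)
        assert unified["Cell Line"] == "HeLa-S3"
        assert unified["Cell Type"] is None
        assert unified["Tissue"] is None
        assert unified["Classification"] == "cell line"

    def test_tissue_classification(self):
        record = SourceRecord(
            source="encode",
            attrs={
                "Classification": "tissue",
                "Biosample term name": "liver",
                "Sex": "male",
                "Health status": "healthy",
            },
        )
        unified = map_encode(record)
        assert unified["Tissue"] == "liver"
        assert unified["Cell Line"] is None
        assert unified["Cell Type"] is None
        assert unified["Sex"] == "male"
        assert unified["Disease"] == "healthy"

    def test_unknown_classification_warns_and_leaves_null(self):
        record = SourceRecord(
            source="encode",
            attrs={"Classification": "organoid", "Biosample term name": "liver"},
        )
        with pytest.warns(UserWarning):
            unified = map_encode(record)
        assert unified["Cell Line"] is None and unified["Tissue"] is None

    def test_empty_record_all_null(self):
        unified = map_encode(SourceRecord(source="encode", attrs={}))
        assert all(v is None for v in unified.values())

    def test_encode_schema_carries_fifteen_attributes(self):
        assert len(ENCODE_ATTRIBUTES) == 15
        assert len(CISTROME_ATTRIBUTES) == 4


class TestFallbackText:
    def test_concatenation_order(self):
        record = SourceRecord(
            source="encode",
            attrs={
                "Description": "d",
                "Biosample summary": "b",
                "replicates.library.biosample.description": "r",
            },
        )
        sample = build_fallback_text(record)
        assert sample.fields["characteristics"] == "d b r"
        assert sample.fields["description"] == "d b r"

    def test_all_empty(self):
        sample = build_fallback_text(SourceRecord(source="encode", attrs={}))
        assert sample.fields["characteristics"] == ""

    def test_missing_components_skipped(self):
        record = SourceRecord(source="encode", attrs={"Biosample summary": "b"})
        assert build_fallback_text(record).fields["description"] == "b"


class TestTrainingExamples:
    def test_cistrome_record_splits_into_four(self):
        unified = map_cistrome(
            SourceRecord(
                source="cistrome",
                attrs={
                    "Cell Line": "k562",
                    "Cell Type": "erythroblast",
                    "Tissue Type": "blood",
                    "Factor Name": "ctcf",
                },
            )
        )
        examples = split_into_training_examples(unified, "some input")
        assert len(examples) == 4
        assert all(ex.input_text == "some input" for ex in examples)

    def test_all_null_gives_zero(self):
        assert split_into_training_examples({a: None for a in ATTRIBUTE_NAMES}, "x") == []

    def test_count_equals_non_null_attributes(self):
        unified = {a: None for a in ATTRIBUTE_NAMES}
        for a in ATTRIBUTE_NAMES[:9]:
            unified[a] = "v"
        examples = split_into_training_examples(unified, "shared")
        assert len(examples) == 9
        assert len({ex.input_text for ex in examples}) == 1
        assert {ex.task[:-1] for ex in examples} == {a.lower() for a in ATTRIBUTE_NAMES[:9]}

    def test_format_matches_special_keyword_layout(self):
        ex = TrainingExample(input_text="s", task="cell line:", target="hela-s3")
        assert format_training_string(ex) == "<BOS> s <SEP> cell line: hela-s3 <EOS>"

    def test_task_must_be_schema_attribute(self):
        with pytest.raises(SchemaError):
            TrainingExample(input_text="s", task="flavour:", target="x")

    targets = st.text(alphabet="abcdefgh0123456789- ", min_size=1, max_size=20).map(
        lambda s: " ".join(s.split())
    ).filter(bool)

    @given(
        input_text=st.text(alphabet="abcdef ", max_size=40).map(lambda s: " ".join(s.split())),
        attr=st.sampled_from(ATTRIBUTE_NAMES),
        target=targets,
    )
    @settings(max_examples=100, deadline=None)
    def test_parse_back_inverts_format(self, input_text, attr, target):
        ex = TrainingExample(input_text=input_text, task=attr.lower() + ":", target=target)
        assert parse_training_string(format_training_string(ex)) == ex


class TestMerge:
    def test_counts_concatenate(self):
        a = [TrainingExample("i", "cell line:", "k562")] * 4
        b = [TrainingExample("j", "sex:", "male")] * 9
        assert len(merge_datasets(a, b)) == 13
        assert merge_datasets([], []) == []

    def test_task_union(self):
        a = [TrainingExample("i", "cell line:", "k562")]
        b = [TrainingExample("j", "sex:", "male"), TrainingExample("j", "age:", "53")]
        merged = merge_datasets(a, b)
        assert {ex.task for ex in merged} == {"cell line:", "sex:", "age:"}
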