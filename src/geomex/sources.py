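"""Integrating Cistrome- and ENCODE-style annotations into the unified schema.

The two resources annotate different attribute sets.  Cistrome records carry
Cell Line, Cell Type, Tissue Type and Factor Name; ENCODE records carry
biosample and assay attributes whose interpretation depends on the
``Classification`` column ("cell line" vs "tissue").  Each annotated sample
is split into as many training examples as it has non-null attributes; all
examples of a sample share the same linearized input text and differ only in
the task keyword and the target value.  A training example is rendered for
fine-tuning as::

    <BOS> {input text} <SEP> {attribute name}: {value} <EOS>
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import LinearizedText, RawSampleRecord
from .schema import (
    ATTRIBUTE_NAMES,
    CISTROME_ATTRIBUTES,
    ENCODE_ATTRIBUTES,
    ENCODE_EXTRA_TEXT_ATTRIBUTE,
)

BOS = "<BOS>"
SEP = "<SEP>"
EOS = "<EOS>"
SPECIAL_KEYWORDS = (BOS, SEP, EOS)


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class SourceRecord:
    """One annotation row from Cistrome or ENCODE."""

    source: str  # "cistrome" | "encode"
    attrs: dict[str, str]
    gsm: str | None = None

    def __post_init__(self) -> None:
        if self.source not in ("cistrome", "encode"):
            raise SchemaError(f"unknown source {self.source!r}")
        declared = (
            set(CISTROME_ATTRIBUTES)
            if self.source == "cistrome"
            else set(ENCODE_ATTRIBUTES) | {ENCODE_EXTRA_TEXT_ATTRIBUTE}
        )
        unknown = set(self.attrs) - declared
        if unknown:
            raise SchemaError(
                f"attributes not in the {self.source} schema: {sorted(unknown)}"
            )


#: mapping unified-attribute <- source attribute, per-source
_CISTROME_MAP = {
    "Cell Line": "Cell Line",
    "Cell Type": "Cell Type",
    "Tissue": "Tissue Type",
    # Table-driven mapping has no explicit row for Factor Name; it is the
    # factor/target annotation so it feeds the Target attribute.
    "Target": "Factor Name",
}

_ENCODE_DIRECT_MAP = {
    "Technique": "Assay Name",
    "Technique Type": "Assay Type",
    "Target": "Target of Assay",
    "Species": "Organism",
    "Life stage": "Life stage",
    "Age": "Age",
    "Age units": "Age units",
    "Sex": "Sex",
    "Ethnicity": "Ethnicity",
    "Disease": "Health status",
    "Classification": "Classification",
    "Feature": "Investigated as",
}


def new_unified_record() -> dict[str, str | None]:
    """All-null record over the unified 15-attribute schema."""
    return {name: None for name in ATTRIBUTE_NAMES}


def _get(attrs: dict[str, str], key: str) -> str | None:
    value = attrs.get(key)
    if value is None:
        return None
    value = str(value).strip()
    return value or None


def map_cistrome(record: SourceRecord) -> dict[str, str | None]:
    """Map a Cistrome annotation row onto the unified schema.

    Attributes are mapped independently; a missing source attribute leaves
    the corresponding unified attribute null.
    """
    if record.source != "cistrome":
        raise SchemaError("map_cistrome requires a cistrome record")
    out = new_unified_record()
    for unified, source_attr in _CISTROME_MAP.items():
        out[unified] = _get(record.attrs, source_attr)
    return out


def map_encode(record: SourceRecord) -> dict[str, str | None]:
    """Map an ENCODE annotation row onto the unified schema.

    ``Classification`` decides how ``Biosample term name`` is interpreted:
    "cell line" routes it to Cell Line, "tissue" routes it to Tissue; Cell
    Type is always null for ENCODE records.  Everything else maps directly.
    """
    if record.source != "encode":
        raise SchemaError("map_encode requires an encode record")
    out = new_unified_record()
    for unified, source_attr in _ENCODE_DIRECT_MAP.items():
        out[unified] = _get(record.attrs, source_attr)
    classification = _get(record.attrs, "Classification")
    term = _get(record.attrs, "Biosample term name")
    norm = classification.lower() if classification else None
    if norm == "cell line":
        out["Cell Line"] = term
    elif norm == "tissue":
        out["Tissue"] = term
    elif classification is not None:
        warnings.warn(
            f"unknown Classification value {classification!r}; "
            "leaving Cell Line and Tissue null",
            stacklevel=2,
        )
    out["Cell Type"] = None
    return out


def map_source(record: SourceRecord) -> dict[str, str | None]:
    return map_cistrome(record) if record.source == "cistrome" else map_encode(record)


def build_fallback_text(record: SourceRecord) -> RawSampleRecord:
    """Construct sample text for ENCODE experiments without a GSM identifier.

    The ``characteristics`` and ``description`` fields are filled with the
    space-separated concatenation of the ENCODE free-text attributes
    Description, Biosample summary and replicates.library.biosample.description
    (missing components are skipped).
    """
    if record.source != "encode":
        raise SchemaError("fallback text is defined for encode records only")
    parts = [
        _get(record.attrs, key)
        for key in ("Description", "Biosample summary", ENCODE_EXTRA_TEXT_ATTRIBUTE)
    ]
    text = " ".join(p for p in parts if p)
    sample_id = record.gsm or "encode-sample"
    return RawSampleRecord(
        sample_id=sample_id,
        fields={"characteristics": text, "description": text},
    )


@dataclass(frozen=True)
class TrainingExample:
    """(linearized input text, task keyword, target value) fine-tuning triple."""

    input_text: str
    task: str  # attribute name, lowercased, with trailing ':'
    target: str

    def __post_init__(self) -> None:
        if not self.task.endswith(":"):
            raise ValueError("task must end with ':'")
        name = self.task[:-1]
        if name not in {a.lower() for a in ATTRIBUTE_NAMES}:
            raise SchemaError(f"task {name!r} is not a schema attribute")
        if not self.target:
            raise ValueError("target must be non-empty")


def split_into_training_examples(
    unified: dict[str, str | None], input_text: str | LinearizedText
) -> list[TrainingExample]:
    """One training example per non-null attribute, sharing the input text.

    Tasks and targets are lowercased, consistent with text preprocessing.
    """
    if isinstance(input_text, LinearizedText):
        input_text = input_text.text
    examples = []
    for name in ATTRIBUTE_NAMES:
        value = unified.get(name)
        if value:
            examples.append(
                TrainingExample(
                    input_text=input_text,
                    task=name.lower() + ":",
                    target=str(value).lower(),
                )
            )
    return examples


def format_training_string(ex: TrainingExample) -> str:
    """Render a training example with the literal special keywords."""
    return f"{BOS} {ex.input_text} {SEP} {ex.task} {ex.target} {EOS}"


def parse_training_string(s: str) -> TrainingExample:
    """Inverse of :func:`format_training_string`."""
    if not s.startswith(BOS) or not s.rstrip().endswith(EOS):
        raise ValueError("training string lacks <BOS>/<EOS> delimiters")
    body = s[len(BOS):].rsplit(EOS, 1)[0]
    input_part, sep, tail = body.partition(f" {SEP} ")
    if not sep:
        raise ValueError("training string lacks <SEP>")
    tail = tail.strip()
    # the task keyword is everything up to and including the first ':'
    colon = tail.index(":")
    task = tail[: colon + 1]
    target = tail[colon + 1:].strip()
    return TrainingExample(input_text=input_part.strip(), task=task, target=target)


def merge_datasets(*example_lists: Sequence[TrainingExample]) -> list[TrainingExample]:
    """Concatenate example sets from heterogeneous sources (no deduplication)."""
    merged: list[TrainingExample] = []
    for lst in example_lists:
        merged.extend(lst)
    return merged


# ---------------------------------------------------------------------------
# table and JSON-lines I/O

def read_source_table(path: str | Path, source: str, sep: str | None = None) -> list[SourceRecord]:
    """Read a Cistrome/ENCODE annotation table (CSV or TSV with header)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    declared = (
        set(CISTROME_ATTRIBUTES)
        if source == "cistrome"
        else set(ENCODE_ATTRIBUTES) | {ENCODE_EXTRA_TEXT_ATTRIBUTE}
    )
    records = []
    for _, row in df.iterrows():
        attrs = {k: v for k, v in row.items() if k in declared and str(v).strip()}
        gsm = str(row.get("GSM", "")).strip() or None
        records.append(SourceRecord(source=source, attrs=attrs, gsm=gsm))
    return records


def write_examples_jsonl(examples: Iterable[TrainingExample], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ex in examples:
            fh.write(json.dumps(ex.__dict__) + "\n")


def read_examples_jsonl(path: str | Path) -> list[TrainingExample]:
    examples = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                examples.append(TrainingExample(**json.loads(line)))
    return examples
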