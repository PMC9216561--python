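"""Reading and linearizing GEO-style sample metadata.

A GEO Sample (GSM) is a bag of named free-text fields, optionally with a
nested ``characteristics`` key/value block.  Two on-disk dialects are
supported:

* **SOFT-lite** — a minimal key/value subset of NCBI's SOFT exchange format:
  a ``^SAMPLE = GSMxxx`` header followed by ``!Sample_<key> = <value>``
  lines; repeated ``!Sample_characteristics_ch1 = k: v`` lines populate the
  characteristics map.  Underscores in keys become spaces and a trailing
  ``_ch1`` channel suffix is dropped, so ``!Sample_source_name_ch1``
  becomes the field ``source name``.
* **JSON** — mirrors :class:`RawSampleRecord` one-to-one.

For the language model the record is *linearized* into a single string in
which every field name is enclosed in square brackets::

    [gsm]: gsm1565792 [title]: DC_MTB_H3K9me3_rep1 (ChIP-Seq) ...

and then *preprocessed*: lowercased, special characters (default ``*`` and
``_``) replaced by spaces, words longer than 30 characters removed, and the
token sequence truncated to the first 400 tokens.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator


class ParseError(ValueError):
    """Malformed sample stream; the message names the offending line."""


@dataclass
class RawSampleRecord:
    """One GEO sample: identifiers plus an ordered field map."""

    sample_id: str
    series_id: str | None = None
    fields: dict[str, str] = field(default_factory=dict)
    characteristics: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "series_id": self.series_id,
            "fields": dict(self.fields),
            "characteristics": dict(self.characteristics),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RawSampleRecord":
        return cls(
            sample_id=d.get("sample_id", ""),
            series_id=d.get("series_id"),
            fields=dict(d.get("fields", {})),
            characteristics=dict(d.get("characteristics", {})),
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Text clean-up applied between linearization and tokenization."""

    lowercase: bool = True
    strip_chars: frozenset[str] = frozenset({"*", "_"})
    max_word_chars: int = 30
    max_tokens: int = 400

    def __post_init__(self) -> None:
        if self.max_word_chars < 1:
            raise ValueError("max_word_chars must be >= 1")
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be >= 1")


@dataclass(frozen=True)
class LinearizedText:
    """Plain-text rendering of a sample plus its token count."""

    text: str
    token_count: int


def _coerce_stream(stream: str | IO[str]) -> Iterator[str]:
    if isinstance(stream, str):
        return iter(io.StringIO(stream))
    return iter(stream)


def _field_name_from_soft_key(key: str) -> str:
    if key.endswith("_ch1"):
        key = key[: -len("_ch1")]
    return key.replace("_", " ")


def _soft_key_from_field_name(name: str) -> str:
    return name.replace(" ", "_")


def parse_sample(stream: str | IO[str], dialect: str = "soft-lite") -> RawSampleRecord:
    """Parse one sample from ``stream`` in the named dialect.

    Field order is preserved as found in the source; nested characteristics
    sub-pairs are kept in their own ordered map.
    """
    if dialect == "json":
        text = stream if isinstance(stream, str) else stream.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed JSON sample: {exc}") from exc
        if not data.get("sample_id"):
            raise ParseError("sample record is missing its sample identifier")
        return RawSampleRecord.from_dict(data)
    if dialect != "soft-lite":
        raise ValueError(f"unknown dialect: {dialect!r}")

    sample_id = ""
    series_id: str | None = None
    fields: dict[str, str] = {}
    characteristics: dict[str, str] = {}
    for lineno, raw in enumerate(_coerce_stream(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("^SAMPLE"):
            _, _, value = line.partition("=")
            sample_id = value.strip()
            continue
        if not line.startswith("!Sample_"):
            raise ParseError(f"line {lineno}: unrecognized line {line!r}")
        body = line[len("!Sample_"):]
        key, sep, value = body.partition(" = ")
        if not sep:
            raise ParseError(f"line {lineno}: expected 'key = value' in {line!r}")
        value = value.strip()
        if key == "geo_accession":
            sample_id = value
        elif key == "series_id":
            series_id = value
        elif key.startswith("characteristics"):
            sub_key, csep, sub_value = value.partition(":")
            if not csep:
                raise ParseError(
                    f"line {lineno}: characteristics entry lacks 'key: value' form"
                )
            characteristics[sub_key.strip()] = sub_value.strip()
            fields.setdefault("characteristics", "")
        else:
            name = _field_name_from_soft_key(key)
            if name in fields:
                raise ParseError(f"line {lineno}: duplicate field {name!r}")
            fields[name] = value
    if not sample_id:
        raise ParseError("sample record is missing its sample identifier")
    return RawSampleRecord(
        sample_id=sample_id,
        series_id=series_id,
        fields=fields,
        characteristics=characteristics,
    )


def serialize_sample(record: RawSampleRecord, dialect: str = "soft-lite") -> str:
    """Inverse of :func:`parse_sample` for round-tripping records to disk."""
    if dialect == "json":
        return json.dumps(record.to_dict())
    if dialect != "soft-lite":
        raise ValueError(f"unknown dialect: {dialect!r}")
    lines = [f"^SAMPLE = {record.sample_id}"]
    if record.series_id:
        lines.append(f"!Sample_series_id = {record.series_id}")
    for name, value in record.fields.items():
        if name == "characteristics":
            continue
        lines.append(f"!Sample_{_soft_key_from_field_name(name)} = {value}")
    for k, v in record.characteristics.items():
        lines.append(f"!Sample_characteristics_ch1 = {k}: {v}")
    return "\n".join(lines) + "\n"


def render_characteristics(characteristics: dict[str, str]) -> str:
    """Render nested sub-pairs as ``'key: value key2: value2'`` text."""
    return " ".join(f"{k}: {v}" for k, v in characteristics.items())


def linearize(record: RawSampleRecord) -> LinearizedText:
    """Concatenate fields, in record order, as ``[field-name]: value`` text.

    Field values are kept verbatim; this runs *before* preprocessing.  The
    nested characteristics map is rendered inline inside the value of the
    ``characteristics`` field.  Token count is word count at this stage.
    """
    parts: list[str] = []
    for name, value in record.fields.items():
        if name == "characteristics":
            rendered = render_characteristics(record.characteristics)
            value = f"{value} {rendered}".strip() if value else rendered
        parts.append(f"[{name}]: {value}".rstrip())
    text = " ".join(parts)
    return LinearizedText(text=text, token_count=len(text.split()))


def preprocess(
    text: str | LinearizedText,
    config: PreprocessConfig = PreprocessConfig(),
    tokenizer=None,
) -> LinearizedText:
    """Apply the standard clean-up rules to linearized text.

    Lowercase, replace each stripped character by a space (so fused tokens
    like ``dc_mtb`` become separable words), collapse whitespace, drop any
    word longer than ``max_word_chars`` characters, and keep only the first
    ``max_tokens`` tokens.  With the default word-level tokenization one
    word is one token; a ``tokenizer`` with an ``encode`` method may be
    supplied to count sub-word tokens instead.  Idempotent.
    """
    if isinstance(text, LinearizedText):
        text = text.text
    if config.lowercase:
        text = text.lower()
    if config.strip_chars:
        table = {ord(c): " " for c in config.strip_chars}
        text = text.translate(table)
    words = [w for w in text.split() if len(w) <= config.max_word_chars]
    if tokenizer is not None:
        kept: list[str] = []
        total = 0
        for w in words:
            n = len(tokenizer.encode(w, add_special=False))
            if total + n > config.max_tokens:
                break
            kept.append(w)
            total += n
        return LinearizedText(text=" ".join(kept), token_count=total)
    words = words[: config.max_tokens]
    return LinearizedText(text=" ".join(words), token_count=len(words))


def read_samples(stream: str | IO[str], dialect: str = "soft-lite") -> list[RawSampleRecord]:
    """Read multiple samples: SOFT-lite blocks split on ``^SAMPLE`` headers,
    or a JSON-lines stream with one record per line."""
    text = stream if isinstance(stream, str) else stream.read()
    records: list[RawSampleRecord] = []
    if dialect == "json":
        for line in text.splitlines():
            if line.strip():
                records.append(parse_sample(line, dialect="json"))
        return records
    block: list[str] = []
    for line in text.splitlines():
        if line.startswith("^SAMPLE") and block:
            records.append(parse_sample("\n".join(block), dialect="soft-lite"))
            block = []
        if line.strip():
            block.append(line)
    if block:
        records.append(parse_sample("\n".join(block), dialect="soft-lite"))
    return records


def write_samples(
    records: Iterable[RawSampleRecord], dialect: str = "soft-lite"
) -> str:
    if dialect == "json":
        return "\n".join(serialize_sample(r, "json") for r in records) + "\n"
    return "".join(serialize_sample(r, "soft-lite") for r in records)
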