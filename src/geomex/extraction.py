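"""Task-conditioned attribute extraction and confidence scoring.

Each of the 15 schema attributes is extracted independently by prompting
the model with::

    <BOS> {preprocessed sample text} <SEP> {attribute name}:

and greedily decoding until <EOS>.  An empty generation is reported as the
value ``"unknown"``, with confidence equal to the probability the model
assigned to the immediate <EOS> (its commitment to "nothing to extract").

Confidence of a non-empty generation combines the per-token conditional
probabilities with one of three strategies: the product over all tokens,
the minimum over all tokens, or the probability of the first token.  The
first-token option is the default: the product and the minimum produce too
many low values even for correct predictions, whereas the first token is
better calibrated with correctness.  Confidences map to a traffic light:
green above 0.8, red below 0.6, yellow in between (boundaries inclusive
into yellow).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .model.adapters import GenerationTrace, ModelAdapter, generate
from .records import LinearizedText, PreprocessConfig, RawSampleRecord, linearize, preprocess
from .schema import DEFAULT_SCHEMA, AttributeSchema
from .sources import BOS, SEP

UNKNOWN_VALUE = "unknown"
STRATEGIES = ("product", "min", "first")


class SchemaError(KeyError):
    pass


@dataclass(frozen=True)
class Thresholds:
    """Traffic-light cut points on the confidence scale."""

    green: float = 0.8
    yellow: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 <= self.yellow < self.green <= 1.0):
            raise ValueError("need 0 <= yellow < green <= 1")


def confidence(trace: GenerationTrace, strategy: str = "first") -> float:
    """Collapse per-token probabilities into one confidence value.

    Empty generations fall back to the recorded <EOS> probability (or 0.0
    if the generation was cut off before committing to anything).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not trace.probs:
        return float(trace.stop_prob) if trace.stop_prob is not None else 0.0
    if strategy == "product":
        return float(math.prod(trace.probs))
    if strategy == "min":
        return float(min(trace.probs))
    return float(trace.probs[0])


def classify_confidence(conf: float, thresholds: Thresholds = Thresholds()) -> str:
    """green iff conf > green threshold; red iff conf < yellow threshold."""
    if not (0.0 <= conf <= 1.0):
        raise ValueError(f"confidence {conf} outside [0, 1]")
    if conf > thresholds.green:
        return "green"
    if conf < thresholds.yellow:
        return "red"
    return "yellow"


@dataclass
class Prediction:
    """One extracted attribute value with its confidence evidence."""

    attribute: str
    value: str
    trace: GenerationTrace
    confidence: float
    strategy: str = "first"
    traffic_light: str = "red"
    approved: bool = False
    error: str | None = None

    @property
    def effective_light(self) -> str:
        """Display colour: user approval forces green."""
        return "green" if self.approved else self.traffic_light

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "value": self.value,
            "tokens": list(self.trace.tokens),
            "token_probs": list(self.trace.probs),
            "stop_prob": self.trace.stop_prob,
            "confidence": self.confidence,
            "strategy": self.strategy,
            "traffic_light": self.traffic_light,
            "approved": self.approved,
            "error": self.error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Prediction":
        return cls(
            attribute=d["attribute"],
            value=d["value"],
            trace=GenerationTrace(
                tokens=tuple(d.get("tokens", ())),
                probs=tuple(d.get("token_probs", ())),
                stop_prob=d.get("stop_prob"),
            ),
            confidence=d["confidence"],
            strategy=d.get("strategy", "first"),
            traffic_light=d.get("traffic_light", "red"),
            approved=d.get("approved", False),
            error=d.get("error"),
        )


@dataclass
class ExtractionResult:
    """Structured table row for one sample: one prediction per attribute."""

    sample_id: str
    series_id: str | None
    input_text: str
    predictions: dict[str, Prediction] = field(default_factory=dict)

    def non_green_count(self) -> int:
        return sum(1 for p in self.predictions.values() if p.effective_light != "green")

    def count_light(self, light: str) -> int:
        return sum(1 for p in self.predictions.values() if p.effective_light == light)

    def all_approved(self) -> bool:
        return all(p.approved for p in self.predictions.values())

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "series_id": self.series_id,
            "input_text": self.input_text,
            "predictions": {k: p.to_dict() for k, p in self.predictions.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionResult":
        return cls(
            sample_id=d["sample_id"],
            series_id=d.get("series_id"),
            input_text=d.get("input_text", ""),
            predictions={
                k: Prediction.from_dict(v) for k, v in d.get("predictions", {}).items()
            },
        )


def build_prompt(input_text: str, attribute: str, schema: AttributeSchema = DEFAULT_SCHEMA) -> str:
    if attribute not in schema:
        raise SchemaError(attribute)
    return f"{BOS} {input_text} {SEP} {schema.task_keyword(attribute)}"


def extract_attribute(
    adapter: ModelAdapter,
    input_text: str | LinearizedText,
    attribute: str,
    schema: AttributeSchema = DEFAULT_SCHEMA,
    strategy: str = "first",
    thresholds: Thresholds = Thresholds(),
    max_new_tokens: int = 8,
) -> Prediction:
    """Extract one attribute from preprocessed sample text.

    Stateless with respect to other attributes: extracting attribute A
    before or after attribute B yields identical results.
    """
    if isinstance(input_text, LinearizedText):
        input_text = input_text.text
    prompt = build_prompt(input_text, attribute, schema)
    trace = generate(adapter, prompt, max_new_tokens=max_new_tokens)
    value = " ".join(trace.tokens) if trace.tokens else UNKNOWN_VALUE
    conf = confidence(trace, strategy)
    return Prediction(
        attribute=attribute,
        value=value,
        trace=trace,
        confidence=conf,
        strategy=strategy,
        traffic_light=classify_confidence(conf, thresholds),
    )


def extract_all(
    adapter: ModelAdapter,
    record: RawSampleRecord,
    schema: AttributeSchema = DEFAULT_SCHEMA,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    strategy: str = "first",
    thresholds: Thresholds = Thresholds(),
) -> ExtractionResult:
    """Linearize, preprocess and extract every schema attribute.

    A failure on one attribute is recorded on its prediction (value
    ``unknown``, confidence 0) without aborting the remaining attributes.
    """
    text = preprocess(linearize(record), preprocess_config, tokenizer=None)
    result = ExtractionResult(
        sample_id=record.sample_id, series_id=record.series_id, input_text=text.text
    )
    for attribute in schema.names:
        try:
            pred = extract_attribute(
                adapter, text.text, attribute, schema, strategy, thresholds
            )
        except Exception as exc:  # per-attribute containment
            pred = Prediction(
                attribute=attribute,
                value=UNKNOWN_VALUE,
                trace=GenerationTrace((), ()),
                confidence=0.0,
                strategy=strategy,
                traffic_light="red",
                error=str(exc),
            )
        result.predictions[attribute] = pred
    return result


# ---------------------------------------------------------------------------
# serialization

def results_to_json(results: Iterable[ExtractionResult]) -> str:
    return json.dumps([r.to_dict() for r in results], indent=2)


def results_from_json(text: str) -> list[ExtractionResult]:
    return [ExtractionResult.from_dict(d) for d in json.loads(text)]


def results_to_frame(
    results: Iterable[ExtractionResult],
    schema: AttributeSchema = DEFAULT_SCHEMA,
    include_confidence: bool = False,
) -> pd.DataFrame:
    """One row per sample: gsm, gse, then the 15 attribute columns."""
    rows = []
    for r in results:
        row: dict[str, object] = {"gsm": r.sample_id, "gse": r.series_id or ""}
        for name in schema.names:
            pred = r.predictions.get(name)
            row[name] = pred.value if pred else ""
            if include_confidence:
                row[f"{name} confidence"] = pred.confidence if pred else ""
        rows.append(row)
    columns = ["gsm", "gse"]
    for name in schema.names:
        columns.append(name)
        if include_confidence:
            columns.append(f"{name} confidence")
    return pd.DataFrame(rows, columns=columns)
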