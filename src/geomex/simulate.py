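"""Synthetic GEO-like sample corpora with known ground truth.

The generator emulates the metadata of functional-genomics samples the way
they appear on GEO: a title, source name, organism, a characteristics block
and a short description, populated from per-attribute vocabularies via
templates that imitate the typical field inventory (gsm, title, sample
type, source name, organism, characteristics, description).

Three kinds of ground-truth evidence are produced:

* **explicit** — the attribute value appears verbatim in the text;
* **synonymous** — the text carries a synonym (e.g. "human" for
  "homo sapiens") while the truth keeps the canonical value;
* **implicit** — the value is absent from the text but implied by a cue
  that is present, the way a cell line implies the donor's sex, tissue and
  disease (e.g. K562 implies haematopoietic and lymphoid tissue and
  leukemia, and a prostate biosample implies a male donor).

Each attribute that would be written to the characteristics block is
dropped with probability ``field_dropout_rate``; a dropped attribute stays
in the truth table only if a cue present in the rendered text implies that
exact attribute/value pair, and is then labelled implicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .records import (
    PreprocessConfig,
    RawSampleRecord,
    linearize,
    preprocess,
    serialize_sample,
)
from .sources import TrainingExample, format_training_string

# --------------------------------------------------------------------- vocab

#: Donor/biosample profiles of widely used, documented cell lines.
DEFAULT_CELL_LINES: dict[str, dict[str, str]] = {
    "k562": {
        "Cell Type": "erythroblast",
        "Tissue": "haematopoietic and lymphoid tissue",
        "Disease": "leukemia",
        "Sex": "female",
        "Age": "53",
        "Age units": "year",
        "Life stage": "adult",
    },
    "hela-s3": {
        "Cell Type": "epithelium",
        "Tissue": "cervix",
        "Disease": "cervical adenocarcinoma",
        "Sex": "female",
        "Age": "31",
        "Age units": "year",
        "Life stage": "adult",
        "Ethnicity": "black",
    },
    "lncap": {
        "Cell Type": "epithelium",
        "Tissue": "prostate",
        "Disease": "prostate carcinoma",
        "Sex": "male",
        "Age": "50",
        "Age units": "year",
        "Life stage": "adult",
        "Ethnicity": "caucasian",
    },
    "mcf-7": {
        "Cell Type": "epithelium",
        "Tissue": "breast",
        "Disease": "breast cancer",
        "Sex": "female",
        "Age": "69",
        "Age units": "year",
        "Life stage": "adult",
        "Ethnicity": "caucasian",
    },
    "gm12878": {
        "Cell Type": "b lymphocyte",
        "Tissue": "blood",
        "Disease": "healthy",
        "Sex": "female",
        "Life stage": "adult",
        "Ethnicity": "caucasian",
    },
    "hepg2": {
        "Cell Type": "hepatocyte",
        "Tissue": "liver",
        "Disease": "hepatocellular carcinoma",
        "Sex": "male",
        "Age": "15",
        "Age units": "year",
        "Life stage": "child",
        "Ethnicity": "caucasian",
    },
    "a549": {
        "Cell Type": "epithelium",
        "Tissue": "lung",
        "Disease": "lung carcinoma",
        "Sex": "male",
        "Age": "58",
        "Age units": "year",
        "Life stage": "adult",
        "Ethnicity": "caucasian",
    },
    "imr-90": {
        "Cell Type": "fibroblast",
        "Tissue": "lung",
        "Disease": "healthy",
        "Sex": "female",
        "Age": "16",
        "Age units": "week",
        "Life stage": "embryonic",
    },
    "hct116": {
        "Cell Type": "epithelium",
        "Tissue": "colon",
        "Disease": "colorectal carcinoma",
        "Sex": "male",
        "Age": "48",
        "Age units": "year",
        "Life stage": "adult",
    },
}

#: Profiles held out of the defaults, handy for studying how the online
#: loop adapts to sample families the base model has never seen.
EXTRA_CELL_LINES: dict[str, dict[str, str]] = {
    "jurkat": {
        "Cell Type": "t lymphocyte",
        "Tissue": "blood",
        "Disease": "leukemia",
        "Sex": "male",
        "Age": "14",
        "Age units": "year",
        "Life stage": "child",
    },
}

DEFAULT_TISSUES: tuple[str, ...] = (
    "liver",
    "lung",
    "brain",
    "heart",
    "kidney",
    "spleen",
    "prostate",
    "breast",
    "colon",
    "skin",
)

#: (technique, technique type, takes a molecular target)
DEFAULT_ASSAYS: tuple[tuple[str, str, bool], ...] = (
    ("chip-seq", "dna binding", True),
    ("rna-seq", "transcription profiling", False),
    ("atac-seq", "dna accessibility", False),
    ("dnase-seq", "dna accessibility", False),
    ("wgbs", "dna methylation", False),
)

DEFAULT_TARGETS: tuple[str, ...] = (
    "ctcf",
    "polr2a",
    "myc",
    "ep300",
    "h3k4me1",
    "h3k4me3",
    "h3k27ac",
    "h3k27me3",
    "h3k36me3",
    "h3k9me3",
)

_HISTONE_PREFIXES = ("h3k", "h4k", "h2a", "h2b")

SYNONYMS: dict[str, tuple[str, ...]] = {
    "homo sapiens": ("human",),
    "mus musculus": ("mouse",),
    "chip-seq": ("chromatin immunoprecipitation sequencing",),
    "rna-seq": ("rna sequencing",),
    "blood": ("peripheral blood",),
    "healthy": ("normal",),
}


def default_cue_table(
    cell_lines: dict[str, dict[str, str]] | None = None
) -> dict[str, dict[str, str]]:
    """Cue term -> implied attribute/value pairs.

    Every cell line name implies its full donor profile plus the
    cell-line classification; every tissue name implies the tissue
    classification; biologically documented pattern cues (prostate ->
    male donor) are added on top.  Every assay name implies its class.
    """
    cell_lines = cell_lines if cell_lines is not None else DEFAULT_CELL_LINES
    cues: dict[str, dict[str, str]] = {}
    for name, profile in cell_lines.items():
        implied = dict(profile)
        implied["Cell Line"] = name
        implied["Classification"] = "cell line"
        implied["Species"] = "homo sapiens"
        cues[name] = implied
    for tissue in DEFAULT_TISSUES:
        cues.setdefault(tissue, {})
        cues[tissue].setdefault("Classification", "tissue")
    cues["prostate"]["Sex"] = "male"
    for technique, ttype, _ in DEFAULT_ASSAYS:
        cues.setdefault(technique, {})
        cues[technique]["Technique Type"] = ttype
    return cues


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus."""

    n_samples: int = 100
    seed: int = 0
    field_dropout_rate: float = 0.2
    synonym_rate: float = 0.2
    cell_line_fraction: float = 0.5
    mouse_fraction: float = 0.2  # of tissue-kind samples
    cell_lines: dict[str, dict[str, str]] = dc_field(
        default_factory=lambda: dict(DEFAULT_CELL_LINES)
    )
    cell_line_weights: dict[str, float] | None = None
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    assays: tuple[tuple[str, str, bool], ...] = DEFAULT_ASSAYS
    targets: tuple[str, ...] = DEFAULT_TARGETS
    implicit_cue_table: dict[str, dict[str, str]] | None = None
    gsm_offset: int = 1_000_000
    series_size: int = 4

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be nonnegative")
        for rate in (self.field_dropout_rate, self.synonym_rate, self.cell_line_fraction):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")

    def cues(self) -> dict[str, dict[str, str]]:
        if self.implicit_cue_table is not None:
            return self.implicit_cue_table
        return default_cue_table(self.cell_lines)


@dataclass
class LabeledSample:
    """A synthetic record plus its ground-truth attribute table.

    ``provenance[attr]`` says whether the truth value is stated in the
    text ("explicit", possibly as a synonym) or implied by a cue
    ("implicit").
    """

    record: RawSampleRecord
    truth: dict[str, str]
    provenance: dict[str, str] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "record": self.record.to_dict(),
            "truth": dict(self.truth),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabeledSample":
        return cls(
            record=RawSampleRecord.from_dict(d["record"]),
            truth=dict(d["truth"]),
            provenance=dict(d.get("provenance", {})),
        )


# characteristics sub-key used to render each attribute explicitly
_CHAR_KEYS: tuple[tuple[str, str], ...] = (
    ("Cell Line", "cell line"),
    ("Cell Type", "cell type"),
    ("Tissue", "tissue"),
    ("Disease", "disease"),
    ("Sex", "sex"),
    ("Age", "age"),
    ("Age units", "age units"),
    ("Life stage", "life stage"),
    ("Ethnicity", "ethnicity"),
    ("Classification", "classification"),
    ("Target", "chip antibody"),
    ("Technique Type", "assay type"),
    ("Feature", "investigated as"),
)

_ETHNICITIES = ("caucasian", "black", "asian", "hispanic")
_LIFE_STAGES = ("adult", "child", "embryonic")
_TISSUE_DISEASES = ("healthy", "carcinoma", "adenocarcinoma")


def _feature_for(target: str) -> str:
    return "histone" if target.startswith(_HISTONE_PREFIXES) else "transcription factor"


def _choice(rng: np.random.Generator, items, weights=None):
    items = list(items)
    if weights is not None:
        p = np.asarray([weights.get(i, 1.0) for i in items], dtype=float)
        p = p / p.sum()
        return items[rng.choice(len(items), p=p)]
    return items[rng.integers(len(items))]


def _build_truth(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, str]:
    technique, ttype, has_target = _choice(rng, config.assays)
    truth: dict[str, str] = {"Technique": technique, "Technique Type": ttype}
    if has_target:
        target = _choice(rng, config.targets)
        truth["Target"] = target
        truth["Feature"] = _feature_for(target)
    if rng.random() < config.cell_line_fraction:
        name = _choice(rng, sorted(config.cell_lines), config.cell_line_weights)
        truth.update(config.cell_lines[name])
        truth["Cell Line"] = name
        truth["Classification"] = "cell line"
        truth["Species"] = "homo sapiens"
    else:
        tissue = _choice(rng, config.tissues)
        truth["Tissue"] = tissue
        truth["Classification"] = "tissue"
        truth["Species"] = (
            "mus musculus" if rng.random() < config.mouse_fraction else "homo sapiens"
        )
        truth["Sex"] = "male" if tissue == "prostate" else _choice(rng, ("male", "female"))
        truth["Age"] = str(int(rng.integers(1, 90)))
        truth["Age units"] = "year"
        truth["Life stage"] = _choice(rng, _LIFE_STAGES)
        if rng.random() < 0.5:
            truth["Ethnicity"] = _choice(rng, _ETHNICITIES)
        truth["Disease"] = _choice(rng, _TISSUE_DISEASES)
    return truth


def _surface_form(value: str, rng: np.random.Generator, synonym_rate: float) -> str:
    options = SYNONYMS.get(value)
    if options and rng.random() < synonym_rate:
        return options[rng.integers(len(options))]
    return value


def generate_sample(
    config: GeneratorConfig, rng: np.random.Generator, index: int
) -> LabeledSample:
    truth = _build_truth(config, rng)
    cues = config.cues()
    anchor = truth.get("Cell Line") or truth["Tissue"]
    technique = truth["Technique"]

    # anchor, technique and (if any) target are always stated in the text
    always_explicit = {"Technique"}
    always_explicit.add("Cell Line" if "Cell Line" in truth else "Tissue")
    if "Target" in truth:
        always_explicit.add("Target")

    rendered: dict[str, str] = {}
    for attr in truth:
        if attr in always_explicit or rng.random() >= config.field_dropout_rate:
            rendered[attr] = _surface_form(truth[attr], rng, config.synonym_rate)

    title_bits = [anchor]
    if "Target" in rendered:
        title_bits.append(rendered["Target"])
    title_bits.append(rendered.get("Technique", technique))
    title_bits.append(f"rep{int(rng.integers(1, 4))}")

    fields: dict[str, str] = {
        "gsm": f"gsm{config.gsm_offset + index}",
        "title": " ".join(title_bits),
        "sample type": "sra",
        "source name": (
            f"{anchor} cells" if "Cell Line" in truth else f"{anchor} tissue"
        ),
    }
    if "Species" in rendered:
        fields["organism"] = rendered["Species"]
    characteristics: dict[str, str] = {}
    for attr, key in _CHAR_KEYS:
        if attr in rendered and attr not in ("Technique",):
            characteristics[key] = rendered[attr]
    if characteristics:
        fields["characteristics"] = ""
    fields["description"] = f"{anchor} {rendered.get('Technique', technique)} experiment"

    record = RawSampleRecord(
        sample_id=fields["gsm"],
        series_id=f"gse{config.gsm_offset // 100 + index // config.series_size}",
        fields=fields,
        characteristics=characteristics,
    )

    # dropped attributes survive in the truth only when a cue in the text
    # implies that exact attribute/value pair
    text = linearize(record).text.lower()
    words = set(text.split())
    final_truth: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for attr, value in truth.items():
        if attr in rendered:
            final_truth[attr] = value
            provenance[attr] = "explicit"
            continue
        for cue, implied in cues.items():
            present = cue in words or (" " in cue and cue in text)
            if present and implied.get(attr) == value:
                final_truth[attr] = value
                provenance[attr] = "implicit"
                break
    return LabeledSample(record=record, truth=final_truth, provenance=provenance)


def generate_corpus(config: GeneratorConfig) -> list[LabeledSample]:
    """Deterministic (seeded) corpus of labelled GEO-like samples."""
    rng = np.random.default_rng(config.seed)
    return [generate_sample(config, rng, i) for i in range(config.n_samples)]


def split_corpus(
    corpus: list[LabeledSample], train_fraction: float, seed: int = 0
) -> tuple[list[LabeledSample], list[LabeledSample]]:
    """Disjoint, exhaustive, seeded train/test split."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_train = int(round(train_fraction * len(corpus)))
    train = [corpus[i] for i in sorted(order[:n_train])]
    test = [corpus[i] for i in sorted(order[n_train:])]
    return train, test


def sample_to_examples(
    sample: LabeledSample, config: PreprocessConfig = PreprocessConfig()
) -> list[TrainingExample]:
    """Per-attribute training examples for one labelled sample."""
    text = preprocess(linearize(sample.record), config)
    return [
        TrainingExample(input_text=text.text, task=attr.lower() + ":", target=value.lower())
        for attr, value in sample.truth.items()
    ]


def corpus_to_training_strings(
    corpus: list[LabeledSample],
    config: PreprocessConfig = PreprocessConfig(),
    unknown_per_sample: int = 3,
    seed: int = 0,
) -> list[str]:
    """Formatted training strings for a corpus.

    Besides one example per ground-truth attribute, each sample
    contributes up to ``unknown_per_sample`` examples (seeded choice among
    its absent schema attributes) with the literal target ``unknown``.
    Teaching the model to abstain mirrors the annotation interface's
    "unknown" option and gives absent attributes a confident, stable
    answer instead of low-confidence noise.
    """
    from .schema import ATTRIBUTE_NAMES

    rng = np.random.default_rng(seed)
    strings = []
    for sample in corpus:
        examples = sample_to_examples(sample, config)
        strings.extend(format_training_string(ex) for ex in examples)
        if unknown_per_sample > 0:
            absent = [a for a in ATTRIBUTE_NAMES if a not in sample.truth]
            k = min(unknown_per_sample, len(absent))
            if k and examples:
                chosen = rng.choice(len(absent), size=k, replace=False)
                input_text = examples[0].input_text
                for i in sorted(chosen):
                    ex = TrainingExample(
                        input_text=input_text,
                        task=absent[i].lower() + ":",
                        target="unknown",
                    )
                    strings.append(format_training_string(ex))
    return strings


# ---------------------------------------------------------------------- I/O

def write_corpus_jsonl(corpus: list[LabeledSample], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample in corpus:
            fh.write(json.dumps(sample.to_dict()) + "\n")


def read_corpus_jsonl(path: str | Path) -> list[LabeledSample]:
    corpus = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                corpus.append(LabeledSample.from_dict(json.loads(line)))
    return corpus


def write_corpus_soft(corpus: list[LabeledSample], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample in corpus:
            fh.write(serialize_sample(sample.record, "soft-lite"))
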