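"""The unified 15-attribute annotation schema.

GEO sample descriptions are free text; downstream integration needs a fixed
relational schema.  The schema used throughout this package unifies the
curated annotation vocabularies of two major resources: the Cistrome Data
Browser (four attributes: Cell Line, Cell Type, Tissue Type, Factor Name)
and the ENCODE portal (biosample- and assay-level attributes).  Each
attribute doubles as an extraction *task*: the language model is conditioned
on the attribute name and generates the value for one attribute at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AttributeDescriptor:
    """One output attribute: name plus the guidance shown to annotators."""

    name: str
    description: str = ""
    common_values: tuple[str, ...] = ()
    external_links: tuple[str, ...] = ()


#: The 15 unified output attributes, in canonical column order.
ATTRIBUTE_NAMES: tuple[str, ...] = (
    "Cell Line",
    "Cell Type",
    "Tissue",
    "Technique",
    "Technique Type",
    "Target",
    "Species",
    "Life stage",
    "Age",
    "Age units",
    "Sex",
    "Ethnicity",
    "Disease",
    "Classification",
    "Feature",
)

_DESCRIPTORS: tuple[AttributeDescriptor, ...] = (
    AttributeDescriptor(
        "Cell Line",
        "Immortalized cell line the sample derives from, if any.",
        ("k562", "hela-s3", "gm12878", "hepg2", "mcf-7"),
        ("https://www.atcc.org/search", "https://www.cellosaurus.org/"),
    ),
    AttributeDescriptor(
        "Cell Type",
        "Cell type of the biosample (e.g. erythroblast, fibroblast).",
        ("erythroblast", "epithelium", "fibroblast", "b lymphocyte"),
    ),
    AttributeDescriptor(
        "Tissue",
        "Tissue of origin of the biosample.",
        ("liver", "lung", "blood", "haematopoietic and lymphoid tissue"),
    ),
    AttributeDescriptor(
        "Technique",
        "Assay used to produce the sample (e.g. chip-seq, rna-seq).",
        ("chip-seq", "rna-seq", "atac-seq", "dnase-seq"),
    ),
    AttributeDescriptor(
        "Technique Type",
        "Broad class of the assay (e.g. dna binding, transcription profiling).",
        ("dna binding", "transcription profiling", "dna accessibility"),
    ),
    AttributeDescriptor(
        "Target",
        "Molecular target of the assay: a transcription factor or histone mark.",
        ("ctcf", "polr2a", "h3k4me3", "h3k27ac"),
    ),
    AttributeDescriptor(
        "Species",
        "Organism the sample derives from.",
        ("homo sapiens", "mus musculus"),
    ),
    AttributeDescriptor(
        "Life stage",
        "Life stage of the donor (adult, child, embryonic ...).",
        ("adult", "child", "embryonic"),
    ),
    AttributeDescriptor("Age", "Numeric age of the donor.", ("53", "31")),
    AttributeDescriptor("Age units", "Units of the donor age.", ("year", "week", "day")),
    AttributeDescriptor("Sex", "Sex of the donor.", ("male", "female")),
    AttributeDescriptor(
        "Ethnicity", "Ethnicity of the donor.", ("caucasian", "black", "asian")
    ),
    AttributeDescriptor(
        "Disease",
        "Health status or disease of the donor/biosample.",
        ("healthy", "leukemia", "breast cancer"),
    ),
    AttributeDescriptor(
        "Classification",
        "Whether the biosample is a cell line or a tissue.",
        ("cell line", "tissue"),
    ),
    AttributeDescriptor(
        "Feature",
        "What the assay target is investigated as (transcription factor, histone ...).",
        ("transcription factor", "histone", "control"),
    ),
)


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of the unified output attributes.

    Invariants: exactly 15 attributes with unique names.
    """

    attributes: tuple[AttributeDescriptor, ...] = field(default=_DESCRIPTORS)

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(names) != len(set(names)):
            raise ValueError("attribute names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def descriptor(self, name: str) -> AttributeDescriptor:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def task_keyword(self, name: str) -> str:
        """Textual task keyword conditioning the model, e.g. ``'cell line:'``."""
        if name not in self:
            raise KeyError(name)
        return name.lower() + ":"


#: Default schema instance used across the package.
DEFAULT_SCHEMA = AttributeSchema()

#: Attribute names of a Cistrome-style annotation record.
CISTROME_ATTRIBUTES: tuple[str, ...] = (
    "Cell Line",
    "Cell Type",
    "Tissue Type",
    "Factor Name",
)

#: Attribute names of an ENCODE-style annotation record (15 columns: the 13
#: distinct mapped annotation attributes plus two free-text summary fields).
ENCODE_ATTRIBUTES: tuple[str, ...] = (
    "Classification",
    "Biosample term name",
    "Assay Name",
    "Assay Type",
    "Target of Assay",
    "Organism",
    "Life stage",
    "Age",
    "Age units",
    "Sex",
    "Ethnicity",
    "Health status",
    "Investigated as",
    "Description",
    "Biosample summary",
)

#: Extra ENCODE free-text column recognized for fallback-text construction.
ENCODE_EXTRA_TEXT_ATTRIBUTE = "replicates.library.biosample.description"
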