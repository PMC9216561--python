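"""Map Cistrome- and ENCODE-style annotations onto the unified 15-attribute
schema and split them into per-attribute training examples.

Each annotated sample becomes as many training examples as it has non-null
attributes; all share the input text and differ only in the task keyword.
"""

from geomex import (
    SourceRecord,
    format_training_string,
    map_cistrome,
    map_encode,
    merge_datasets,
    split_into_training_examples,
)

cistrome = SourceRecord(
    source="cistrome",
    attrs={
        "Cell Line": "k562",
        "Cell Type": "erythroblast",
        "Tissue Type": "blood",
        "Factor Name": "ctcf",
    },
)
encode = SourceRecord(
    source="encode",
    attrs={
        "Classification": "cell line",
        "Biosample term name": "HeLa-S3",
        "Assay Name": "chip-seq",
        "Organism": "homo sapiens",
        "Sex": "female",
    },
)

u1 = map_cistrome(cistrome)
u2 = map_encode(encode)
print("unified attributes:", len(u1))
print("cistrome ->", {k: v for k, v in u1.items() if v})
print("encode   ->", {k: v for k, v in u2.items() if v})

e1 = split_into_training_examples(u1, "cistrome sample text")
e2 = split_into_training_examples(u2, "encode sample text")
merged = merge_datasets(e1, e2)
print(f"\n{len(e1)} + {len(e2)} = {len(merged)} training examples, e.g.:")
print(format_training_string(merged[0]))
# A fully annotated Cistrome record always yields 4 examples (its four
# curated attributes); the merged set covers the union of both schemas.
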