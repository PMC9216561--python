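"""Parse a GEO sample from SOFT-lite text, linearize and preprocess it.

The linearized form puts every field name in square brackets so the
language model can exploit the table structure; preprocessing lowercases,
strips '*' and '_', drops words over 30 characters and truncates to 400
tokens.
"""

from geomex import linearize, parse_sample, preprocess

SOFT = """\
^SAMPLE = GSM1565792
!Sample_title = DC_MTB_H3K9me3_rep1 (ChIP-Seq)
!Sample_type = sra
!Sample_source_name_ch1 = Monocyte-derived dendritic cells
!Sample_organism_ch1 = homo sapiens
!Sample_characteristics_ch1 = condition: MTB-infected
!Sample_characteristics_ch1 = chip antibody: H3K9me3 (MABI, 0318, 13 001)
"""

record = parse_sample(SOFT)
print("sample:", record.sample_id)

linear = linearize(record)
print("\nlinearized (verbatim):")
print(linear.text)

clean = preprocess(linear)
print("\npreprocessed (model input,", clean.token_count, "tokens):")
print(clean.text)
# Note how DC_MTB_H3K9me3_rep1 became separable lowercase words: the
# underscore is replaced by a space so each part is searchable by the model.
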