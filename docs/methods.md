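# Methods

## Problem and model

GEO sample metadata is semi-structured free text; the goal is a fixed
15-attribute table per sample. Extraction is cast as conditional text
generation: a single autoregressive language model represents
`P(output | input, task)`, where the input is the linearized sample text,
the task is an attribute name rendered as the text keyword
`"{attribute}:"`, and the output is the attribute value. One model serves
all 15 attributes; each is extracted independently by greedy decoding
from `"<BOS> {input} <SEP> {task}"` until `<EOS>`. Casting the problem as
multitask generation lets heterogeneous training sources (Cistrome-style
records annotating 4 attributes, ENCODE-style records annotating the
rest) train the same model: every annotated sample is split into one
(input, task, target) example per non-null attribute.

Greedy (argmax) decoding is used rather than sampling: the annotation
loop and the tests require determinism, and extraction targets are short
(1–4 words). Ties in the argmax break toward the lexicographically
smaller token.

## Input linearization and preprocessing

A sample's fields are concatenated in source order as
`"[field name]: value"`, with nested characteristics pairs rendered
inline. Preprocessing lowercases, replaces each stripped character
(default `*` and `_`) with a single space — so compound tokens such as
`dc_mtb` become separable words rather than fused ones — collapses
whitespace, removes any word longer than 30 characters (long tokens are
mostly accession junk), and truncates to the first 400 tokens. The head
of the document is kept because GEO records front-load identifying
fields. Preprocessing is idempotent. A "word" is a maximal run of
non-whitespace characters measured after lowercasing; with the word-level
tokenizer, one word is one token.

## Source-schema integration

The unified schema is the union of Cistrome's and ENCODE's attribute
vocabularies (15 names). Cistrome maps Cell Line and Cell Type directly,
Tissue Type to Tissue, and Factor Name to Target — the latter is an
inference: Target is the only factor-like unified attribute. ENCODE's
Classification decides whether the Biosample term name populates Cell
Line or Tissue (Cell Type is always null for ENCODE records); the
remaining attributes rename directly (Assay Name to Technique, Health
status to Disease, Investigated as to Feature, and so on). ENCODE
experiments lacking a GSM get fallback input text by concatenating their
three free-text fields (Description, Biosample summary,
replicates.library.biosample.description), skipping missing components.
Merging performs no deduplication of samples annotated by both sources.

## The trainable backend

The shipped backend is a decoder-only transformer written in numpy with
an explicit backward pass: learned token and position embeddings,
pre-layer-norm blocks of causal multi-head attention and a position-wise
MLP, final layer norm, and a logit projection tied to the embedding
matrix (tying helps the copy-heavy extraction task and keeps the
parameter count down). Defaults: 2 layers, 2 heads, embedding 64, MLP
256, context 512, word-level tokenizer built from the training corpus.
Sample-identifier words (`gsm1234`, `gse77`) are excluded from the
vocabulary and map to `<UNK>`: each is unique to one sample, and keeping
them as tokens lets a small model key predictions on the sample id rather
than the metadata content, which measurably blocks transfer across
near-duplicate series members.
The MLP activation is ReLU by default — on CPU the tanh-based GELU costs
about two thirds of an epoch in `np.tanh` alone for no measurable
accuracy difference at this scale — with GELU available by
configuration. Larger GPT-style shapes (12 layers, 12 heads, embedding
768) are expressible through the same configuration but are not exercised
by the tests. Precision is configurable (float64 default; float32
halves memory, and the trainable adapter uses it).

Training uses Adam with cross-entropy loss. The loss is masked to the
span after the task keyword (target value and `<EOS>`), aligning the
optimization with the extraction objective; full-sequence loss is a
configuration option. The published defaults for the full-scale setup
(learning rate 1e-4, batch 12, early stopping with patience 2 and
min-delta 0) are the `TrainConfig` defaults; the package's own studies of
the tiny backend use learning rate 1e-3 — scale-appropriate for a
2-layer, d=64 model — batch 12 and at most 6 epochs. Early stopping
watches a seeded 10% validation split, stops after `patience + 1`
consecutive non-improving epochs, and restores the best-validation
weights. An `replicas` field mirrors data-parallel training (effective
batch = batch × replicas); it defaults to 1.

The word-level tokenizer grows online: corrections supplied during
annotation may contain words never seen in training, so unseen words get
fresh embedding rows (seeded initialization) before each fine-tuning
round, making user-typed values generatable.

Fixed seeds make corpus generation, splitting, initialization, batching
and training bit-reproducible on a given platform.

## Confidence and traffic lights

A generation's confidence combines its per-token conditional
probabilities. Three strategies are implemented — product over all
tokens, minimum over all tokens, first-token probability — and the
first-token strategy is the default: the product and the minimum
systematically produce low values even for correct multi-token
predictions, while the first token tracks correctness best. The
inequality product ≤ min ≤ first-token holds for every non-empty trace.
An empty generation (immediate `<EOS>`) is reported as the value
`unknown` with confidence equal to the probability of that `<EOS>` — the
model's commitment that there is nothing to extract. Confidences map to
green (> 0.8), red (< 0.6) and yellow otherwise; both boundary values
fall in yellow, reading "above 0.8" and "below 0.6" literally.

## Saliency

Predictions are explained with gradient-times-input (InputXGrad): for
each generated token, the gradient of that token's probability with
respect to every input-token embedding is multiplied elementwise by the
embedding and reduced to a per-input-token L2 norm; norms are summed
across the generated tokens (how a multi-token prediction is aggregated
for display is a package choice) and normalized to sum to one. If every
norm is zero — a model whose output is constant in the input — the map is
uniform. Scores are reported at token granularity; consecutive sub-word
tokens are merged by summation for word-level display (identity under
the word-level tokenizer). Display bins partition `[0, max score]` into
equal widths.

Correctness is anchored by a central finite-difference oracle that
recomputes the same quantities from forward passes on perturbed
embeddings (step 1e-5 in float64, 3e-3 in float32); agreement is
measured as the cosine between the per-token norm vectors.

## Annotation loop

The session holds a queue of extraction results, an augmentation store
of user-approved training examples, and an annotated store. Samples are
loaded by GSM/GSE identifier through a resolver; the queue is sorted by
descending count of non-green fields (stable on ties) — "low confidence"
means any non-green field, since both yellow and red require user
attention. Edits confirm a value, set it to `unknown`, or replace it;
edited fields count as approved and display green. Finalizing a fully
approved sample appends its values to the augmentation store — including
`unknown` values as literal abstention targets by default (excludable by
configuration) — retrains the model online, moves the sample to the
annotated store, and re-extracts and re-sorts the remaining queue. The
loop stops when the queue is empty or entirely green.

Online retraining is adaptive experience replay built around a per-item
notion of *absorption*: a store item is absorbed when greedy extraction
on its input reproduces the approved value with green confidence. A
finalize whose store is fully absorbed triggers no update at all.
Otherwise the whole store — not only the unabsorbed items, because
corrected attributes are correlated (a disease implies a tissue) and
training new facts alone lets settled ones drift — is repeated
(`store_repeat`, default 20, capped at 600 repeated examples so
per-finalize cost stays bounded) and trained together with a seeded
replay subsample of the base dataset (default 1000 examples), one epoch
at a time at the gentle published learning rate (1e-4), until every item
is absorbed or an epoch cap (60) is reached. Training to per-item
absorption rather than a mean loss guarantees corrections transfer
confidently to duplicate samples instead of lingering half-learned,
while the low learning rate and large replay leave settled predictions
essentially untouched. Replaying the base approximates retraining on the
full base-plus-store union and counteracts forgetting.

## Abstention training

The backend must know when *not* to extract: for an attribute absent
from a sample, the desired answer is `unknown`, mirroring the annotation
interface's unknown option. The synthetic training assembly therefore
adds up to 3 examples per sample (seeded choice among its absent
attributes) with the literal target `unknown`. Without abstention
training, absent attributes receive unstable low-confidence guesses that
dominate the red counts in the annotation queue and churn under online
updates.

## Synthetic data

The generator emulates GEO sample records with a known ground-truth
table, imitating the typical field inventory (gsm, title, sample type,
source name, organism, characteristics, description). A sample is either
cell-line-based — drawn from profiles of documented lines (K562, HeLa-S3,
LNCaP, MCF-7, GM12878, HepG2, A549, IMR-90, HCT116) carrying the donor's
cell type, tissue, disease, sex, age and life stage — or tissue-based,
with donor attributes drawn from small vocabularies. An assay (ChIP-seq,
RNA-seq, ATAC-seq, DNase-seq, WGBS) fixes Technique/Technique Type and,
for ChIP, a Target and its Feature class.

Three evidence types arise. Explicit: the value is written in the text
(anchor entities — the cell line or tissue, the technique, the ChIP
target — always are; donor attributes are written into the
characteristics block unless dropped). Synonymous: with probability
`synonym_rate` the text carries a synonym (human / homo sapiens,
chromatin immunoprecipitation sequencing / chip-seq, ...) while the truth
keeps the canonical value. Implicit: with probability
`field_dropout_rate` (default 0.2) an attribute is omitted from the text;
it stays in the truth only if a cue present in the text implies that
exact attribute/value pair — cell line names imply their donor profiles
and the cell-line classification, tissue names imply the tissue
classification, assay names imply their class, and `prostate` implies a
male donor. A `jurkat` profile is deliberately held out of the defaults
so studies of the online loop can confront the model with a family it
has never seen.

What the generator does *not* emulate: real GEO's vocabulary breadth and
spelling noise, multi-valued or contradictory fields, long narrative
descriptions, and attribute cardinalities beyond its closed vocabularies
(donor age in tissue samples, an integer 1–89, is the hardest field for
the tiny backend precisely because it is the least closed). Passing the
synthetic studies therefore demonstrates that the pipeline's mechanics —
task conditioning, confidence, saliency, online learning — work end to
end, not that the tiny backend matches full-scale extraction quality on
real GEO text.

## Study sizes

The standard synthetic study uses 2000 samples (80/20 train/test split,
dropout 0.2, synonym rate 0.2), about 24k training examples, trained for
at most 6 epochs — roughly 5 minutes on one CPU. The annotation-loop
study queues 50 samples — a series of duplicate samples from a cell
line held out of training (the common case where a loaded GEO series
repeats one experiment description across replicates) plus familiar
samples — and runs up to 8 finalize iterations with a simulated curator
who always corrects to ground truth and reviews every queued sample:
high confidence alone does not end the study session, because confident
predictions can still be wrong (notably confident abstention on an
unseen family). The saliency check verifies 20
random 8-token inputs against finite differences. These sizes keep the
full test suite within a laptop-scale CPU budget while leaving every
measured property comfortably determined.

## Degenerate inputs and tie-breaks

Empty records linearize to empty text; extraction still returns all 15
predictions. Queue sorting and greedy decoding are stable/deterministic
as described. An unknown ENCODE Classification value leaves both Cell
Line and Tissue null with a warning. Unresolvable identifiers during
loading are reported and skipped. `classify_confidence` rejects values
outside [0, 1]; thresholds must satisfy 0 ≤ yellow < green ≤ 1.

## Known limitations

The tiny backend's confidence is under-calibrated on high-cardinality
copy fields (ages); the word-level tokenizer cannot compose unseen
surface forms from sub-words (novel words become learnable only through
vocabulary growth); saliency maps for abstention (`unknown`) reflect the
probability of the first generated token only when a token is generated;
and the SOFT-lite reader covers the minimal key/value subset of SOFT,
not the full NCBI grammar.
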