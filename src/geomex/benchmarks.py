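"""Reproducible end-to-end evaluation workflows.

These functions bundle the package's standard study designs so that the
same computation backs the test suite, the acceptance script and the
worked examples: training the tiny backend on a synthetic corpus and
scoring held-out extraction accuracy, checking the confidence-strategy
inequality, validating saliency gradients against finite differences, and
driving the annotation loop with a simulated oracle annotator.
"""

from __future__ import annotations

import numpy as np

from .extraction import extract_all, extract_attribute
from .model import GenerationTrace, TinyTransformerAdapter, TrainConfig, fine_tune
from .model.adapters import ModelAdapter
from .records import RawSampleRecord
from .saliency import finite_difference_attributions, raw_attributions
from .session import (
    OnlineConfig,
    SessionState,
    apply_edit,
    finalize_sample,
    load_samples,
    make_resolver,
    oracle_user,
    sort_queue,
)
from .simulate import (
    DEFAULT_CELL_LINES,
    EXTRA_CELL_LINES,
    GeneratorConfig,
    LabeledSample,
    corpus_to_training_strings,
    generate_corpus,
    split_corpus,
)

#: optimization settings used for the tiny backend throughout the package's
#: own studies (scale-appropriate learning rate for a 2-layer, d=64 model)
TINY_BACKEND_TRAINING = dict(learning_rate=1e-3, batch_size=12, max_epochs=6)


def train_reference_model(
    seed: int,
    n_samples: int = 2000,
    field_dropout_rate: float = 0.2,
    synonym_rate: float = 0.2,
    train_fraction: float = 0.8,
):
    """Generate the standard synthetic study corpus, fine-tune the tiny
    backend on the training split, and return (adapter, train, test)."""
    corpus = generate_corpus(
        GeneratorConfig(
            n_samples=n_samples,
            seed=seed,
            field_dropout_rate=field_dropout_rate,
            synonym_rate=synonym_rate,
        )
    )
    train, test = split_corpus(corpus, train_fraction, seed=seed)
    adapter = TinyTransformerAdapter(seed=seed)
    config = TrainConfig(seed=seed, **TINY_BACKEND_TRAINING)
    fine_tune(adapter, corpus_to_training_strings(train), config)
    return adapter, train, test


def extraction_accuracy(
    adapter: ModelAdapter, samples: list[LabeledSample]
) -> dict[str, float | int]:
    """Exact-match accuracy on ground-truth attributes, split by whether
    the value is stated in the text or only implied by a cue."""
    ok = {"explicit": 0, "implicit": 0}
    total = {"explicit": 0, "implicit": 0}
    for sample in samples:
        result = extract_all(adapter, sample.record)
        for attr, value in sample.truth.items():
            kind = sample.provenance.get(attr, "explicit")
            total[kind] += 1
            if result.predictions[attr].value == value.lower():
                ok[kind] += 1
    return {
        "explicit_accuracy": ok["explicit"] / max(1, total["explicit"]),
        "implicit_accuracy": ok["implicit"] / max(1, total["implicit"]),
        "n_explicit": total["explicit"],
        "n_implicit": total["implicit"],
        "n_samples": len(samples),
    }


def confidence_inequality_fraction(seed: int, n_traces: int = 1000) -> float:
    """Fraction of random traces for which product <= min <= first-token."""
    from .extraction import confidence

    rng = np.random.default_rng(seed)
    holds = 0
    for _ in range(n_traces):
        length = int(rng.integers(1, 9))
        probs = tuple(rng.uniform(1e-9, 1.0, size=length))
        trace = GenerationTrace(tokens=("t",) * length, probs=probs)
        holds += (
            confidence(trace, "product") <= confidence(trace, "min") + 1e-12
            and confidence(trace, "min") <= probs[0] + 1e-12
        )
    return holds / n_traces


def saliency_agreement(
    adapter: TinyTransformerAdapter,
    seed: int,
    n_inputs: int = 20,
    n_tokens: int = 8,
    max_attempts: int = 60,
) -> list[float]:
    """Cosine similarity between analytic and finite-difference
    attributions on random inputs assembled from the model vocabulary."""
    rng = np.random.default_rng(seed)
    vocab = [
        w
        for w in adapter.tokenizer.itos
        if not (w.startswith("<") or w.startswith("gsm") or w.endswith(":"))
    ]
    attributes = ("Cell Line", "Sex", "Technique", "Tissue", "Disease")
    cosines: list[float] = []
    for attempt in range(max_attempts):
        if len(cosines) == n_inputs:
            break
        words = [vocab[i] for i in rng.integers(0, len(vocab), size=n_tokens)]
        text = " ".join(words)
        attribute = attributes[attempt % len(attributes)]
        pred = extract_attribute(adapter, text, attribute, max_new_tokens=2)
        if not pred.trace.tokens:
            continue
        analytic = raw_attributions(adapter, text, attribute, pred.trace)
        numeric = finite_difference_attributions(adapter, text, attribute, pred.trace)
        denom = np.linalg.norm(analytic) * np.linalg.norm(numeric)
        if denom == 0:
            continue
        cosines.append(float(analytic @ numeric / denom))
    return cosines


def _clone_sample(sample: LabeledSample, index: int) -> LabeledSample:
    """A duplicate series member: the same biosample, assay and metadata
    text under a new GSM identifier — the way real GEO series repeat one
    experiment description across their samples."""
    record = sample.record
    gsm = f"gsm{9_500_000 + index}"
    fields = dict(record.fields)
    fields["gsm"] = gsm
    clone = RawSampleRecord(
        sample_id=gsm,
        series_id=record.series_id,
        fields=fields,
        characteristics=dict(record.characteristics),
    )
    return LabeledSample(record=clone, truth=dict(sample.truth),
                         provenance=dict(sample.provenance))


def annotation_loop_study(
    adapter: TinyTransformerAdapter,
    base_dataset: list[str],
    seed: int,
    n_queue: int = 50,
    n_novel: int = 6,
    max_iterations: int = 8,
) -> dict:
    """Oracle-annotator study of the four-phase loop.

    The queue mixes familiar samples with a series of near-duplicate
    samples from a cell line the backend has never seen (held out of the
    generator defaults) — mirroring the common case where a loaded GEO
    series repeats one experiment across replicates — so corrections are
    genuinely informative and should transfer to the rest of the series.
    Tracks the per-iteration count of red fields in the queue and how many
    corrections were needed before a held-out duplicate of the novel
    series is predicted correctly.
    """
    config = GeneratorConfig(
        n_samples=n_queue + 20,
        seed=seed + 101,
        cell_lines={**DEFAULT_CELL_LINES, **EXTRA_CELL_LINES},
        cell_line_weights={"jurkat": 4.0},
        gsm_offset=9_000_000,
    )
    pool = generate_corpus(config)
    seed_sample = next(s for s in pool if s.truth.get("Cell Line") == "jurkat")
    novel = [_clone_sample(seed_sample, i) for i in range(n_novel)]
    familiar = [s for s in pool if s.truth.get("Cell Line") != "jurkat"]
    probe = novel[-1]
    queued = (novel[:-1] + familiar)[: n_queue]

    session = SessionState(
        adapter=adapter,
        base_dataset=list(base_dataset),
        train_config=TrainConfig(seed=seed, **TINY_BACKEND_TRAINING),
        online=OnlineConfig(seed=seed),
    )
    records = [s.record for s in queued]
    truth_by_gsm = {s.record.sample_id: s.truth for s in queued}
    oracle = oracle_user(truth_by_gsm)
    load_samples(session, [r.sample_id for r in records], make_resolver(records))
    sort_queue(session)

    red_counts: list[int] = []
    novel_ids = {s.record.sample_id for s in novel}
    corrections_of_novel = 0
    corrections_until_duplicate = None
    # the simulated curator reviews every queued sample: high confidence
    # alone does not end the session, since confident predictions can
    # still be wrong (notably confident abstention on an unseen family)
    for _ in range(max_iterations):
        if not session.queue:
            break
        red_counts.append(sum(r.count_light("red") for r in session.queue))
        target = session.queue[0]
        for edit in oracle(target):
            apply_edit(session, target.sample_id, edit)
        finalize_sample(session, target.sample_id)
        if target.sample_id in novel_ids:
            corrections_of_novel += 1
            if corrections_until_duplicate is None:
                result = extract_all(session.adapter, probe.record)
                if all(
                    result.predictions[a].value == v.lower()
                    for a, v in probe.truth.items()
                ):
                    corrections_until_duplicate = corrections_of_novel
    red_counts.append(sum(r.count_light("red") for r in session.queue))
    return {
        "red_counts": red_counts,
        "non_increasing": all(
            a >= b for a, b in zip(red_counts, red_counts[1:])
        ),
        "corrections_of_novel": corrections_of_novel,
        "corrections_until_duplicate_correct": corrections_until_duplicate,
        "finalized": len(session.annotated_store),
        "session": session,
    }
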