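"""Drive the four-phase annotation loop headlessly with a simulated
annotator that always corrects to ground truth.

The queue is sorted so the sample with the most low-confidence fields is
annotated first; each finalize retrains the model online and re-extracts
the remaining queue.  Runs in a few minutes on one CPU.
"""

from geomex import (
    GeneratorConfig,
    TinyTransformerAdapter,
    TrainConfig,
    export,
    fine_tune,
    generate_corpus,
    load_samples,
    make_resolver,
    oracle_user,
    run_headless_loop,
    sort_queue,
    split_corpus,
)
from geomex.session import SessionState, OnlineConfig
from geomex.simulate import corpus_to_training_strings

corpus = generate_corpus(GeneratorConfig(n_samples=300, seed=11))
train, test = split_corpus(corpus, 0.8, seed=11)
base = corpus_to_training_strings(train)
adapter = TinyTransformerAdapter(seed=11)
fine_tune(adapter, base, TrainConfig(learning_rate=1e-3, max_epochs=6, seed=11))

queued = test[:10]
session = SessionState(
    adapter=adapter,
    base_dataset=base,
    train_config=TrainConfig(learning_rate=1e-3, max_epochs=6, seed=11),
    online=OnlineConfig(seed=11),
)
records = [s.record for s in queued]
load_samples(session, [r.sample_id for r in records], make_resolver(records))
sort_queue(session)
print("queued:", len(session.queue), " red fields:",
      sum(r.count_light("red") for r in session.queue))

oracle = oracle_user({s.record.sample_id: s.truth for s in queued})
red_counts = run_headless_loop(session, oracle, max_iterations=3)
print("red fields per iteration:", red_counts)
print("annotated:", len(session.annotated_store),
      " augmentation examples:", len(session.augmentation_store))

csv_text = export(session, "csv")
print("\nexported table (first 2 lines):")
print("\n".join(csv_text.splitlines()[:2]))
# Red counts shrink as corrected samples leave the queue and the online
# updates teach the model their patterns; the export holds the finalized
# table plus the current queue snapshot.
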