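"""Headless annotation session: the four-phase human-in-the-loop cycle.

1. **Load** — the user supplies GSM/GSE identifiers; a resolver turns them
   into sample records and every sample is extracted into the queue.
2. **Sort** — the queue is ordered so the sample with the most
   low-confidence (non-green) fields comes first; ties keep their prior
   relative order.
3. **Edit** — for each attribute the user confirms the prediction, sets it
   to unknown, or types a new value; edited fields count as approved.
4. **Finalize** — once every field of a sample is approved, its values
   become training examples in the augmentation store, the model is
   retrained online, the sample moves to the annotated store, and the
   remaining queue is re-extracted and re-sorted.

The loop stops when the queue is empty or every queued prediction is
green.  Online retraining is experience-replay style: the augmentation
store (repeated so fresh corrections carry weight, up to a volume cap) is
trained together with a seeded subsample of the base dataset, at a gentle
learning rate for a bounded number of epochs per finalize — enough to
absorb the new facts without disturbing settled predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

from .extraction import (
    ExtractionResult,
    Thresholds,
    UNKNOWN_VALUE,
    extract_all,
    extract_attribute,
    results_to_frame,
)
from .model.adapters import ModelAdapter, TinyTransformerAdapter
from .model.training import TrainConfig, fine_tune
from .records import PreprocessConfig, RawSampleRecord
from .schema import DEFAULT_SCHEMA, AttributeSchema
from .sources import TrainingExample, format_training_string


class SessionError(RuntimeError):
    pass


@dataclass(frozen=True)
class UserEdit:
    """One user action on one attribute of one queued sample."""

    attribute: str
    action: str  # "confirm" | "set-unknown" | "new-value"
    value: str | None = None

    def __post_init__(self) -> None:
        if self.action not in ("confirm", "set-unknown", "new-value"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "new-value" and not (self.value and self.value.strip()):
            raise ValueError("new-value requires non-empty text")


@dataclass(frozen=True)
class OnlineConfig:
    """Per-finalize retraining budget.

    The augmentation store is repeated ``store_repeat`` times so fresh
    corrections carry weight, but never beyond ``max_store_volume``
    repeated examples, keeping per-finalize cost bounded as the store
    grows.
    """

    max_epochs: int = 60
    learning_rate: float = 1e-4   # gentle updates: learn the new facts
    store_repeat: int = 20        # without disturbing settled predictions
    max_store_volume: int = 600
    replay_size: int = 1000
    include_unknown: bool = True  # train "unknown" edits as literal targets
    seed: int = 0


#: maps one identifier to the sample records it denotes (a GSM to itself,
#: a GSE to its member GSMs); unknown identifiers raise KeyError
Resolver = Callable[[str], list[RawSampleRecord]]


def make_resolver(records: Iterable[RawSampleRecord]) -> Resolver:
    """Resolver backed by an in-memory record store."""
    by_gsm: dict[str, RawSampleRecord] = {}
    by_gse: dict[str, list[RawSampleRecord]] = {}
    for r in records:
        by_gsm[r.sample_id] = r
        if r.series_id:
            by_gse.setdefault(r.series_id, []).append(r)

    def resolve(identifier: str) -> list[RawSampleRecord]:
        if identifier in by_gsm:
            return [by_gsm[identifier]]
        if identifier in by_gse:
            return list(by_gse[identifier])
        raise KeyError(identifier)

    return resolve


@dataclass
class SessionState:
    adapter: ModelAdapter
    base_dataset: list[str] = field(default_factory=list)  # formatted strings
    thresholds: Thresholds = field(default_factory=Thresholds)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    online: OnlineConfig = field(default_factory=OnlineConfig)
    schema: AttributeSchema = DEFAULT_SCHEMA
    strategy: str = "first"
    preprocess_config: PreprocessConfig = field(default_factory=PreprocessConfig)
    queue: list[ExtractionResult] = field(default_factory=list)
    annotated_store: list[ExtractionResult] = field(default_factory=list)
    augmentation_store: list[TrainingExample] = field(default_factory=list)
    records: dict[str, RawSampleRecord] = field(default_factory=dict)
    load_errors: list[str] = field(default_factory=list)
    finalize_count: int = 0

    # ------------------------------------------------------------------ load

    def _extract(self, record: RawSampleRecord) -> ExtractionResult:
        return extract_all(
            self.adapter,
            record,
            schema=self.schema,
            preprocess_config=self.preprocess_config,
            strategy=self.strategy,
            thresholds=self.thresholds,
        )

    def find(self, sample_id: str) -> ExtractionResult:
        for r in self.queue:
            if r.sample_id == sample_id:
                return r
        raise SessionError(f"sample {sample_id!r} is not in the queue")


def load_samples(session: SessionState, ids: list[str], resolver: Resolver) -> SessionState:
    """Resolve identifiers and queue one extraction per distinct GSM.

    Unresolvable identifiers are reported in ``session.load_errors``; the
    remaining identifiers are still processed.
    """
    seen = {r.sample_id for r in session.queue} | {
        r.sample_id for r in session.annotated_store
    }
    for identifier in ids:
        try:
            records = resolver(identifier)
        except KeyError:
            session.load_errors.append(identifier)
            continue
        for record in records:
            if record.sample_id in seen:
                continue
            seen.add(record.sample_id)
            session.records[record.sample_id] = record
            session.queue.append(session._extract(record))
    return session


def sort_queue(session: SessionState) -> SessionState:
    """Most low-confidence (non-green) fields first; stable on ties."""
    session.queue.sort(key=lambda r: -r.non_green_count())
    return session


def apply_edit(session: SessionState, sample_id: str, edit: UserEdit) -> SessionState:
    """Apply one confirm / set-unknown / new-value action; the edited field
    becomes user-approved (displayed green)."""
    if any(r.sample_id == sample_id for r in session.annotated_store):
        raise SessionError(f"sample {sample_id!r} is already finalized")
    result = session.find(sample_id)
    if edit.attribute not in session.schema:
        raise SessionError(f"unknown attribute {edit.attribute!r}")
    pred = result.predictions[edit.attribute]
    if edit.action == "set-unknown":
        pred.value = UNKNOWN_VALUE
    elif edit.action == "new-value":
        pred.value = edit.value.strip().lower()
    pred.approved = True
    return session


def finalize_sample(session: SessionState, sample_id: str) -> SessionState:
    """Commit an approved sample: augment, retrain online, re-extract.

    Raises if any attribute is still unapproved.  The finalized sample's
    approved values (including "unknown" as a literal abstention target,
    unless configured otherwise) are
    appended to the augmentation store; the adapter is fine-tuned on the
    store plus a replay subsample of the base dataset; the sample moves to
    the annotated store; the remaining queue is re-extracted and re-sorted.
    """
    result = session.find(sample_id)
    pending = [a for a, p in result.predictions.items() if not p.approved]
    if pending:
        raise SessionError(f"unapproved fields remain: {pending}")

    for attribute, pred in result.predictions.items():
        if pred.value == UNKNOWN_VALUE and not session.online.include_unknown:
            continue
        session.augmentation_store.append(
            TrainingExample(
                input_text=result.input_text,
                task=attribute.lower() + ":",
                target=pred.value,
            )
        )

    _online_update(session)
    session.queue.remove(result)
    session.annotated_store.append(result)
    session.finalize_count += 1

    requeued = [session._extract(session.records[r.sample_id]) for r in session.queue]
    session.queue = requeued
    return sort_queue(session)


def _unabsorbed_examples(session: SessionState) -> list[TrainingExample]:
    """Store items the model has not absorbed: greedy extraction disagrees
    with the approved target, or agrees without green confidence."""
    name_by_task = {n.lower() + ":": n for n in session.schema.names}
    needs = []
    for ex in session.augmentation_store:
        pred = extract_attribute(
            session.adapter,
            ex.input_text,
            name_by_task[ex.task],
            schema=session.schema,
            strategy=session.strategy,
            thresholds=session.thresholds,
        )
        if pred.value != ex.target or pred.confidence <= session.thresholds.green:
            needs.append(ex)
    return needs


def _online_update(session: SessionState) -> None:
    """Absorb the augmentation store into the model.

    Adaptive: if every store item is already absorbed (greedy extraction
    matches the approved value with green confidence), no update runs.
    Otherwise the whole store — not only the unabsorbed items, since
    corrected attributes are correlated (a disease implies a tissue) and
    training new facts alone lets settled ones drift — is repeated and
    trained together with a replay subsample of the base dataset, one
    epoch at a time at a gentle learning rate, until every item is
    absorbed or the epoch cap is reached.  Per-item absorption (rather
    than a mean loss) guarantees corrections transfer confidently to
    duplicate samples instead of lingering in a half-learned state.
    """
    online = session.online
    if not session.adapter.capabilities.trainable or not session.augmentation_store:
        return
    if not _unabsorbed_examples(session):
        return
    store = [format_training_string(ex) for ex in session.augmentation_store]
    repeats = max(1, min(online.store_repeat, online.max_store_volume // len(store)))
    rng = np.random.default_rng(online.seed + session.finalize_count)
    base = session.base_dataset
    if base and len(base) > online.replay_size:
        idx = rng.choice(len(base), size=online.replay_size, replace=False)
        base = [base[i] for i in sorted(idx)]
    dataset = list(base) + store * repeats
    for epoch in range(online.max_epochs):
        config = replace(
            session.train_config,
            learning_rate=online.learning_rate,
            max_epochs=1,
            val_fraction=0.0,
            seed=online.seed + 1000 * session.finalize_count + epoch,
        )
        fine_tune(session.adapter, dataset, config)
        if not _unabsorbed_examples(session):
            break


def stop_condition(session: SessionState) -> bool:
    """True when the queue is empty or every queued prediction is green."""
    return all(
        p.effective_light == "green"
        for r in session.queue
        for p in r.predictions.values()
    )


def run_headless_loop(
    session: SessionState,
    oracle: Callable[[ExtractionResult], list[UserEdit]],
    max_iterations: int = 50,
) -> list[int]:
    """Drive the loop with a scripted user; returns the per-iteration count
    of red fields in the queue (measured before each finalize)."""
    red_counts: list[int] = []
    iterations = 0
    sort_queue(session)
    while session.queue and not stop_condition(session) and iterations < max_iterations:
        red_counts.append(sum(r.count_light("red") for r in session.queue))
        target = session.queue[0]
        for edit in oracle(target):
            apply_edit(session, target.sample_id, edit)
        finalize_sample(session, target.sample_id)
        iterations += 1
    red_counts.append(sum(r.count_light("red") for r in session.queue))
    return red_counts


def oracle_user(truth_by_gsm: dict[str, dict[str, str]], schema: AttributeSchema = DEFAULT_SCHEMA):
    """Simulated annotator that always corrects to the ground truth."""

    def edit_plan(result: ExtractionResult) -> list[UserEdit]:
        truth = truth_by_gsm.get(result.sample_id, {})
        edits = []
        for attribute in schema.names:
            expected = truth.get(attribute, "").lower()
            predicted = result.predictions[attribute].value
            if not expected:
                edits.append(UserEdit(attribute, "set-unknown"))
            elif predicted == expected:
                edits.append(UserEdit(attribute, "confirm"))
            else:
                edits.append(UserEdit(attribute, "new-value", expected))
        return edits

    return edit_plan


# --------------------------------------------------------------------- export

def export(
    session: SessionState,
    fmt: str = "csv",
    destination: str | Path | None = None,
    include_confidence: bool = False,
) -> str:
    """Write the annotated store plus a queue snapshot as CSV or JSON.

    CSV columns: gsm, gse, then the 15 schema attributes.  Returns the
    rendered text (and writes it to ``destination`` when given).
    """
    results = list(session.annotated_store) + list(session.queue)
    if fmt == "csv":
        frame = results_to_frame(results, session.schema, include_confidence)
        text = frame.to_csv(index=False)
    elif fmt == "json":
        text = json.dumps(
            {
                "annotated": [r.to_dict() for r in session.annotated_store],
                "queue": [r.to_dict() for r in session.queue],
            },
            indent=2,
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    if destination is not None:
        Path(destination).write_text(text)
    return text


def save_session(session: SessionState, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(session.adapter, TinyTransformerAdapter):
        session.adapter.save(directory / "adapter")
    state = {
        "thresholds": {"green": session.thresholds.green, "yellow": session.thresholds.yellow},
        "strategy": session.strategy,
        "queue": [r.to_dict() for r in session.queue],
        "annotated": [r.to_dict() for r in session.annotated_store],
        "augmentation": [ex.__dict__ for ex in session.augmentation_store],
        "records": {k: v.to_dict() for k, v in session.records.items()},
        "base_dataset": session.base_dataset,
        "finalize_count": session.finalize_count,
    }
    (directory / "session.json").write_text(json.dumps(state))


def load_session(directory: str | Path, adapter: ModelAdapter | None = None) -> SessionState:
    directory = Path(directory)
    state = json.loads((directory / "session.json").read_text())
    if adapter is None:
        adapter = TinyTransformerAdapter.load(directory / "adapter")
    session = SessionState(
        adapter=adapter,
        base_dataset=list(state.get("base_dataset", [])),
        thresholds=Thresholds(**state["thresholds"]),
        strategy=state.get("strategy", "first"),
    )
    session.queue = [ExtractionResult.from_dict(d) for d in state["queue"]]
    session.annotated_store = [ExtractionResult.from_dict(d) for d in state["annotated"]]
    session.augmentation_store = [TrainingExample(**d) for d in state["augmentation"]]
    session.records = {
        k: RawSampleRecord.from_dict(v) for k, v in state.get("records", {}).items()
    }
    session.finalize_count = state.get("finalize_count", 0)
    return session
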