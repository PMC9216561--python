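"""Fine-tuning with early stopping.

Training strings have the form ``<BOS> input <SEP> task: target <EOS>``.
By default cross-entropy is computed only on the span after the task
keyword (the target value and <EOS>), aligning the optimization with the
extraction objective; full-sequence loss is available through
``loss_mask="full"``.  A seeded validation split drives Keras-style early
stopping: training halts once the validation loss has failed to improve by
``min_delta`` for more than ``patience`` consecutive epochs, and the best
validation weights are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .adapters import CapabilityError, ModelAdapter, TinyTransformerAdapter
from .tokenizer import SEP


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam + cross-entropy throughout)."""

    learning_rate: float = 1e-4
    batch_size: int = 12
    replicas: int = 1  # data-parallel replicas; effective batch = batch_size * replicas
    max_epochs: int = 20
    patience: int = 2
    min_delta: float = 0.0
    val_fraction: float = 0.1
    loss_mask: str = "target"  # "target" | "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.replicas < 1:
            raise ValueError("learning rate, batch size and replicas must be positive")
        if self.loss_mask not in ("target", "full"):
            raise ValueError("loss_mask must be 'target' or 'full'")

    @property
    def effective_batch(self) -> int:
        return self.batch_size * self.replicas


class EarlyStopping:
    """Plateau detector: stop after ``patience + 1`` non-improving epochs."""

    def __init__(self, patience: int = 2, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0
        self.history: list[float] = []

    def update(self, loss: float) -> bool:
        """Record an epoch's validation loss; return True when training
        should stop."""
        self.history.append(loss)
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = len(self.history) - 1
            self.wait = 0
            return False
        self.wait += 1
        return self.wait > self.patience


@dataclass
class TrainingReport:
    epochs_run: int
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    stopped_early: bool = False
    best_epoch: int = -1


def _loss_mask_for(ids: list[int], sep_id: int, tokenizer, mode: str) -> np.ndarray:
    """Mask over predicted positions t (predicting ids[t+1])."""
    T = len(ids)
    mask = np.zeros(T - 1, dtype=bool)
    if mode == "full":
        mask[:] = True
        return mask
    try:
        sep_pos = ids.index(sep_id)
    except ValueError as exc:
        raise TrainingError("training string lacks <SEP>") from exc
    # the task keyword spans sep_pos+1 .. first token ending with ':'
    k = sep_pos + 1
    while k < T and not tokenizer.itos[ids[k]].endswith(":"):
        k += 1
    # predictions of tokens k+1 .. T-1 (target value and <EOS>)
    mask[k : T - 1] = True
    return mask


def fine_tune(
    adapter: ModelAdapter,
    dataset: list[str],
    config: TrainConfig = TrainConfig(),
) -> ModelAdapter:
    """Fine-tune a trainable backend on formatted training strings.

    Mutates and returns ``adapter``; the loss/early-stop trajectory is
    stored on ``adapter.last_training_report``.  Bit-reproducible for a
    fixed seed on a given platform.
    """
    if not adapter.capabilities.trainable:
        raise CapabilityError("adapter is not trainable")
    if not dataset:
        raise TrainingError("training dataset is empty")
    if not isinstance(adapter, TinyTransformerAdapter):
        raise CapabilityError("unsupported trainable backend")

    adapter.ensure_built(dataset)
    tok = adapter.tokenizer
    model = adapter.model
    # corrections supplied online may introduce unseen words; grow the
    # vocabulary (and embedding table) so they become generatable targets
    unseen = sorted({w for s in dataset for w in s.split() if w not in tok.stoi})
    if unseen:
        added = tok.add_words(unseen)  # identifier-like words stay <UNK>
        model.grow_vocab(added, seed=config.seed)
    sep_id = tok.stoi[SEP]

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    n_val = int(round(config.val_fraction * len(dataset)))
    n_val = min(n_val, len(dataset) - 1)
    val_idx = order[:n_val]
    train_idx = order[n_val:]

    encoded = [tok.encode(s) for s in dataset]
    masks = [_loss_mask_for(ids, sep_id, tok, config.loss_mask) for ids in encoded]

    def batches(indices: np.ndarray, shuffle_rng=None):
        # length-sorted batching limits padding waste; batch order shuffled
        idx = sorted(indices, key=lambda i: len(encoded[i]))
        bs = config.effective_batch
        groups = [idx[i : i + bs] for i in range(0, len(idx), bs)]
        if shuffle_rng is not None:
            shuffle_rng.shuffle(groups)
        for group in groups:
            L = max(len(encoded[i]) for i in group)
            ids = np.full((len(group), L), tok.pad_id, dtype=np.int64)
            pad = np.zeros((len(group), L), dtype=bool)
            lmask = np.zeros((len(group), L - 1), dtype=bool)
            for r, i in enumerate(group):
                seq = encoded[i]
                ids[r, : len(seq)] = seq
                pad[r, : len(seq)] = True
                lmask[r, : len(seq) - 1] = masks[i]
            yield ids, pad, lmask

    stopper = EarlyStopping(config.patience, config.min_delta)
    report = TrainingReport(epochs_run=0)
    best_params = None

    for epoch in range(config.max_epochs):
        epoch_losses = []
        for ids, pad, lmask in batches(train_idx, shuffle_rng=rng):
            loss, grads = model.loss_and_grads(ids, pad, lmask)
            model.adam_step(grads, lr=config.learning_rate)
            epoch_losses.append(loss)
        report.train_losses.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
        report.epochs_run = epoch + 1

        if len(val_idx):
            val_losses = [
                model.loss_only(ids, pad, lmask) for ids, pad, lmask in batches(val_idx)
            ]
            val_loss = float(np.mean(val_losses))
            report.val_losses.append(val_loss)
            improved = val_loss < stopper.best - stopper.min_delta
            stop = stopper.update(val_loss)
            if improved:
                best_params = {k: v.copy() for k, v in model.params.items()}
            if stop:
                report.stopped_early = True
                break

    if best_params is not None:
        model.params = best_params
    report.best_epoch = stopper.best_epoch
    adapter.last_training_report = report
    return adapter


def online_config(config: TrainConfig, epochs: int = 1) -> TrainConfig:
    """Bounded-epoch variant of a config for per-annotation online updates."""
    return replace(config, max_epochs=epochs, val_fraction=0.0)


def evaluate_loss(adapter: ModelAdapter, dataset: list[str], batch_size: int = 12,
                  loss_mask: str = "target") -> float:
    """Mean masked cross-entropy of the current model on formatted strings."""
    if not isinstance(adapter, TinyTransformerAdapter) or adapter.model is None:
        raise CapabilityError("loss evaluation needs a built trainable backend")
    tok = adapter.tokenizer
    model = adapter.model
    sep_id = tok.stoi[SEP]
    encoded = [tok.encode(s) for s in dataset]
    masks = [_loss_mask_for(ids, sep_id, tok, loss_mask) for ids in encoded]
    order = sorted(range(len(encoded)), key=lambda i: len(encoded[i]))
    losses = []
    for start in range(0, len(order), batch_size):
        group = order[start : start + batch_size]
        L = max(len(encoded[i]) for i in group)
        ids = np.full((len(group), L), tok.pad_id, dtype=np.int64)
        pad = np.zeros((len(group), L), dtype=bool)
        lmask = np.zeros((len(group), L - 1), dtype=bool)
        for r, i in enumerate(group):
            seq = encoded[i]
            ids[r, : len(seq)] = seq
            pad[r, : len(seq)] = True
            lmask[r, : len(seq) - 1] = masks[i]
        losses.append(model.loss_only(ids, pad, lmask))
    return float(np.mean(losses))
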