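"""Pluggable autoregressive language-model backends.

Extraction, saliency and the annotation loop only see the
:class:`ModelAdapter` contract: a tokenizer with the reserved keywords, a
next-token conditional distribution, and capability flags saying whether
the backend can generate, be trained, and be differentiated.  Two backends
ship with the package:

* :class:`TinyTransformerAdapter` — a small trainable numpy transformer
  (default: 2 layers, 2 heads, embedding size 64) with a word-level
  tokenizer built from the training corpus.  Larger GPT-style shapes are
  expressible through the same configuration.
* :class:`TableLookupAdapter` — an exact, table-driven fixture: the
  conditional distribution for each prompt is read off a dictionary.
  Useful for deterministic tests of everything downstream of the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .network import ModelConfig, TransformerLM
from .tokenizer import BOS, EOS, PAD, SEP, UNK, WordTokenizer


class CapabilityError(RuntimeError):
    """The backend lacks a capability required by the requested operation."""


class ContextError(ValueError):
    """Prompt does not fit the model context window."""


@dataclass(frozen=True)
class Capabilities:
    generates: bool = True
    trainable: bool = False
    differentiable: bool = False


@dataclass(frozen=True)
class GenerationTrace:
    """Greedy generation output: tokens up to (excluding) <EOS>.

    ``probs[i]`` is the conditional probability the model assigned to the
    chosen token ``tokens[i]``.  When generation stopped because <EOS> was
    the greedy choice, ``stop_prob`` records the probability of <EOS> at
    that step (the model's commitment to "nothing more to extract").
    """

    tokens: tuple[str, ...]
    probs: tuple[float, ...]
    stop_prob: float | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.probs):
            raise ValueError("tokens and probs must have equal length")
        if any(not (0.0 <= p <= 1.0) for p in self.probs):
            raise ValueError("probabilities must lie in [0, 1]")


class ModelAdapter:
    """Base contract; see module docstring."""

    capabilities: Capabilities = Capabilities()
    tokenizer: WordTokenizer | None = None
    max_context: int = 512

    def next_distribution(self, prefix_tokens: list[str]) -> dict[str, float]:
        raise NotImplementedError


_NON_GENERATABLE = {PAD, UNK, BOS, SEP}


def generate(
    adapter: ModelAdapter, prompt: str, max_new_tokens: int = 8
) -> GenerationTrace:
    """Greedy (argmax) decoding from ``prompt`` until <EOS> or the cap.

    Deterministic: probability ties break toward the lexicographically
    smaller token.  Structural special tokens other than <EOS> are never
    emitted.
    """
    if not adapter.capabilities.generates:
        raise CapabilityError("adapter cannot generate")
    prefix = prompt.split()
    if len(prefix) + max_new_tokens > adapter.max_context:
        raise ContextError(
            f"prompt of {len(prefix)} tokens plus {max_new_tokens} new tokens "
            f"exceeds the context length {adapter.max_context}"
        )
    tokens: list[str] = []
    probs: list[float] = []
    stop_prob: float | None = None
    for _ in range(max_new_tokens):
        dist = adapter.next_distribution(prefix + tokens)
        candidates = [
            (p, t) for t, p in dist.items() if t not in _NON_GENERATABLE
        ]
        if not candidates:
            break
        best_p, best_t = max(candidates, key=lambda pt: (pt[0], [-ord(c) for c in pt[1]]))
        if best_t == EOS:
            stop_prob = best_p
            break
        tokens.append(best_t)
        probs.append(best_p)
    return GenerationTrace(tokens=tuple(tokens), probs=tuple(probs), stop_prob=stop_prob)


class TableLookupAdapter(ModelAdapter):
    """Exact fixture backend: ``table[prompt] -> {token: prob}``.

    Prompts are matched on whitespace-normalized text of the full prefix
    (prompt plus already-generated tokens).  Unlisted prompts yield an
    immediate <EOS> with probability 1.
    """

    capabilities = Capabilities(generates=True)

    def __init__(self, table: dict[str, dict[str, float]], max_context: int = 512):
        self.table = {" ".join(k.split()): v for k, v in table.items()}
        self.max_context = max_context

    def next_distribution(self, prefix_tokens: list[str]) -> dict[str, float]:
        return dict(self.table.get(" ".join(prefix_tokens), {EOS: 1.0}))


class TinyTransformerAdapter(ModelAdapter):
    """Trainable, differentiable numpy-transformer backend."""

    capabilities = Capabilities(generates=True, trainable=True, differentiable=True)

    def __init__(
        self,
        tokenizer: WordTokenizer | None = None,
        d_model: int = 64,
        n_heads: int = 2,
        n_layers: int = 2,
        d_ff: int = 256,
        max_context: int = 512,
        seed: int = 0,
        dtype: str = "float32",
    ):
        self.tokenizer = tokenizer
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.max_context = max_context
        self.seed = seed
        self.dtype = dtype
        self.model: TransformerLM | None = None
        self.last_training_report = None
        if tokenizer is not None:
            self._build_model()

    def _build_model(self) -> None:
        config = ModelConfig(
            vocab_size=len(self.tokenizer),
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            d_ff=self.d_ff,
            max_len=self.max_context,
            seed=self.seed,
            dtype=self.dtype,
        )
        self.model = TransformerLM(config)

    def ensure_built(self, corpus: list[str]) -> None:
        """Build the word-level tokenizer and network from a corpus."""
        if self.tokenizer is None:
            self.tokenizer = WordTokenizer.build(corpus)
        if self.model is None:
            self._build_model()

    def _require_model(self) -> TransformerLM:
        if self.model is None:
            raise CapabilityError("backend not yet built; fine-tune it first")
        return self.model

    def encode_prompt(self, prompt: str) -> list[int]:
        ids = self.tokenizer.encode(prompt)
        if len(ids) > self.max_context:
            raise ContextError(
                f"prompt of {len(ids)} tokens exceeds context {self.max_context}"
            )
        return ids

    def next_distribution(self, prefix_tokens: list[str]) -> dict[str, float]:
        model = self._require_model()
        ids = self.encode_prompt(" ".join(prefix_tokens))
        probs = model.next_token_distribution(ids)
        return {tok: float(p) for tok, p in zip(self.tokenizer.itos, probs)}

    # ------------------------------------------------------------- gradients

    def token_prob_grad(self, sequence_tokens: list[str], position: int, target_token: str):
        """(probability, d prob / d input-embeddings, input embeddings)."""
        model = self._require_model()
        ids = np.asarray(self.tokenizer.encode(" ".join(sequence_tokens)))
        target = self.tokenizer.stoi.get(target_token, self.tokenizer.stoi[UNK])
        return model.token_prob_grad(ids, position, target)

    def token_prob_from_embeddings(self, x_emb, position: int, target_token: str):
        model = self._require_model()
        target = self.tokenizer.stoi.get(target_token, self.tokenizer.stoi[UNK])
        return model.token_prob_from_embeddings(x_emb, position, target)

    def embed_tokens(self, sequence_tokens: list[str]) -> np.ndarray:
        model = self._require_model()
        ids = np.asarray(self.tokenizer.encode(" ".join(sequence_tokens)))
        return model.embed(ids[None, :])[0]

    # ----------------------------------------------------------- persistence

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        model = self._require_model()
        model.save(directory)
        self.tokenizer.save(directory / "tokenizer.json")
        manifest = {
            "backend": "tiny-transformer",
            "d_model": self.d_model,
            "n_heads": self.n_heads,
            "n_layers": self.n_layers,
            "d_ff": self.d_ff,
            "max_context": self.max_context,
            "seed": self.seed,
            "dtype": self.dtype,
        }
        (directory / "adapter.yaml").write_text(yaml.safe_dump(manifest))

    @classmethod
    def load(cls, directory: str | Path) -> "TinyTransformerAdapter":
        directory = Path(directory)
        manifest = yaml.safe_load((directory / "adapter.yaml").read_text())
        tokenizer = WordTokenizer.load(directory / "tokenizer.json")
        adapter = cls(
            tokenizer=tokenizer,
            d_model=manifest["d_model"],
            n_heads=manifest["n_heads"],
            n_layers=manifest["n_layers"],
            d_ff=manifest["d_ff"],
            max_context=manifest["max_context"],
            seed=manifest.get("seed", 0),
            dtype=manifest.get("dtype", "float64"),
        )
        adapter.model = TransformerLM.load(directory)
        return adapter
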