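"""Gradient-times-input saliency maps for extraction predictions.

For a predicted attribute value, the relevance of each input token is
computed with the InputXGrad rule: take the gradient of the generated
token's probability with respect to each input-token embedding, multiply
elementwise by that embedding, and reduce to a per-token L2 norm.  For
multi-token predictions the per-token norms are summed across generated
tokens; the resulting nonnegative scores are normalized to sum to one (a
uniform map is returned if every norm is zero, e.g. for a model whose
output ignores the input).

A central finite-difference oracle over the input embeddings is provided
for verification; it approximates the same quantities without using the
analytic backward pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model.adapters import CapabilityError, GenerationTrace, ModelAdapter
from .schema import DEFAULT_SCHEMA, AttributeSchema
from .sources import BOS, SEP


@dataclass(frozen=True)
class SaliencyMap:
    """Per-input-token relevance for one predicted attribute."""

    tokens: tuple[str, ...]
    scores: tuple[float, ...]
    bins: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.tokens):
            raise ValueError("scores and tokens must have equal length")
        if any(s < 0 for s in self.scores):
            raise ValueError("scores must be nonnegative")
        if self.scores and abs(sum(self.scores) - 1.0) > 1e-6:
            raise ValueError("scores must sum to 1")
        if self.bins and len(self.bins) != len(self.tokens):
            raise ValueError("bins and tokens must have equal length")

    def to_json(self) -> str:
        bins = self.bins or tuple([0] * len(self.tokens))
        return json.dumps(
            [
                {"token": t, "score": s, "bin": b}
                for t, s, b in zip(self.tokens, self.scores, bins)
            ]
        )


def _normalize(tokens: tuple[str, ...], norms: np.ndarray) -> SaliencyMap:
    total = float(norms.sum())
    if total <= 0.0:
        n = len(tokens)
        scores = tuple([1.0 / n] * n)
    else:
        scores = tuple(float(s) for s in norms / total)
    return SaliencyMap(tokens=tokens, scores=scores)


def _prompt_parts(input_text: str, attribute: str, schema: AttributeSchema):
    """Prompt tokens plus the index span of the input-text tokens."""
    input_tokens = input_text.split()
    task_tokens = schema.task_keyword(attribute).split()
    prompt_tokens = [BOS] + input_tokens + [SEP] + task_tokens
    span = (1, 1 + len(input_tokens))  # input tokens sit after <BOS>
    return prompt_tokens, span


def raw_attributions(
    adapter: ModelAdapter,
    input_text: str,
    attribute: str,
    trace: GenerationTrace,
    schema: AttributeSchema = DEFAULT_SCHEMA,
) -> np.ndarray:
    """Unnormalized per-input-token InputXGrad norms, summed over the
    generated tokens of ``trace``."""
    if not adapter.capabilities.differentiable:
        raise CapabilityError(
            "adapter is not differentiable; use finite_difference_attributions "
            "with an embedding-level forward instead"
        )
    prompt_tokens, (lo, hi) = _prompt_parts(input_text, attribute, schema)
    norms = np.zeros(hi - lo)
    for k, token in enumerate(trace.tokens):
        sequence = prompt_tokens + list(trace.tokens[:k])
        position = len(sequence) - 1  # the slot predicting token k
        _, grad, emb = adapter.token_prob_grad(sequence, position, token)
        contrib = grad[lo:hi] * emb[lo:hi]
        norms += np.linalg.norm(contrib, axis=-1)
    return norms


def input_x_grad(
    adapter: ModelAdapter,
    input_text: str,
    attribute: str,
    trace: GenerationTrace,
    schema: AttributeSchema = DEFAULT_SCHEMA,
) -> SaliencyMap:
    """InputXGrad saliency map over the input tokens for one prediction."""
    input_tokens = tuple(input_text.split())
    if not trace.tokens or not input_tokens:
        n = max(len(input_tokens), 1)
        return SaliencyMap(tokens=input_tokens or ("",), scores=tuple([1.0 / n] * n))
    norms = raw_attributions(adapter, input_text, attribute, trace, schema)
    return _normalize(input_tokens, norms)


def finite_difference_attributions(
    adapter: ModelAdapter,
    input_text: str,
    attribute: str,
    trace: GenerationTrace,
    schema: AttributeSchema = DEFAULT_SCHEMA,
    epsilon: float | None = None,
) -> np.ndarray:
    """Central finite-difference estimate of the InputXGrad norms.

    Perturbs every embedding coordinate of every input token by ±epsilon
    and differences the generated-token probability; the gradient estimate
    is then combined with the embeddings exactly as in
    :func:`raw_attributions`.  Independent of the analytic backward pass.
    """
    prompt_tokens, (lo, hi) = _prompt_parts(input_text, attribute, schema)
    n_input = hi - lo
    norms = np.zeros(n_input)
    for k, token in enumerate(trace.tokens):
        sequence = prompt_tokens + list(trace.tokens[:k])
        position = len(sequence) - 1
        base = adapter.embed_tokens(sequence)  # (L, d)
        if epsilon is None:
            epsilon = 1e-5 if base.dtype == np.float64 else 3e-3
        L, d = base.shape
        grad = np.zeros((n_input, d))
        # batch all ± perturbations for one input token at a time
        for i in range(n_input):
            batch = np.repeat(base[None, :, :], 2 * d, axis=0)
            for j in range(d):
                batch[2 * j, lo + i, j] += epsilon
                batch[2 * j + 1, lo + i, j] -= epsilon
            probs = adapter.token_prob_from_embeddings(batch, position, token)
            grad[i] = (probs[0::2] - probs[1::2]) / (2 * epsilon)
        contrib = grad * base[lo:hi]
        norms += np.linalg.norm(contrib, axis=-1)
    return norms


def bin_scores(saliency: SaliencyMap, n_bins: int = 5) -> SaliencyMap:
    """Assign display-intensity bins by equal-width partition of [0, max].

    Monotone: a higher score never receives a lower bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scores = np.asarray(saliency.scores)
    top = scores.max() if scores.size else 0.0
    if top <= 0:
        bins = np.zeros(len(scores), dtype=int)
    else:
        width = top / n_bins
        bins = np.minimum((scores / width).astype(int), n_bins - 1)
    return SaliencyMap(
        tokens=saliency.tokens, scores=saliency.scores, bins=tuple(int(b) for b in bins)
    )


def merge_word_scores(saliency: SaliencyMap) -> SaliencyMap:
    """Word-level display: merge consecutive sub-tokens of a word by summing.

    With the word-level tokenizer this is the identity; kept for sub-word
    backends where tokens carry a continuation marker ``##``.
    """
    tokens: list[str] = []
    scores: list[float] = []
    for t, s in zip(saliency.tokens, saliency.scores):
        if t.startswith("##") and tokens:
            tokens[-1] += t[2:]
            scores[-1] += s
        else:
            tokens.append(t)
            scores.append(s)
    return SaliencyMap(tokens=tuple(tokens), scores=tuple(scores))
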