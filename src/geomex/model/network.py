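"""A small decoder-only transformer language model in pure numpy.

The network follows the standard GPT-style architecture: learned token and
position embeddings, pre-layer-norm blocks of causal multi-head
self-attention and a position-wise MLP (ReLU by default, GELU optionally), a final layer norm and a logit projection
tied to the token-embedding matrix.  Forward, backward and the Adam update
are written out explicitly; the backward pass also returns the gradient of
the loss (or of a chosen token's probability) with respect to the input
token embeddings, which is what gradient-times-input saliency needs.

Arithmetic precision is configurable: float64 (default) lets analytic
gradients agree with central finite differences to near machine precision;
float32 roughly halves CPU training time and is what the shipped trainable
adapter uses.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

_NEG = -1e30  # additive mask value for disallowed attention links
_LN_EPS = 1e-5


@dataclass(frozen=True)
class ModelConfig:
    vocab_size: int
    d_model: int = 64
    n_heads: int = 2
    n_layers: int = 2
    d_ff: int = 256
    max_len: int = 512
    init_std: float = 0.02
    seed: int = 0
    dtype: str = "float64"
    activation: str = "relu"  # "relu" | "gelu"; relu is much cheaper on CPU

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")
        if self.activation not in ("relu", "gelu"):
            raise ValueError("activation must be relu or gelu")

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0).astype(x.dtype)


def _gelu(x: np.ndarray) -> np.ndarray:
    c = np.sqrt(2.0 / np.pi)
    return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * x**3)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    c = np.sqrt(2.0 / np.pi)
    u = c * (x + 0.044715 * x**3)
    t = np.tanh(u)
    du = c * (1.0 + 3 * 0.044715 * x**2)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * du


def _layernorm_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    n = xhat.shape[-1]
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dx = (
        dxhat - dxhat.mean(-1, keepdims=True) - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    ) * inv
    return dx, dg, db


class TransformerLM:
    """Trainable autoregressive LM over word-level token ids."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c, d = config, config.d_model
        std = c.init_std
        dt = c.np_dtype

        def w(*shape):
            return rng.normal(0.0, std, size=shape).astype(dt)

        self.params: dict[str, np.ndarray] = {
            "wte": w(c.vocab_size, d),
            "wpe": w(c.max_len, d),
            "lnf_g": np.ones(d, dtype=dt),
            "lnf_b": np.zeros(d, dtype=dt),
        }
        for i in range(c.n_layers):
            p = self.params
            p[f"l{i}_ln1_g"] = np.ones(d, dtype=dt)
            p[f"l{i}_ln1_b"] = np.zeros(d, dtype=dt)
            p[f"l{i}_wqkv"] = w(d, 3 * d)
            p[f"l{i}_bqkv"] = np.zeros(3 * d, dtype=dt)
            p[f"l{i}_wo"] = w(d, d)
            p[f"l{i}_bo"] = np.zeros(d, dtype=dt)
            p[f"l{i}_ln2_g"] = np.ones(d, dtype=dt)
            p[f"l{i}_ln2_b"] = np.zeros(d, dtype=dt)
            p[f"l{i}_w1"] = w(d, c.d_ff)
            p[f"l{i}_b1"] = np.zeros(c.d_ff, dtype=dt)
            p[f"l{i}_w2"] = w(c.d_ff, d)
            p[f"l{i}_b2"] = np.zeros(d, dtype=dt)
        self._act = _relu if c.activation == "relu" else _gelu
        self._act_grad = _relu_grad if c.activation == "relu" else _gelu_grad
        self._adam_m: dict[str, np.ndarray] | None = None
        self._adam_v: dict[str, np.ndarray] | None = None
        self._adam_t = 0

    def grow_vocab(self, n_new: int, seed: int = 0) -> None:
        """Append freshly initialized embedding rows for new vocabulary
        entries (used when online annotation introduces unseen words)."""
        if n_new <= 0:
            return
        c = self.config
        rng = np.random.default_rng(seed + c.vocab_size)
        rows = rng.normal(0.0, c.init_std, size=(n_new, c.d_model)).astype(c.np_dtype)
        self.params["wte"] = np.vstack([self.params["wte"], rows])
        if self._adam_m is not None:
            pad = np.zeros((n_new, c.d_model), dtype=c.np_dtype)
            self._adam_m["wte"] = np.vstack([self._adam_m["wte"], pad])
            self._adam_v["wte"] = np.vstack([self._adam_v["wte"], pad])
        self.config = replace(c, vocab_size=c.vocab_size + n_new)

    # ------------------------------------------------------------------ forward

    def embed(self, ids: np.ndarray) -> np.ndarray:
        """Token embeddings (without position) for an (B, L) id array."""
        return self.params["wte"][ids]

    def forward(
        self,
        ids: np.ndarray | None = None,
        pad_mask: np.ndarray | None = None,
        x_emb: np.ndarray | None = None,
    ):
        """Run the network, returning final hidden states and a cache.

        Either ``ids`` (B, L) or explicit input token embeddings ``x_emb``
        (B, L, d) must be given; position embeddings are added internally.
        ``pad_mask`` is True at real positions.
        """
        p, c = self.params, self.config
        if x_emb is None:
            if ids is None:
                raise ValueError("either ids or x_emb required")
            x_emb = p["wte"][ids]
        B, L, d = x_emb.shape
        if L > c.max_len:
            raise ValueError(f"sequence length {L} exceeds context {c.max_len}")
        x = x_emb + p["wpe"][:L]
        if pad_mask is None:
            pad_mask = np.ones((B, L), dtype=bool)
        # attention mask: query i may attend key j if j <= i and key is real
        causal = np.tril(np.ones((L, L), dtype=bool))
        att_mask = causal[None, None] & pad_mask[:, None, None, :]

        nh, dh = c.n_heads, d // c.n_heads
        layer_caches = []
        for i in range(c.n_layers):
            a, ln1c = _layernorm_forward(x, p[f"l{i}_ln1_g"], p[f"l{i}_ln1_b"])
            qkv = a @ p[f"l{i}_wqkv"] + p[f"l{i}_bqkv"]
            q, k, v = np.split(qkv, 3, axis=-1)

            def heads(t):
                return t.reshape(B, L, nh, dh).transpose(0, 2, 1, 3)

            qh, kh, vh = heads(q), heads(k), heads(v)
            scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh)
            scores = np.where(att_mask, scores, _NEG)
            scores -= scores.max(-1, keepdims=True)
            e = np.exp(scores)
            att = e / e.sum(-1, keepdims=True)
            oh = att @ vh
            o = oh.transpose(0, 2, 1, 3).reshape(B, L, d)
            proj = o @ p[f"l{i}_wo"] + p[f"l{i}_bo"]
            x_attn = x + proj

            m, ln2c = _layernorm_forward(x_attn, p[f"l{i}_ln2_g"], p[f"l{i}_ln2_b"])
            pre = m @ p[f"l{i}_w1"] + p[f"l{i}_b1"]
            h1 = self._act(pre)
            x_out = x_attn + h1 @ p[f"l{i}_w2"]
            x_out = x_out + p[f"l{i}_b2"]
            layer_caches.append((a, ln1c, qh, kh, vh, att, o, x, m, ln2c, pre, h1, x_attn))
            x = x_out

        hf, lnfc = _layernorm_forward(x, p["lnf_g"], p["lnf_b"])
        cache = {
            "ids": ids,
            "x_emb": x_emb,
            "pad_mask": pad_mask,
            "layers": layer_caches,
            "lnf": lnfc,
            "shape": (B, L, d),
        }
        return hf, cache

    def logits_at(self, hf: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Logits (tied to wte) at selected (batch, position) coordinates."""
        return hf[rows, cols] @ self.params["wte"].T

    # ----------------------------------------------------------------- backward

    def backward(self, cache, d_hf: np.ndarray):
        """Backprop ``d_hf`` (gradient at final hidden states) to parameters
        and to the input token embeddings.

        Returns ``(grads, dx_emb)`` where ``dx_emb`` has shape (B, L, d).
        Parameter gradients exclude any logit-projection contribution; the
        caller adds the tied-embedding term for ``wte`` itself.
        """
        p, c = self.params, self.config
        B, L, d = cache["shape"]
        nh, dh = c.n_heads, d // c.n_heads
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dx, dg, db = _layernorm_backward(d_hf, cache["lnf"])
        grads["lnf_g"] += dg
        grads["lnf_b"] += db

        for i in reversed(range(c.n_layers)):
            (a, ln1c, qh, kh, vh, att, o, x_in, m, ln2c, pre, h1, x_attn) = cache["layers"][i]
            # MLP block: x_out = x_attn + gelu(m @ w1 + b1) @ w2 + b2
            grads[f"l{i}_b2"] += dx.sum((0, 1))
            dh1 = dx @ p[f"l{i}_w2"].T
            grads[f"l{i}_w2"] += h1.reshape(-1, c.d_ff).T @ dx.reshape(-1, d)
            dpre = dh1 * self._act_grad(pre)
            grads[f"l{i}_b1"] += dpre.sum((0, 1))
            dm = dpre @ p[f"l{i}_w1"].T
            grads[f"l{i}_w1"] += m.reshape(-1, d).T @ dpre.reshape(-1, c.d_ff)
            dxa, dg, db = _layernorm_backward(dm, ln2c)
            grads[f"l{i}_ln2_g"] += dg
            grads[f"l{i}_ln2_b"] += db
            dx_attn = dx + dxa

            # attention block: x_attn = x_in + (att @ v heads) @ wo + bo
            grads[f"l{i}_bo"] += dx_attn.sum((0, 1))
            do = dx_attn @ p[f"l{i}_wo"].T
            grads[f"l{i}_wo"] += o.reshape(-1, d).T @ dx_attn.reshape(-1, d)
            doh = do.reshape(B, L, nh, dh).transpose(0, 2, 1, 3)
            datt = doh @ vh.transpose(0, 1, 3, 2)
            dvh = att.transpose(0, 1, 3, 2) @ doh
            dscores = att * (datt - (datt * att).sum(-1, keepdims=True))
            dqh = dscores @ kh / np.sqrt(dh)
            dkh = dscores.transpose(0, 1, 3, 2) @ qh / np.sqrt(dh)

            def merge(t):
                return t.transpose(0, 2, 1, 3).reshape(B, L, d)

            dqkv = np.concatenate([merge(dqh), merge(dkh), merge(dvh)], axis=-1)
            grads[f"l{i}_bqkv"] += dqkv.sum((0, 1))
            grads[f"l{i}_wqkv"] += a.reshape(-1, d).T @ dqkv.reshape(-1, 3 * d)
            da = dqkv @ p[f"l{i}_wqkv"].T
            dxi, dg, db = _layernorm_backward(da, ln1c)
            grads[f"l{i}_ln1_g"] += dg
            grads[f"l{i}_ln1_b"] += db
            dx = dx_attn + dxi

        # dx is now the gradient at x_emb + wpe
        grads["wpe"][:L] += dx.sum(0)
        dx_emb = dx
        if cache["ids"] is not None:
            np.add.at(grads["wte"], cache["ids"], dx_emb)
        return grads, dx_emb

    # ------------------------------------------------------------ loss/training

    def loss_and_grads(self, ids: np.ndarray, pad_mask: np.ndarray, loss_mask: np.ndarray):
        """Mean cross-entropy over masked next-token predictions.

        ``ids`` is (B, L); position t predicts token t+1.  ``loss_mask``
        is (B, L-1), True where the prediction of ids[:, t+1] contributes.
        """
        inputs = ids[:, :-1]
        targets = ids[:, 1:]
        hf, cache = self.forward(inputs, pad_mask=pad_mask[:, :-1])
        rows, cols = np.nonzero(loss_mask)
        if rows.size == 0:
            raise ValueError("empty loss mask")
        tgt = targets[rows, cols]
        logits = self.logits_at(hf, rows, cols)  # (S, V)
        logits = logits - logits.max(-1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(-1, keepdims=True)
        S = rows.size
        nll = -np.log(probs[np.arange(S), tgt] + 1e-300)
        loss = float(nll.mean())

        dlogits = probs
        dlogits[np.arange(S), tgt] -= 1.0
        dlogits /= S
        hsel = hf[rows, cols]
        d_hf = np.zeros_like(hf)
        d_hf[rows, cols] = dlogits @ self.params["wte"]
        grads, _ = self.backward(cache, d_hf)
        grads["wte"] += dlogits.T @ hsel
        return loss, grads

    def loss_only(self, ids, pad_mask, loss_mask) -> float:
        inputs = ids[:, :-1]
        targets = ids[:, 1:]
        hf, _ = self.forward(inputs, pad_mask=pad_mask[:, :-1])
        rows, cols = np.nonzero(loss_mask)
        tgt = targets[rows, cols]
        logits = self.logits_at(hf, rows, cols)
        logits = logits - logits.max(-1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(-1, keepdims=True)
        nll = -np.log(probs[np.arange(rows.size), tgt] + 1e-300)
        return float(nll.mean())

    def adam_step(self, grads, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_m is None:
            self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
            self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ------------------------------------------------------------- inference

    def next_token_distribution(self, ids: list[int] | np.ndarray) -> np.ndarray:
        """P(next token | prefix) for a single sequence of token ids."""
        arr = np.asarray(ids, dtype=np.int64)[None, :]
        hf, _ = self.forward(arr)
        logits = hf[0, -1] @ self.params["wte"].T
        logits = logits - logits.max()
        e = np.exp(logits)
        return e / e.sum()

    def token_prob_grad(self, ids: np.ndarray, position: int, target: int):
        """Gradient of P(target token at ``position``) w.r.t. input embeddings.

        Returns ``(prob, dx_emb, x_emb)`` for a single (L,) id sequence.
        """
        arr = np.asarray(ids, dtype=np.int64)[None, :]
        hf, cache = self.forward(arr)
        logits = hf[0, position] @ self.params["wte"].T
        logits = logits - logits.max()
        e = np.exp(logits)
        probs = e / e.sum()
        p_t = probs[target]
        # d p_t / d logits = p_t * (delta - probs)
        dlogits = -p_t * probs
        dlogits[target] += p_t
        d_hf = np.zeros_like(hf)
        d_hf[0, position] = dlogits @ self.params["wte"]
        _, dx_emb = self.backward(cache, d_hf)
        return float(p_t), dx_emb[0], cache["x_emb"][0].copy()

    def token_prob_from_embeddings(
        self, x_emb: np.ndarray, position: int, target: int
    ) -> np.ndarray:
        """P(target at ``position``) for a batch of explicit input embeddings."""
        hf, _ = self.forward(x_emb=x_emb)
        logits = hf[:, position] @ self.params["wte"].T
        logits = logits - logits.max(-1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(-1, keepdims=True)
        return probs[:, target]

    # ------------------------------------------------------------- persistence

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params)
        (directory / "model_config.json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, directory: str | Path) -> "TransformerLM":
        directory = Path(directory)
        config = ModelConfig(**json.loads((directory / "model_config.json").read_text()))
        model = cls(config)
        with np.load(directory / "weights.npz") as data:
            for k in model.params:
                model.params[k] = data[k]
        return model
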