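"""Filtering posterior: a small GPT2-style causal transformer.

q(z_t | x_{0:t}) = N(mu_t, sigma^2 I) where every mu_t is read off one
forward pass of a decoder-only transformer (learned token + position
embeddings, pre-norm blocks with single-head causal self-attention and a
4x GELU feed-forward, final layer norm, linear head to R^2). The causal
mask guarantees mu_t depends on x_{0:t} only, making the posterior a
filter rather than a smoother. The posterior scale sigma is one learned
global scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .exceptions import InvalidArgumentError
from .nn import LayerNorm, Linear, Module, gelu


@dataclass
class TransformerConfig:
    n_layers: int = 2
    n_heads: int = 1
    embed_dim: int = 32
    max_len: int = 91  # maximum token-sequence length (a T=90 window has 91 frames)
    token_in_dim: int = 4
    out_dim: int = 2

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise InvalidArgumentError("embed_dim must divide by n_heads")
        if self.n_layers < 0 or self.max_len < 1:
            raise InvalidArgumentError("bad transformer configuration")


def causal_mask(L: int) -> np.ndarray:
    """Additive mask: -inf strictly above the diagonal."""
    return np.triu(np.full((L, L), -np.inf), k=1)


def scaled_dot_attention(Q, K, V, mask=None):
    """softmax(Q K^T / sqrt(dK) + mask) V.

    Works on Tensors (differentiable) or plain arrays; Q, K, V have shape
    (..., L, d) with Q and K sharing the key dimension dK. Returns
    (outputs, weights).
    """
    plain = not any(isinstance(a, Tensor) for a in (Q, K, V))
    Q, K, V = (a if isinstance(a, Tensor) else Tensor(a) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise InvalidArgumentError(
            f"Q and K key dims differ: {Q.shape[-1]} vs {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise InvalidArgumentError("K and V sequence lengths differ")
    dK = Q.shape[-1]
    logits = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(dK))
    if mask is not None:
        logits = logits + Tensor(mask)
    weights = logits.softmax(axis=-1)
    out = weights @ V
    if plain:
        return out.data, weights.data
    return out, weights


class _Block(Module):
    """Pre-norm transformer block: x += attn(ln(x)); x += mlp(ln(x))."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        E = cfg.embed_dim
        self.cfg = cfg
        self.ln1 = LayerNorm(E)
        self.wq = Linear(E, E, rng)
        self.wk = Linear(E, E, rng)
        self.wv = Linear(E, E, rng)
        self.wo = Linear(E, E, rng)
        self.ln2 = LayerNorm(E)
        self.fc1 = Linear(E, 4 * E, rng)
        self.fc2 = Linear(4 * E, E, rng)
        self.last_weights: np.ndarray | None = None  # (B, H, L, L) cache

    def _heads(self, t: Tensor, B: int, L: int) -> Tensor:
        H = self.cfg.n_heads
        dh = self.cfg.embed_dim // H
        return t.reshape(B, L, H, dh).swapaxes(1, 2)  # (B, H, L, dh)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, E = x.shape
        h = self.ln1(x)
        q = self._heads(self.wq(h), B, L)
        k = self._heads(self.wk(h), B, L)
        v = self._heads(self.wv(h), B, L)
        att, w = scaled_dot_attention(q, k, v, mask)
        self.last_weights = w.data
        att = att.swapaxes(1, 2).reshape(B, L, E)
        x = x + self.wo(att)
        h = self.ln2(x)
        return x + self.fc2(gelu(self.fc1(h)))


class GPT2Posterior(Module):
    """phi: transformer weights plus the global posterior log-sd."""

    def __init__(self, config: TransformerConfig, rng: np.random.Generator,
                 init_q_sd: float = 0.1):
        self.config = config
        E = config.embed_dim
        self.tok_embed = Linear(config.token_in_dim, E, rng)
        self.pos_embed = Tensor(
            0.02 * rng.standard_normal((config.max_len, E)),
            requires_grad=True)
        self.blocks = [_Block(config, rng) for _ in range(config.n_layers)]
        self.ln_f = LayerNorm(E)
        self.head = Linear(E, config.out_dim, rng)
        self.q_log_sd = Tensor(float(np.log(init_q_sd)), requires_grad=True)

    @property
    def q_sd(self) -> float:
        return float(np.exp(self.q_log_sd.data))

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, L, 4) -> posterior means (B, L, 2)."""
        B, L, _ = x.shape
        if L > self.config.max_len:
            raise InvalidArgumentError(
                f"sequence length {L} exceeds max_len {self.config.max_len}")
        h = self.tok_embed(x) + self.pos_embed[:L]
        mask = causal_mask(L)
        for block in self.blocks:
            h = block(h, mask)
        return self.head(self.ln_f(h))

    def posterior_means(self, frames) -> np.ndarray:
        """mu_0..mu_{L-1} for one window (L, 4) or a batch (B, L, 4).

        Each mu_t is a function of x_{0:t} only (causal mask); inference
        is deterministic (no dropout anywhere in the model).
        """
        frames = np.asarray(frames, dtype=float)
        single = frames.ndim == 2
        if single:
            frames = frames[None]
        out = self.forward(Tensor(frames)).data
        return out[0] if single else out

    def attention_heatmap(self, window, layer_index: int = 0,
                          head: int = 0, row_span: tuple | None = None
                          ) -> np.ndarray:
        """L x L attention-weight matrix of one layer/head for a window.

        ``row_span=(a, b)`` returns the row slice [a, b) — e.g. (50, 90)
        restricts the view to recent queries, away from remote-past rows.
        """
        if not (0 <= layer_index < self.config.n_layers):
            raise InvalidArgumentError(
                f"layer_index {layer_index} out of range "
                f"[0, {self.config.n_layers})")
        window = np.asarray(window, dtype=float)
        self.forward(Tensor(window[None]))
        w = self.blocks[layer_index].last_weights[0, head]
        if row_span is not None:
            a, b = row_span
            w = w[a:b]
        return w


def sample_posterior(means, q_log_sd: float, seed: int) -> np.ndarray:
    """Reparameterized draw z_t = mu_t + exp(q_log_sd) eps_t, seeded."""
    means = np.asarray(means, dtype=float)
    rng = np.random.default_rng(seed)
    return means + np.exp(q_log_sd) * rng.standard_normal(means.shape)
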