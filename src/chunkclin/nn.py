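"""Neural building blocks: a small BERT-style transformer encoder.

The backbone is a standard post-norm transformer encoder (token + learned
position embeddings, multi-head self-attention, GELU feed-forward,
residual connections, layer norm) exposing every layer's hidden states so
chunk embeddings can average the last layers. A causal attention mode
supports next-token (causal LM) adaptation.

The default configuration is a deliberately tiny backbone (2 layers,
width 32, 2 heads) suitable for CPU-scale experiments; any encoder
honouring the same interface (per-layer states, pad masking) can stand in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Adam, Parameter, Tensor


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = a.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(rng.normal(0.0, 0.02, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.W = Parameter(rng.normal(0.0, 0.02, size=(n_vocab, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.W[ids]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


def gelu(x: Tensor) -> Tensor:
    # tanh approximation of GELU
    inner = 0.7978845608028654 * (x + 0.044715 * x * x * x)
    return 0.5 * x * (1.0 + inner.tanh())


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("width must be divisible by the head count")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, attn_bias: np.ndarray) -> Tensor:
        """x: (B, L, D); attn_bias: additive (B, 1, L) or (B, L, L) mask."""
        B, L, D = x.shape
        H, Hd = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B, L, D) -> (B, H, L, Hd)
            return t.reshape(B, L, H, Hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(Hd))
        bias = attn_bias[:, None, :, :] if attn_bias.ndim == 3 else attn_bias
        attn = (scores + Tensor(bias)).softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.out(ctx)


class TransformerLayer(Module):
    def __init__(self, dim: int, n_heads: int, ffn_dim: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln1 = LayerNorm(dim)
        self.fc1 = Linear(dim, ffn_dim, rng)
        self.fc2 = Linear(ffn_dim, dim, rng)
        self.ln2 = LayerNorm(dim)

    def __call__(self, x: Tensor, attn_bias: np.ndarray) -> Tensor:
        x = self.ln1(x + self.attn(x, attn_bias))
        x = self.ln2(x + self.fc2(gelu(self.fc1(x))))
        return x


@dataclass
class BackboneConfig:
    vocab_size: int
    width: int = 32
    n_layers: int = 2
    n_heads: int = 2
    ffn_dim: int = 64
    max_len: int = 512
    seed: int = 0


class TinyEncoder(Module):
    """Small BERT-style encoder exposing per-layer hidden states."""

    def __init__(self, config: BackboneConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.tok = Embedding(config.vocab_size, config.width, rng)
        self.pos = Embedding(config.max_len, config.width, rng)
        self.ln_in = LayerNorm(config.width)
        self.layers = [
            TransformerLayer(config.width, config.n_heads, config.ffn_dim, rng)
            for _ in range(config.n_layers)
        ]

    @property
    def n_layers(self) -> int:
        return self.config.n_layers

    def forward(
        self, ids: np.ndarray, pad_mask: np.ndarray, causal: bool = False
    ) -> list[Tensor]:
        """ids, pad_mask: (B, L); returns hidden states after each layer.

        pad_mask is 1 for real tokens, 0 for padding. Padding keys (and, in
        causal mode, future positions) get a large negative attention bias.
        """
        B, L = ids.shape
        bias = np.where(pad_mask[:, None, :] > 0, 0.0, -1e9)  # (B, 1, L)
        if causal:
            future = np.triu(np.full((L, L), -1e9), k=1)  # (L, L)
            bias = bias + future[None, :, :]  # (B, L, L)
        x = self.ln_in(self.tok(ids) + self.pos(np.arange(L)[None, :].repeat(B, axis=0)))
        states: list[Tensor] = []
        for layer in self.layers:
            x = layer(x, bias)
            states.append(x)
        return states


def make_optimizer(modules: list[Module], lr: float) -> Adam:
    params: list[Parameter] = []
    for m in modules:
        params.extend(m.parameters())
    return Adam(params, lr=lr)
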