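"""Minimal NumPy layers with explicit forward/backward passes.

The network is small (one attention pooler + two shallow MLPs), so gradients
are written by hand rather than pulling in an autodiff framework.  Each layer
accumulates parameter gradients into ``.grads`` (same order as ``.params``);
``zero_grad`` resets them.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigError, DataError


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Linear:
    """Affine map x @ W + b, with W of shape (n_in, n_out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _he_init(rng, n_in, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.gb]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return x @ self.W + self.b, x

    def backward(self, g_out: np.ndarray, cache: np.ndarray) -> np.ndarray:
        self.gW += cache.T @ g_out
        self.gb += g_out.sum(axis=0)
        return g_out @ self.W.T


def hidden_widths(n_in: int, n_out: int, depth: int) -> list[int]:
    """Geometric interpolation of layer widths between input and output."""
    if depth < 1:
        raise ConfigError(f"depth must be >= 1, got {depth}")
    widths = [
        max(1, round(n_in ** (1 - t) * n_out**t))
        for t in (i / depth for i in range(1, depth))
    ]
    return [n_in, *widths, n_out]


class MLP:
    """ReLU MLP (no activation on the output layer); optional dropout on
    hidden activations during training."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        depth: int,
        rng: np.random.Generator,
        dropout: float = 0.0,
    ):
        widths = hidden_widths(n_in, n_out, depth)
        self.layers = [Linear(widths[i], widths[i + 1], rng) for i in range(depth)]
        self.dropout = dropout
        self.n_in = n_in
        self.n_out = n_out

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise DataError(
                f"MLP expected input width {self.n_in}, got shape {tuple(x.shape)}"
            )
        caches = []
        h = x
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            h, lin_cache = layer.forward(h)
            relu_mask = None
            drop_mask = None
            if i != last:
                relu_mask = h > 0
                h = h * relu_mask
                if train and self.dropout > 0:
                    if rng is None:
                        raise ConfigError("dropout requires an RNG during training")
                    drop_mask = rng.random(h.shape) >= self.dropout
                    h = h * drop_mask / (1.0 - self.dropout)
            caches.append((lin_cache, relu_mask, drop_mask))
        return h, caches

    def backward(self, g_out: np.ndarray, caches: list) -> np.ndarray:
        g = g_out
        for layer, (lin_cache, relu_mask, drop_mask) in zip(
            reversed(self.layers), reversed(caches)
        ):
            if drop_mask is not None:
                g = g * drop_mask / (1.0 - self.dropout)
            if relu_mask is not None:
                g = g * relu_mask
            g = layer.backward(g, lin_cache)
        return g


def masked_softmax(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Softmax over the last axis, restricted to mask==True positions."""
    s = np.where(mask, scores, -np.inf)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    e = np.where(mask, e, 0.0)
    return e / e.sum(axis=-1, keepdims=True)


class AttentionPooler:
    """Multi-head attention pooling with one learned query per head.

    Residue embeddings (B, L, E) are projected to keys and values per head;
    a learned query scores each residue, softmax weights aggregate the
    values, and heads are concatenated (or averaged) into the pooled vector.
    Padding positions are excluded via the mask.
    """

    def __init__(
        self,
        embed_width: int,
        n_heads: int,
        key_width: int,
        value_width: int,
        rng: np.random.Generator,
        head_merge: str = "concat",
    ):
        E, H, dk, dv = embed_width, n_heads, key_width, value_width
        self.Wk = _he_init(rng, E, (H, E, dk))
        self.Wv = _he_init(rng, E, (H, E, dv))
        self.q = rng.standard_normal((H, dk)) / np.sqrt(dk)
        self.gWk = np.zeros_like(self.Wk)
        self.gWv = np.zeros_like(self.Wv)
        self.gq = np.zeros_like(self.q)
        self.n_heads = H
        self.embed_width = E
        self.key_width = dk
        self.value_width = dv
        self.head_merge = head_merge
        self.out_width = H * dv if head_merge == "concat" else dv

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wk, self.Wv, self.q]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.gWk, self.gWv, self.gq]

    def forward(
        self, M: np.ndarray, mask: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, tuple]:
        """Pool (B, L, E) matrices -> (pooled (B, out), attention (B, H, L))."""
        if M.ndim != 3 or M.shape[2] != self.embed_width:
            raise DataError(
                f"pooler expected (B, L, {self.embed_width}), got {tuple(M.shape)}"
            )
        if M.shape[1] == 0 or not mask.any(axis=1).all():
            raise DataError("attention pooling requires at least one residue")
        scale = 1.0 / np.sqrt(self.key_width)
        K = np.einsum("ble,hek->bhlk", M, self.Wk)
        scores = np.einsum("bhlk,hk->bhl", K, self.q) * scale
        attn = masked_softmax(scores, mask[:, None, :])
        V = np.einsum("ble,hev->bhlv", M, self.Wv)
        heads = np.einsum("bhl,bhlv->bhv", attn, V)
        if self.head_merge == "concat":
            pooled = heads.reshape(M.shape[0], -1)
        else:
            pooled = heads.mean(axis=1)
        return pooled, attn, (M, K, attn, V)

    def backward(self, g_pooled: np.ndarray, cache: tuple) -> None:
        M, K, attn, V = cache
        B, H = attn.shape[0], self.n_heads
        scale = 1.0 / np.sqrt(self.key_width)
        if self.head_merge == "concat":
            g_heads = g_pooled.reshape(B, H, self.value_width)
        else:
            g_heads = np.repeat(g_pooled[:, None, :], H, axis=1) / H
        g_attn = np.einsum("bhv,bhlv->bhl", g_heads, V)
        g_V = np.einsum("bhl,bhv->bhlv", attn, g_heads)
        self.gWv += np.einsum("ble,bhlv->hev", M, g_V)
        # softmax backward: padded positions have attn == 0, so they vanish
        g_scores = attn * (g_attn - np.sum(attn * g_attn, axis=-1, keepdims=True))
        self.gq += np.einsum("bhlk,bhl->hk", K, g_scores) * scale
        g_K = np.einsum("bhl,hk->bhlk", g_scores, self.q) * scale
        self.gWk += np.einsum("ble,bhlk->hek", M, g_K)


def pad_stack(matrices: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length (L_i, E) matrices into (B, Lmax, E) + mask."""
    if not matrices:
        raise DataError("cannot stack an empty list of matrices")
    lengths = [m.shape[0] for m in matrices]
    E = matrices[0].shape[1]
    Lmax = max(lengths)
    out = np.zeros((len(matrices), Lmax, E))
    mask = np.zeros((len(matrices), Lmax), dtype=bool)
    for i, m in enumerate(matrices):
        out[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = True
    return out, mask
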