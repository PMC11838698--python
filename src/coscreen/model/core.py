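"""Co-embedding model and scoring heads.

Interaction probability is sigmoid(alpha * cosine(Zd, Zt)); predicted
affinity (pK) is the raw dot product Zd . Zt.  Classification therefore
lives on the unit sphere while regression uses unnormalized latents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DataError
from ..featurizers import ResidueEmbeddingMatrix
from .config import ModelConfig
from .layers import MLP, AttentionPooler, pad_stack


@dataclass(frozen=True)
class CoEmbedding:
    """A drug or target vector in the shared latent space."""

    owner_id: str
    vector: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=np.float64)
        object.__setattr__(self, "vector", v)
        if v.ndim != 1:
            raise DataError("co-embedding vector must be 1-D")
        if self.normalized and abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise DataError(f"vector flagged normalized but has norm {np.linalg.norm(v)}")

    def unit(self) -> "CoEmbedding":
        n = np.linalg.norm(self.vector)
        if n == 0:
            raise DataError(f"cannot normalize zero vector for {self.owner_id!r}")
        return CoEmbedding(self.owner_id, self.vector / n, normalized=True)


@dataclass(frozen=True)
class AttentionMap:
    """Per-head, per-residue pooling attention; each head's row sums to 1."""

    target_id: str
    weights: np.ndarray  # (H, L)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2:
            raise DataError("attention weights must be (H, L)")
        if np.any(w < -1e-12):
            raise DataError("attention weights must be non-negative")
        sums = w.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise DataError(f"attention head rows must sum to 1, got {sums}")

    @property
    def n_heads(self) -> int:
        return self.weights.shape[0]

    @property
    def length(self) -> int:
        return self.weights.shape[1]


# ---------------------------------------------------------------------------
# Scoring heads (pure functions)
# ---------------------------------------------------------------------------


def _as_vector(z: CoEmbedding | np.ndarray) -> np.ndarray:
    return z.vector if isinstance(z, CoEmbedding) else np.asarray(z, dtype=np.float64)


def cosine(zd: CoEmbedding | np.ndarray, zt: CoEmbedding | np.ndarray) -> float:
    a, b = _as_vector(zd), _as_vector(zt)
    if a.shape != b.shape:
        raise DataError(f"width mismatch: {a.shape[0]} vs {b.shape[0]}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("cosine undefined for zero vector")
    return float(a @ b / (na * nb))


def interaction_probability(
    zd: CoEmbedding | np.ndarray, zt: CoEmbedding | np.ndarray, alpha: float = 5.0
) -> float:
    """P(interaction) = sigmoid(alpha * cosine(zd, zt)).

    Invariant to positive rescaling of either vector and strictly
    increasing in the cosine; for alpha = 5 outputs lie in
    [sigmoid(-5), sigmoid(5)].
    """
    c = cosine(zd, zt)
    return float(1.0 / (1.0 + np.exp(-alpha * c)))


def predict_affinity(zd: CoEmbedding | np.ndarray, zt: CoEmbedding | np.ndarray) -> float:
    """Predicted pK = Zd . Zt on the raw (unnormalized) latents."""
    a, b = _as_vector(zd), _as_vector(zt)
    if a.shape != b.shape:
        raise DataError(f"width mismatch: {a.shape[0]} vs {b.shape[0]}")
    return float(a @ b)


def bce_loss(
    probabilities: np.ndarray, labels: np.ndarray, eps: float = 1e-7
) -> float:
    """Mean binary cross-entropy; probabilities clipped to [eps, 1-eps]."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise DataError(f"length mismatch: {p.shape} vs {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("labels must be 0 or 1")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def mse_loss(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean squared error."""
    a = np.asarray(predicted, dtype=np.float64)
    b = np.asarray(observed, dtype=np.float64)
    if a.shape != b.shape:
        raise DataError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------


class DTICoEmbedder:
    """Attention pooler + projection MLPs Cd / Ct with both scoring heads.

    All learnable parameters are initialized from ``config.seed``; two
    builds with the same config produce identical initial weights.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
        self.pooler = AttentionPooler(
            embed_width=config.embed_width,
            n_heads=config.n_heads,
            key_width=config.key_width,
            value_width=config.value_width,
            rng=rng,
            head_merge=config.head_merge,
        )
        self.drug_net = MLP(
            config.n_bits, config.d, config.drug_depth, rng, dropout=config.dropout
        )
        self.target_net = MLP(
            config.pooled_width, config.d, config.target_depth, rng, dropout=config.dropout
        )

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return self.pooler.params + self.drug_net.params + self.target_net.params

    @property
    def grads(self) -> list[np.ndarray]:
        return self.pooler.grads + self.drug_net.grads + self.target_net.grads

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def set_params(self, values: list[np.ndarray]) -> None:
        own = self.params
        if len(values) != len(own):
            raise DataError(f"expected {len(own)} parameter arrays, got {len(values)}")
        for p, v in zip(own, values):
            if p.shape != v.shape:
                raise DataError(f"parameter shape mismatch: {p.shape} vs {v.shape}")
            p[...] = v

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    # -- encoding -----------------------------------------------------------

    def embed_drugs(
        self, fingerprints: np.ndarray, train: bool = False, rng=None
    ) -> tuple[np.ndarray, list]:
        X = np.asarray(fingerprints, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        return self.drug_net.forward(X, train=train, rng=rng)

    def embed_targets(
        self,
        matrices: list[np.ndarray],
        train: bool = False,
        rng=None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple]:
        """Pool + project residue matrices.

        Returns (Z (B, d), attention (B, H, Lmax), mask, cache).
        """
        Mb, mask = pad_stack(matrices)
        pooled, attn, pool_cache = self.pooler.forward(Mb, mask)
        Z, net_cache = self.target_net.forward(pooled, train=train, rng=rng)
        return Z, attn, mask, (pool_cache, net_cache)

    def backward_targets(self, g_Z: np.ndarray, cache: tuple) -> None:
        pool_cache, net_cache = cache
        g_pooled = self.target_net.backward(g_Z, net_cache)
        self.pooler.backward(g_pooled, pool_cache)

    def attention_map(self, embeddings: ResidueEmbeddingMatrix) -> AttentionMap:
        _, attn, _, _ = self.embed_targets([embeddings.values])
        return AttentionMap(target_id=embeddings.target_id, weights=attn[0])

    # -- pairwise scoring (inference) --------------------------------------

    def score_pairs(
        self, zd: np.ndarray, zt: np.ndarray, task: str = "classify"
    ) -> np.ndarray:
        """Vectorized row-wise scoring of matched (zd_i, zt_i) pairs."""
        zd = np.atleast_2d(zd)
        zt = np.atleast_2d(zt)
        if zd.shape != zt.shape:
            raise DataError(f"shape mismatch: {zd.shape} vs {zt.shape}")
        if task == "classify":
            c = _row_cosine(zd, zt)
            return 1.0 / (1.0 + np.exp(-self.config.alpha * c))
        if task == "regress":
            return np.sum(zd * zt, axis=1)
        raise DataError(f"unknown task {task!r}")


def _row_cosine(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise DataError("cosine undefined for zero vector")
    return np.sum(A * B, axis=1) / (na * nb)


# ---------------------------------------------------------------------------
# Functional wrappers matching the operation-level contracts
# ---------------------------------------------------------------------------


def attention_pool(
    embeddings: ResidueEmbeddingMatrix, pooler: AttentionPooler
) -> tuple[np.ndarray, AttentionMap]:
    """Pool one residue matrix; returns (pooled vector, attention map)."""
    if embeddings.length == 0:
        raise DataError("cannot pool an empty residue matrix")
    Mb, mask = pad_stack([embeddings.values])
    pooled, attn, _ = pooler.forward(Mb, mask)
    return pooled[0], AttentionMap(target_id=embeddings.target_id, weights=attn[0])


def co_embed_drug(
    fingerprint: np.ndarray, model: DTICoEmbedder, drug_id: str = ""
) -> CoEmbedding:
    fp = np.asarray(fingerprint, dtype=np.float64)
    if fp.ndim != 1 or fp.shape[0] != model.config.n_bits:
        raise DataError(
            f"expected fingerprint of width {model.config.n_bits}, got "
            f"{tuple(fp.shape)}"
        )
    Z, _ = model.embed_drugs(fp)
    return CoEmbedding(owner_id=drug_id, vector=Z[0])


def co_embed_target(
    pooled_or_matrix: ResidueEmbeddingMatrix | np.ndarray,
    model: DTICoEmbedder,
    target_id: str = "",
) -> CoEmbedding:
    if isinstance(pooled_or_matrix, ResidueEmbeddingMatrix):
        Z, _, _, _ = model.embed_targets([pooled_or_matrix.values])
        owner = pooled_or_matrix.target_id or target_id
        return CoEmbedding(owner_id=owner, vector=Z[0])
    pooled = np.asarray(pooled_or_matrix, dtype=np.float64)
    if pooled.ndim != 1 or pooled.shape[0] != model.config.pooled_width:
        raise DataError(
            f"expected pooled vector of width {model.config.pooled_width}, got "
            f"{tuple(pooled.shape)}"
        )
    Z, _ = model.target_net.forward(pooled[None, :])
    return CoEmbedding(owner_id=target_id, vector=Z[0])
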