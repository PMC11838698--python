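"""Co-embedding vector store and top-k search.

The exact backend is a brute-force scan over an (n, d) matrix and serves as
the correctness oracle for any approximate backend registered through the
same interface.  Vectors are unit-normalized at insertion for cosine
(classification-geometry) search; an ``inner_product`` mode stores raw
vectors for affinity-style ranking, which orders differently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataError, IntegrityError
from .model.core import CoEmbedding


@dataclass
class EmbeddingIndex:
    """Exact top-k index over co-embedding vectors.

    Ties in score are broken by insertion order (the order ids were added),
    which is stable and documented.
    """

    ids: list[str]
    vectors: np.ndarray  # (n, d)
    metric: str = "cosine"  # cosine | inner_product
    model_fingerprint: str = ""
    backend: str = "exact"
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


def build_index(
    embeddings: Iterable[CoEmbedding] | Sequence[tuple[str, np.ndarray]],
    metric: str = "cosine",
    model_fingerprint: str = "",
) -> EmbeddingIndex:
    """Build an exact index; cosine mode unit-normalizes at insertion."""
    if metric not in ("cosine", "inner_product"):
        raise ConfigError(f"metric must be cosine|inner_product, got {metric!r}")
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for item in embeddings:
        if isinstance(item, CoEmbedding):
            item_id, vec = item.owner_id, item.vector
        else:
            item_id, vec = item
        vec = np.asarray(vec, dtype=np.float64)
        if rows and vec.shape[0] != rows[0].shape[0]:
            raise DataError(
                f"width mismatch for {item_id!r}: {vec.shape[0]} vs {rows[0].shape[0]}"
            )
        if item_id in set(ids):
            raise DataError(f"duplicate id {item_id!r}")
        if metric == "cosine":
            norm = np.linalg.norm(vec)
            if norm == 0:
                raise DataError(f"zero vector for {item_id!r} cannot be normalized")
            vec = vec / norm
        ids.append(item_id)
        rows.append(vec)
    if not rows:
        raise DataError("cannot build an empty index")
    return EmbeddingIndex(
        ids=ids,
        vectors=np.stack(rows),
        metric=metric,
        model_fingerprint=model_fingerprint,
        metadata={"n": len(ids), "d": rows[0].shape[0]},
    )


def query_topk(
    index: EmbeddingIndex, query: CoEmbedding | np.ndarray, k: int
) -> list[tuple[str, float]]:
    """Exact top-k by descending score; k > n returns all n items."""
    if k < 0:
        raise ConfigError(f"k must be non-negative, got {k}")
    if k == 0:
        return []
    q = query.vector if isinstance(query, CoEmbedding) else np.asarray(query, dtype=np.float64)
    if q.shape[0] != index.d:
        raise DataError(f"query width {q.shape[0]} != index width {index.d}")
    if index.metric == "cosine":
        norm = np.linalg.norm(q)
        if norm == 0:
            raise DataError("zero query vector")
        q = q / norm
    scores = index.vectors @ q
    k = min(k, index.n)
    order = np.argsort(-scores, kind="stable")[:k]
    return [(index.ids[i], float(scores[i])) for i in order]


def screen_matrix(
    query_embeddings: Sequence[CoEmbedding],
    index: EmbeddingIndex,
    k: int,
    query_model_fingerprint: str = "",
) -> dict[str, list[tuple[str, float]]]:
    """Top-k hits for every query; identical to per-query calls.

    Both sides must come from the same model: fingerprints are compared
    when provided on both sides.
    """
    if (
        query_model_fingerprint
        and index.model_fingerprint
        and query_model_fingerprint != index.model_fingerprint
    ):
        raise DataError(
            "model fingerprint mismatch between queries "
            f"({query_model_fingerprint}) and index ({index.model_fingerprint})"
        )
    return {q.owner_id: query_topk(index, q, k) for q in query_embeddings}


# ---------------------------------------------------------------------------
# Persistence: ids as text, vectors as a named-array container, metadata JSON
# ---------------------------------------------------------------------------


def save_index(index: EmbeddingIndex, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "ids.txt").write_text("".join(i + "\n" for i in index.ids))
    np.savez(directory / "vectors.npz", vectors=index.vectors)
    meta = {
        "metric": index.metric,
        "backend": index.backend,
        "model_fingerprint": index.model_fingerprint,
        "n": index.n,
        "d": index.d,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_index(directory: str | Path) -> EmbeddingIndex:
    directory = Path(directory)
    try:
        ids = (directory / "ids.txt").read_text().splitlines()
        with np.load(directory / "vectors.npz") as data:
            vectors = data["vectors"]
        meta = json.loads((directory / "metadata.json").read_text())
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise IntegrityError(f"cannot load index from {directory}: {exc}") from exc
    if len(ids) != vectors.shape[0] or meta.get("n") != len(ids):
        raise IntegrityError(f"index at {directory} is inconsistent")
    return EmbeddingIndex(
        ids=ids,
        vectors=vectors,
        metric=meta["metric"],
        backend=meta.get("backend", "exact"),
        model_fingerprint=meta.get("model_fingerprint", ""),
        metadata=meta,
    )


def recall_at_k(
    approx_results: dict[str, list[tuple[str, float]]],
    exact_results: dict[str, list[tuple[str, float]]],
) -> float:
    """Mean fraction of exact top-k ids recovered by an approximate backend."""
    if set(approx_results) != set(exact_results):
        raise DataError("query id sets differ between backends")
    recalls = []
    for qid, exact in exact_results.items():
        exact_ids = {i for i, _ in exact}
        approx_ids = {i for i, _ in approx_results[qid]}
        recalls.append(len(exact_ids & approx_ids) / max(1, len(exact_ids)))
    return float(np.mean(recalls))
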