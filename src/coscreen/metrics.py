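"""Virtual-screening and classification metrics.

AUROC (tie-aware Mann-Whitney), AUPR (step-wise summation), BEDROC at
configurable alpha, and enrichment factor at configurable top fractions.
Ranking ties are broken by descending score then stable input order, and
BEDROC is normalized by the exact best/worst attainable rank sums so that
a perfect ranking scores 1 and the worst scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import DataError

#: default exponential weight for early recognition.  Field convention for
#: the benchmarks this mirrors is 85; some reports print 0.85 — both are
#: valid inputs here.
DEFAULT_BEDROC_ALPHA = 85.0


@dataclass(frozen=True)
class RankedScreen:
    """A scored screen: ids, scores (higher = more active), binary labels."""

    item_ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(np.int8))
        if not (len(self.item_ids) == scores.shape[0] == labels.shape[0]):
            raise DataError("ids, scores, labels must have equal lengths")
        if not np.isin(labels, (0, 1)).all():
            raise DataError("labels must be 0 or 1")

    @classmethod
    def from_arrays(cls, scores, labels, item_ids=None) -> "RankedScreen":
        scores = np.asarray(scores, dtype=np.float64)
        if item_ids is None:
            item_ids = tuple(f"item_{i}" for i in range(scores.shape[0]))
        return cls(item_ids=tuple(item_ids), scores=scores, labels=np.asarray(labels))

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    def ranking(self) -> np.ndarray:
        """Indices sorted by descending score; ties keep input order."""
        return np.argsort(-self.scores, kind="stable")


def _require_both_classes(screen: RankedScreen, metric: str) -> None:
    if screen.n_pos == 0 or screen.n_pos == screen.n:
        raise DataError(
            f"{metric} requires both classes; got {screen.n_pos} positives "
            f"of {screen.n}"
        )


def auroc(screen: RankedScreen) -> float:
    """Area under the ROC curve via the normalized Mann-Whitney U statistic.

    Equivalent to the probability that a random positive outscores a random
    negative, with ties counting 1/2.
    """
    _require_both_classes(screen, "auroc")
    ranks = rankdata(screen.scores)  # average ranks handle ties
    n_pos = screen.n_pos
    n_neg = screen.n - n_pos
    u = ranks[screen.labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(screen: RankedScreen) -> float:
    """Area under the precision-recall curve by step-wise summation.

    Sum over positives of precision at that positive's rank, divided by the
    number of positives; ties broken by descending score then input order.
    """
    if screen.n_pos == 0:
        raise DataError("auprc requires at least one positive")
    order = screen.ranking()
    y = screen.labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, screen.n + 1)
    return float(precision[y == 1].sum() / screen.n_pos)


def _rie_sum(ranks: np.ndarray, alpha: float, n_total: int) -> float:
    """Sum over actives of exp(-alpha * r / N) at 1-based ranks."""
    return float(np.exp(-alpha * ranks / n_total).sum())


def bedroc(screen: RankedScreen, alpha: float = DEFAULT_BEDROC_ALPHA) -> float:
    """Boltzmann-enhanced discrimination of ROC.

    The exponential rank sum over actives is affinely mapped by its exact
    minimum and maximum attainable values at the given (N, n_actives), so
    all-actives-first -> 1 and all-actives-last -> 0.
    """
    if alpha <= 0:
        raise DataError(f"bedroc alpha must be positive, got {alpha}")
    _require_both_classes(screen, "bedroc")
    N, n = screen.n, screen.n_pos
    order = screen.ranking()
    active_ranks = np.flatnonzero(screen.labels[order] == 1) + 1  # 1-based
    s = _rie_sum(active_ranks, alpha, N)
    best = _rie_sum(np.arange(1, n + 1), alpha, N)
    worst = _rie_sum(np.arange(N - n + 1, N + 1), alpha, N)
    return float((s - worst) / (best - worst))


def enrichment_factor(screen: RankedScreen, fraction: float) -> float:
    """EF at a top fraction: active rate in the top ceil(fraction*N) items
    relative to the overall active rate."""
    if not 0.0 < fraction < 1.0:
        raise DataError(f"fraction must be in (0, 1), got {fraction}")
    if screen.n_pos == 0:
        raise DataError("enrichment_factor requires at least one positive")
    top = int(np.ceil(fraction * screen.n))
    order = screen.ranking()
    hits = int(screen.labels[order[:top]].sum())
    return float((hits / top) / (screen.n_pos / screen.n))


def screen_report(
    screen: RankedScreen,
    ef_fractions: tuple[float, ...] = (0.005, 0.01, 0.05),
    bedroc_alpha: float = DEFAULT_BEDROC_ALPHA,
) -> dict[str, float]:
    """All metrics for one screen, keyed for machine-readable output."""
    report = {
        "auroc": auroc(screen),
        "auprc": auprc(screen),
        f"bedroc_alpha_{bedroc_alpha:g}": bedroc(screen, bedroc_alpha),
    }
    for f in ef_fractions:
        report[f"ef_{f * 100:g}pct"] = enrichment_factor(screen, f)
    return report
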