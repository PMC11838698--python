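"""Interaction records, Kd-threshold labeling, and negative sampling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ..errors import DataError


@dataclass(frozen=True)
class InteractionRecord:
    """One drug-target pair with either a binary label or an affinity pK.

    ``source`` records whether the pair was measured or sampled as a
    negative during dataset assembly.
    """

    drug_id: str
    target_id: str
    label: Optional[int] = None
    pK: Optional[float] = None
    source: str = "measured"

    def __post_init__(self) -> None:
        if (self.label is None) == (self.pK is None):
            raise DataError(
                f"({self.drug_id}, {self.target_id}): exactly one of label/pK "
                "must be present"
            )
        if self.label is not None and self.label not in (0, 1):
            raise DataError(f"label must be 0 or 1, got {self.label}")
        if self.source not in ("measured", "sampled_negative"):
            raise DataError(f"unknown source {self.source!r}")


def label_from_kd(kd: float, threshold: float = 30.0) -> int:
    """Binary label from a dissociation constant: 1 iff kd < threshold.

    The boundary value is non-interacting (kd >= threshold -> 0).  The
    threshold is in the dataset's native units (nM for the usual DTI
    benchmarks); record units in dataset metadata.
    """
    if kd <= 0:
        raise DataError(f"Kd must be positive, got {kd}")
    if threshold <= 0:
        raise DataError(f"threshold must be positive, got {threshold}")
    return 1 if kd < threshold else 0


def sample_negatives(
    positives: Iterable[tuple[str, str]],
    drugs: Sequence[str],
    targets: Sequence[str],
    ratio: float = 1.0,
    seed: int = 0,
) -> list[InteractionRecord]:
    """Sample floor(ratio * n_pos) non-positive pairs uniformly without
    replacement from drugs x targets, deterministically for a given seed."""
    if ratio <= 0:
        raise DataError(f"ratio must be positive, got {ratio}")
    pos = set(positives)
    drugs = list(dict.fromkeys(drugs))
    targets = list(dict.fromkeys(targets))
    n_universe = len(drugs) * len(targets)
    n_available = n_universe - len(pos)
    n_wanted = int(np.floor(ratio * len(pos)))
    if n_wanted > n_available:
        raise DataError(
            f"requested {n_wanted} negatives but only {n_available} "
            f"non-positive pairs exist ({len(drugs)} drugs x {len(targets)} "
            f"targets, {len(pos)} positives)"
        )
    rng = np.random.default_rng(seed)
    # sample flat pair indices without replacement, then drop positives and
    # top up until the quota is met; still uniform over eligible pairs
    chosen: list[tuple[str, str]] = []
    seen: set[int] = set()
    while len(chosen) < n_wanted:
        need = n_wanted - len(chosen)
        batch = rng.integers(0, n_universe, size=max(2 * need, 16))
        for flat in batch:
            flat = int(flat)
            if flat in seen:
                continue
            seen.add(flat)
            pair = (drugs[flat // len(targets)], targets[flat % len(targets)])
            if pair in pos:
                continue
            chosen.append(pair)
            if len(chosen) == n_wanted:
                break
    return [
        InteractionRecord(drug_id=d, target_id=t, label=0, source="sampled_negative")
        for d, t in chosen
    ]


def balance_positives_negatives(
    records: Sequence[InteractionRecord], seed: int = 0
) -> list[InteractionRecord]:
    """Subsample the majority class so positives and negatives are equal in
    count (applied to training splits only)."""
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        idx = rng.choice(len(pos), size=len(neg), replace=False)
        pos = [pos[i] for i in sorted(idx)]
    elif len(neg) > len(pos):
        idx = rng.choice(len(neg), size=len(pos), replace=False)
        neg = [neg[i] for i in sorted(idx)]
    return pos + neg


def interactions_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"drug_id": r.drug_id, "target_id": r.target_id, "source": r.source}
        if r.label is not None:
            row["label"] = r.label
        else:
            row["pK"] = r.pK
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_interactions(df: pd.DataFrame) -> list[InteractionRecord]:
    has_label = "label" in df.columns
    records = []
    for row in df.itertuples(index=False):
        records.append(
            InteractionRecord(
                drug_id=str(row.drug_id),
                target_id=str(row.target_id),
                label=int(row.label) if has_label else None,
                pK=None if has_label else float(row.pK),
                source=getattr(row, "source", "measured"),
            )
        )
    return records
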