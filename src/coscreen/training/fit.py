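"""Minibatch fitting loop for the co-embedding model.

Adam on the pooling + projection parameters, early stopping on the
validation metric (AUPR for classification, MSE for regression), returning
the best-seen checkpoint rather than the last.  Fully deterministic for a
given seed on one device.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..errors import DataError
from ..metrics import RankedScreen, auprc
from ..model.core import DTICoEmbedder, bce_loss, mse_loss


@dataclass(frozen=True)
class FitConfig:
    lr: float = 1e-4
    batch_size: int = 256
    epochs: int = 50
    patience: int = 10
    seed: int = 0
    shuffle: bool = True


@dataclass
class FitResult:
    best_params: list[np.ndarray]
    best_epoch: int
    best_val_metric: float
    history: list[dict] = field(default_factory=list)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _gather(records, drug_features, target_features, task):
    d_ids, t_ids, y = [], [], []
    for r in records:
        d_ids.append(r.drug_id)
        t_ids.append(r.target_id)
        y.append(r.label if task == "classify" else r.pK)
        if y[-1] is None:
            raise DataError(
                f"record ({r.drug_id}, {r.target_id}) lacks the field for task {task!r}"
            )
    for d in d_ids:
        if d not in drug_features:
            raise DataError(f"no fingerprint for drug {d!r}")
    for t in t_ids:
        if t not in target_features:
            raise DataError(f"no residue embeddings for target {t!r}")
    return d_ids, t_ids, np.asarray(y, dtype=np.float64)


def _classify_head_backward(zd, zt, y, alpha):
    """Loss + gradients for sigmoid(alpha*cos) with BCE, batch-mean."""
    nd = np.linalg.norm(zd, axis=1, keepdims=True)
    nt = np.linalg.norm(zt, axis=1, keepdims=True)
    if np.any(nd == 0) or np.any(nt == 0):
        raise DataError("zero-norm co-embedding encountered")
    u, v = zd / nd, zt / nt
    c = np.sum(u * v, axis=1)
    p = 1.0 / (1.0 + np.exp(-alpha * c))
    loss = bce_loss(p, y)
    B = y.shape[0]
    dlogit = (p - y) / B
    dc = (alpha * dlogit)[:, None]
    g_zd = dc * (v - c[:, None] * u) / nd
    g_zt = dc * (u - c[:, None] * v) / nt
    return loss, g_zd, g_zt, p


def _regress_head_backward(zd, zt, y):
    pred = np.sum(zd * zt, axis=1)
    loss = mse_loss(pred, y)
    B = y.shape[0]
    dr = (2.0 * (pred - y) / B)[:, None]
    return loss, dr * zt, dr * zd, pred


def predict_records(
    model: DTICoEmbedder,
    records,
    drug_features: dict[str, np.ndarray],
    target_features: dict[str, np.ndarray],
    task: str = "classify",
    batch_size: int = 1024,
) -> np.ndarray:
    """Score records in batches; unique targets embedded once per batch."""
    d_ids, t_ids, _ = _gather(records, drug_features, target_features, task)
    out = np.empty(len(records))
    for start in range(0, len(records), batch_size):
        sl = slice(start, start + batch_size)
        bd, bt = d_ids[sl], t_ids[sl]
        uniq = list(dict.fromkeys(bt))
        Zt_uniq, _, _, _ = model.embed_targets([target_features[t] for t in uniq])
        t_pos = {t: i for i, t in enumerate(uniq)}
        Zt = Zt_uniq[[t_pos[t] for t in bt]]
        X = np.stack([drug_features[d] for d in bd]).astype(np.float64)
        Zd, _ = model.embed_drugs(X)
        out[sl] = model.score_pairs(Zd, Zt, task=task)
    return out


def fit(
    model: DTICoEmbedder,
    train_records: Sequence,
    val_records: Sequence,
    drug_features: dict[str, np.ndarray],
    target_features: dict[str, np.ndarray],
    task: str = "classify",
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Train Cd/Ct and the pooler; returns the checkpoint-best parameters."""
    if task not in ("classify", "regress"):
        raise DataError(f"task must be classify|regress, got {task!r}")
    if len(train_records) == 0:
        raise DataError("empty training set")
    d_ids, t_ids, y = _gather(train_records, drug_features, target_features, task)
    n = len(train_records)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.lr)
    alpha = model.config.alpha

    best_params = model.copy_params()
    best_epoch = -1
    # classify: higher AUPR is better; regress: lower MSE is better
    best_metric = -np.inf if task == "classify" else np.inf
    history: list[dict] = []
    stale = 0

    fp_matrix = {d: np.asarray(drug_features[d], dtype=np.float64) for d in set(d_ids)}

    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            bd = [d_ids[i] for i in idx]
            bt = [t_ids[i] for i in idx]
            by = y[idx]
            uniq = list(dict.fromkeys(bt))
            t_pos = {t: i for i, t in enumerate(uniq)}
            sel = np.array([t_pos[t] for t in bt])

            model.zero_grad()
            X = np.stack([fp_matrix[d] for d in bd])
            Zd, d_cache = model.embed_drugs(X, train=True, rng=rng)
            Zt_uniq, _, _, t_cache = model.embed_targets(
                [target_features[t] for t in uniq], train=True, rng=rng
            )
            Zt = Zt_uniq[sel]
            if task == "classify":
                loss, g_zd, g_zt, _ = _classify_head_backward(Zd, Zt, by, alpha)
            else:
                loss, g_zd, g_zt, _ = _regress_head_backward(Zd, Zt, by)
            if not np.isfinite(loss):
                raise DataError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}: "
                    f"drugs {bd[:3]}..., targets {bt[:3]}..."
                )
            # scatter pair-gradients back to unique targets
            g_zt_uniq = np.zeros_like(Zt_uniq)
            np.add.at(g_zt_uniq, sel, g_zt)
            model.drug_net.backward(g_zd, d_cache)
            model.backward_targets(g_zt_uniq, t_cache)
            opt.step(model.grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n

        entry = {"epoch": epoch, "train_loss": epoch_loss}
        if len(val_records) > 0:
            val_scores = predict_records(
                model, val_records, drug_features, target_features, task
            )
            _, _, val_y = _gather(val_records, drug_features, target_features, task)
            if task == "classify":
                entry["val_loss"] = bce_loss(val_scores, val_y)
                metric = auprc(RankedScreen.from_arrays(val_scores, val_y))
                entry["val_auprc"] = metric
                improved = metric > best_metric
            else:
                metric = mse_loss(val_scores, val_y)
                entry["val_loss"] = metric
                improved = metric < best_metric
        else:
            metric = -epoch_loss if task == "classify" else epoch_loss
            improved = (
                metric > best_metric if task == "classify" else metric < best_metric
            )
        history.append(entry)
        if improved:
            best_metric = metric
            best_epoch = epoch
            best_params = model.copy_params()
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break

    model.set_params(best_params)
    return FitResult(
        best_params=best_params,
        best_epoch=best_epoch,
        best_val_metric=float(best_metric),
        history=history,
    )
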