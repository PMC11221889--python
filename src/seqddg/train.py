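"""Model optimization against ΔΔG labels with mean-squared-error loss.

Mini-batch Adam on shuffled batches; fully reproducible from the model seed
(parameter initialization) and the training seed (shuffling and dropout).
When a validation set is supplied the best-validation-loss parameters are
returned, otherwise the final state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Adam
from .data_io import MutationDataset
from .network import Featurizer, Model, ModelConfig, batch_records, forward

log = logging.getLogger(__name__)


def mse_loss(pred: Sequence[float], true: Sequence[float]) -> float:
    """Mean squared error (1/N)·Σ(x_i − y_i)² between two equal-length
    nonempty vectors."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.ndim != 1 or true.ndim != 1:
        raise ValueError("mse_loss expects 1-D vectors")
    if pred.size == 0:
        raise ValueError("mse_loss on empty vectors")
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    return float(np.mean((pred - true) ** 2))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    seed: int = 0
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_pcc: list[float] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["epoch\ttrain_loss\tval_loss\tval_pcc"]
        for i, tl in enumerate(self.train_loss):
            vl = f"{self.val_loss[i]:.6g}" if i < len(self.val_loss) else ""
            vp = f"{self.val_pcc[i]:.6g}" if i < len(self.val_pcc) else ""
            lines.append(f"{i + 1}\t{tl:.6g}\t{vl}\t{vp}")
        return "\n".join(lines) + "\n"


def train_model(
    train_set: MutationDataset,
    featurizer: Featurizer | None,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    val_set: MutationDataset | None = None,
) -> tuple[Model, TrainHistory]:
    """Fit a :class:`Model` to ``train_set`` by mini-batch Adam on MSE.

    Aborts with diagnostics if the loss turns non-finite.  Labels are used
    in kcal/mol without normalization.
    """
    featurizer = featurizer or Featurizer()
    model = Model(model_cfg)
    optimizer = Adam(
        model.parameters(),
        lr=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
    )
    rng = np.random.default_rng(train_cfg.seed)
    history = TrainHistory()
    # Mini-batches are drawn within complexes: records of one complex share
    # chain lengths, so per-batch right-padding is (near) zero.  Record
    # order within each complex and the order of batches are reshuffled
    # every epoch.
    by_complex: dict[str, list[int]] = {}
    for i, rec in enumerate(train_set.records):
        by_complex.setdefault(rec.complex_id, []).append(i)
    groups = [np.array(v) for v in by_complex.values()]
    best: tuple[float, dict[str, np.ndarray]] | None = None
    stale = 0

    for epoch in range(train_cfg.epochs):
        batches: list[np.ndarray] = []
        for g in groups:
            perm = g[rng.permutation(len(g))]
            batches += [
                perm[s : s + train_cfg.batch_size]
                for s in range(0, len(perm), train_cfg.batch_size)
            ]
        batches = [batches[i] for i in rng.permutation(len(batches))]
        losses, weights = [], []
        for idx in batches:
            records = [train_set.records[i] for i in idx]
            batch = batch_records(records, featurizer)
            y = np.array([r.ddg for r in records])
            pred, _ = forward(model, batch, training=True, rng=rng)
            diff = pred - _const(y)
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1} "
                    f"(batch of {len(idx)}; lr={train_cfg.learning_rate})"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
            weights.append(len(idx))
        epoch_loss = float(np.average(losses, weights=weights))
        history.train_loss.append(epoch_loss)

        if val_set is not None:
            from .evaluate import pearson  # local import avoids a cycle

            vb = batch_records(list(val_set.records), featurizer)
            vp, _ = forward(model, vb, training=False)
            vy = np.array([r.ddg for r in val_set.records])
            vloss = mse_loss(vp.data, vy)
            history.val_loss.append(vloss)
            try:
                history.val_pcc.append(pearson(vy, vp.data))
            except ValueError:
                history.val_pcc.append(float("nan"))
            if best is None or vloss < best[0]:
                best = (vloss, {k: p.data.copy() for k, p in model.params.items()})
                stale = 0
            else:
                stale += 1
                if train_cfg.early_stop_patience and stale >= train_cfg.early_stop_patience:
                    log.info("early stop at epoch %d", epoch + 1)
                    break
        if (epoch + 1) % 25 == 0 or epoch == 0:
            log.info("epoch %d: train MSE %.4f", epoch + 1, epoch_loss)

    if best is not None:
        for k, p in model.params.items():
            p.data = best[1][k]
    return model, history


def _const(y: np.ndarray):
    from .autodiff import Tensor

    return Tensor(y)
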