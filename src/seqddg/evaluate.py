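"""Evaluation protocols and metrics for ΔΔG prediction.

Two split schemes are implemented: randomized K-fold cross-validation, and a
label-ascending ordered split in which, within every complex, the mutants
with the highest ΔΔG are held out — an extrapolation probe, since the model
must predict affinity changes larger than any it saw for that complex.
Metrics are the Pearson correlation (PCC), the coefficient of determination
(R²), and a rank-consistency score (R² applied to rank vectors) used when
ranking candidate mutations for antibody optimization.  Pooled out-of-fold
metrics (all held-out predictions concatenated) are the primary numbers;
per-fold values are also reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import MutationDataset
from .network import Featurizer, ModelConfig, predict_ddg
from .train import TrainConfig, train_model

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics


def pearson(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Pearson product-moment correlation; raises on constant input."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("pearson needs two equal-length 1-D vectors of size >= 2")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(y, yhat).statistic)


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Coefficient of determination 1 − Σ(y−ŷ)²/Σ(y−ȳ)²; ≤ 1, may be < 0."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("r_squared needs two equal-length 1-D vectors of size >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r_squared undefined for constant observations")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rank_consistency(y: Sequence[float], yhat: Sequence[float]) -> float:
    """R² between ascending rank vectors (average ranks on ties) — measures
    how well the predicted ordering of mutants matches the observed one."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("rank_consistency needs two equal-length vectors of size >= 2")
    return r_squared(stats.rankdata(y), stats.rankdata(yhat))


# ---------------------------------------------------------------------------
# Split plans


@dataclass
class SplitPlan:
    """Record-to-fold assignment.  ``kfold``: ``assignments[i]`` is a fold
    index in [0, k); ``label_ascending``: 1 marks test, 0 train."""

    scheme: str  # "kfold" | "label_ascending"
    assignments: np.ndarray
    k: int | None = None
    test_fraction: float | None = None
    seed: int | None = None

    def folds(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train_indices, test_indices) per fold."""
        idx = np.arange(len(self.assignments))
        if self.scheme == "kfold":
            return [
                (idx[self.assignments != f], idx[self.assignments == f])
                for f in range(self.k)
            ]
        return [(idx[self.assignments == 0], idx[self.assignments == 1])]


def kfold_split(dataset: MutationDataset, k: int, seed: int) -> SplitPlan:
    """Shuffle records with ``seed`` and deal them into ``k`` folds whose
    sizes differ by at most one."""
    n = len(dataset)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    order = np.random.default_rng(seed).permutation(n)
    assignments = np.empty(n, dtype=int)
    # Contiguous blocks of the shuffled order; first n % k folds get the
    # extra record.
    sizes = [n // k + (1 if f < n % k else 0) for f in range(k)]
    start = 0
    for f, size in enumerate(sizes):
        assignments[order[start : start + size]] = f
        start += size
    return SplitPlan(scheme="kfold", assignments=assignments, k=k, seed=seed)


def label_ascending_split(dataset: MutationDataset, test_fraction: float = 0.2) -> SplitPlan:
    """Within each complex, hold out the ceil(fraction·size) records with the
    highest ΔΔG; ties are broken by stable input order.  Singleton complexes
    go entirely to train with a warning."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    assignments = np.zeros(len(dataset), dtype=int)
    by_complex: dict[str, list[int]] = {}
    for i, rec in enumerate(dataset.records):
        by_complex.setdefault(rec.complex_id, []).append(i)
    for cid, indices in by_complex.items():
        if len(indices) == 1:
            warnings.warn(f"complex {cid} has a single record; assigned to train")
            continue
        # sorted() is stable, so ties keep their input order.
        ranked = sorted(indices, key=lambda i: dataset.records[i].ddg)
        n_test = int(np.ceil(test_fraction * len(indices)))
        for i in ranked[len(indices) - n_test :]:
            assignments[i] = 1
    return SplitPlan(
        scheme="label_ascending", assignments=assignments, test_fraction=test_fraction
    )


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class EvalReport:
    predictions: pd.DataFrame  # record_id, complex_id, y_true, y_pred, fold
    fold_pcc: list[float] = field(default_factory=list)
    fold_r2: list[float] = field(default_factory=list)

    @property
    def pooled_pcc(self) -> float:
        return pearson(self.predictions["y_true"], self.predictions["y_pred"])

    @property
    def pooled_r2(self) -> float:
        return r_squared(self.predictions["y_true"], self.predictions["y_pred"])

    def metrics(self) -> dict:
        return {
            "pooled_pcc": self.pooled_pcc,
            "pooled_r2": self.pooled_r2,
            "fold_pcc": self.fold_pcc,
            "fold_r2": self.fold_r2,
        }


def holdout_eval(
    dataset: MutationDataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    *,
    test_fraction: float = 0.2,
    seed: int = 0,
    featurizer: Featurizer | None = None,
) -> dict:
    """Single random train/test split: train once, score the held-out set.

    Returns PCC, R², rank consistency and the prediction table; the split is
    a seeded permutation with the first ``test_fraction`` share held out.
    """
    n = len(dataset)
    order = np.random.default_rng(seed).permutation(n)
    n_test = max(2, int(round(test_fraction * n)))
    test_idx, train_idx = order[:n_test], order[n_test:]
    featurizer = featurizer or Featurizer()
    model, history = train_model(
        dataset.subset(train_idx, name=f"{dataset.name}-train"), featurizer, model_cfg, train_cfg
    )
    test_records = [dataset.records[i] for i in test_idx]
    preds, _ = predict_ddg(model, test_records, featurizer)
    y_true = np.array([r.ddg for r in test_records])
    table = pd.DataFrame(
        {
            "record_id": [f"{r.complex_id}:{r.mutation_string}" for r in test_records],
            "y_true": y_true,
            "y_pred": preds,
        }
    )
    return {
        "pcc": pearson(y_true, preds),
        "r2": r_squared(y_true, preds),
        "rank_consistency": rank_consistency(y_true, preds),
        "n_train": int(len(train_idx)),
        "n_test": int(n_test),
        "final_train_mse": history.train_loss[-1],
        "predictions": table,
        "model": model,
    }


def cross_validate(
    dataset: MutationDataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    plan: SplitPlan,
    featurizer: Featurizer | None = None,
) -> EvalReport:
    """Train on each fold's train portion, predict its held-out portion, and
    pool all out-of-fold predictions.

    Folds too small for a metric are recorded as NaN; pooled metrics are
    always computed over the full predictions table.
    """
    if len(plan.assignments) != len(dataset):
        raise ValueError("split plan does not cover the dataset")
    featurizer = featurizer or Featurizer()
    rows = []
    fold_pcc, fold_r2 = [], []
    for fold_id, (train_idx, test_idx) in enumerate(plan.folds()):
        train_set = dataset.subset(train_idx, name=f"{dataset.name}-fold{fold_id}-train")
        model, _ = train_model(train_set, featurizer, model_cfg, train_cfg)
        test_records = [dataset.records[i] for i in test_idx]
        preds, _ = predict_ddg(model, test_records, featurizer)
        y_true = np.array([r.ddg for r in test_records])
        try:
            fold_pcc.append(pearson(y_true, preds))
            fold_r2.append(r_squared(y_true, preds))
        except ValueError:
            fold_pcc.append(float("nan"))
            fold_r2.append(float("nan"))
        for i, rec, pred in zip(test_idx, test_records, preds):
            rows.append(
                {
                    "index": int(i),
                    "record_id": f"{rec.complex_id}:{rec.mutation_string}",
                    "complex_id": rec.complex_id,
                    "y_true": rec.ddg,
                    "y_pred": float(pred),
                    "fold": fold_id,
                }
            )
        log.info("fold %d: PCC %.3f", fold_id, fold_pcc[-1])
    predictions = pd.DataFrame(rows).sort_values("index").reset_index(drop=True)
    return EvalReport(predictions=predictions, fold_pcc=fold_pcc, fold_r2=fold_r2)
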