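"""Tenfold cross-validation, metrics and candidate ranking.

Folds stratify ALL n x m drug-disease pairs by label, so each fold holds
one tenth of the matrix with balanced positives; the fold's positives are
masked to 0 in the training adjacency and the fold's cells are excluded
from the training pairs entirely.  AUROC and AUPR are micro (computed over
the flattened pair set), accuracy/precision/recall come from pooled
confusion counts, and F1 is macro-averaged over diseases ("each label"),
all following the conventions of the benchmark literature for this task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .graph_data import AssociationMatrix, HeteroBundle
from .interaction_ncf import ModelConfig
from .training import TrainConfig, train

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "tenfold_split",
    "confusion_metrics",
    "ranking_metrics",
    "cross_validate",
    "rank_candidates",
]

METRIC_NAMES = ("acc", "auroc", "aupr", "f1", "precision", "recall")


@dataclass
class FoldSplit:
    """Fold assignment (0..n_folds-1) for every drug-disease pair."""

    fold_id: np.ndarray  # n x m integer matrix
    seed: int
    n_folds: int = 10

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_id == fold


@dataclass
class MetricsReport:
    """Per-fold metric rows plus mean +/- std aggregates."""

    per_fold: list[dict]
    aggregate: dict[str, tuple[float, float]]
    failed_folds: list[int]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(row) for row in self.per_fold]
        agg_mean = {"fold": "mean", **{k: v[0] for k, v in self.aggregate.items()}}
        agg_std = {"fold": "std", **{k: v[1] for k, v in self.aggregate.items()}}
        return pd.DataFrame(rows + [agg_mean, agg_std])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def mean(self, metric: str) -> float:
        return self.aggregate[metric][0]


def tenfold_split(association: AssociationMatrix, seed: int,
                  n_folds: int = 10) -> FoldSplit:
    """Stratified partition of all pairs into folds of near-equal size.

    Fold sizes and per-fold positive counts each differ by at most one.
    """
    labels = association.values.ravel()
    if int(labels.sum()) < n_folds:
        raise ValueError(
            f"need at least {n_folds} positives for {n_folds}-fold "
            f"cross-validation, got {int(labels.sum())}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_id = np.empty(labels.size, dtype=np.int64)
    for f, (_, test) in enumerate(skf.split(np.zeros_like(labels), labels)):
        fold_id[test] = f
    return FoldSplit(fold_id=fold_id.reshape(association.values.shape),
                     seed=seed, n_folds=n_folds)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); using 0")
        return 0.0
    return num / den


def confusion_metrics(labels, scores, threshold: float = 0.5,
                      groups=None) -> dict[str, float]:
    """Accuracy, precision, recall, F1 after binarizing at `threshold`.

    Accuracy, precision and recall use pooled (micro) confusion counts;
    F1 is macro-averaged over `groups` (e.g. the disease of each pair)
    when provided, else computed from the pooled counts.
    """
    y = np.asarray(labels).astype(int).ravel()
    pred = (np.asarray(scores, dtype=np.float64).ravel() >= threshold).astype(int)
    tp = int(((y == 1) & (pred == 1)).sum())
    tn = int(((y == 0) & (pred == 0)).sum())
    fp = int(((y == 0) & (pred == 1)).sum())
    fn = int(((y == 1) & (pred == 0)).sum())
    acc = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy")
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    if groups is None:
        f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    else:
        groups = np.asarray(groups).ravel()
        f1s = []
        for g in np.unique(groups):
            sel = groups == g
            gtp = int(((y[sel] == 1) & (pred[sel] == 1)).sum())
            gfp = int(((y[sel] == 0) & (pred[sel] == 1)).sum())
            gfn = int(((y[sel] == 1) & (pred[sel] == 0)).sum())
            gp = gtp / (gtp + gfp) if gtp + gfp else 0.0
            gr = gtp / (gtp + gfn) if gtp + gfn else 0.0
            f1s.append(2 * gp * gr / (gp + gr) if gp + gr else 0.0)
        f1 = float(np.mean(f1s))
    return {"acc": acc, "precision": precision, "recall": recall, "f1": f1}


def ranking_metrics(labels, scores) -> dict[str, float]:
    """Micro AUROC and AUPR over the flattened pair set."""
    y = np.asarray(labels).astype(int).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("ranking metrics require both classes present")
    return {"auroc": float(roc_auc_score(y, s)),
            "aupr": float(average_precision_score(y, s))}


def cross_validate(bundle: HeteroBundle, train_config: TrainConfig,
                   model_config: ModelConfig | None = None,
                   seed: int | None = None, n_folds: int = 10,
                   threshold: float = 0.5) -> MetricsReport:
    """Train one model per fold on the masked adjacency and score held-out pairs."""
    if model_config is None:
        model_config = ModelConfig()
    if seed is None:
        seed = train_config.seed
    split = tenfold_split(bundle.association, seed, n_folds)
    A = bundle.association.values

    per_fold: list[dict] = []
    failed: list[int] = []
    for fold in range(n_folds):
        test_mask = split.test_mask(fold)
        masked = A.copy()
        masked[test_mask] = 0  # fold positives removed from training labels
        masked_assoc = AssociationMatrix(
            masked, list(bundle.association.drug_ids),
            list(bundle.association.disease_ids))
        fold_bundle = bundle.with_association(masked_assoc)
        fold_config = replace(train_config,
                              seed=(seed * 100003 + fold) % (2**31))
        try:
            state = train(fold_bundle, fold_config, model_config,
                          pair_mask=~test_mask)
            scores = state.model.predict_matrix()
        except Exception as err:  # noqa: BLE001 - fold failures are reported
            warnings.warn(f"fold {fold} failed to train: {err}")
            failed.append(fold)
            continue
        rows, cols = np.nonzero(test_mask)
        y = A[rows, cols]
        s = scores[rows, cols]
        row = {"fold": fold}
        row.update(ranking_metrics(y, s))
        row.update(confusion_metrics(y, s, threshold=threshold, groups=cols))
        per_fold.append(row)

    aggregate = {}
    for metric in METRIC_NAMES:
        vals = np.array([row[metric] for row in per_fold], dtype=np.float64)
        aggregate[metric] = (float(vals.mean()), float(vals.std(ddof=0)))
    return MetricsReport(per_fold=per_fold, aggregate=aggregate,
                         failed_folds=failed)


def rank_candidates(score_matrix: np.ndarray, drug_ids: list[str],
                    disease_ids: list[str], disease_id: str,
                    top_n: int = 10, exclude_known: bool = True,
                    association: AssociationMatrix | None = None
                    ) -> list[tuple[str, float]]:
    """Descending-score drug ranking for one disease (ties broken by drug id).

    With `exclude_known`, drugs already associated with the disease in
    `association` are removed before truncation — the discovery setting.
    """
    if disease_id not in disease_ids:
        raise KeyError(f"unknown disease id {disease_id!r}")
    col = disease_ids.index(disease_id)
    scores = np.asarray(score_matrix, dtype=np.float64)[:, col]
    keep = np.ones(len(drug_ids), dtype=bool)
    if exclude_known:
        if association is None:
            raise ValueError("exclude_known=True requires the association matrix")
        keep = association.values[:, col] == 0
    entries = [(drug_ids[i], float(scores[i])) for i in range(len(drug_ids))
               if keep[i]]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries[:top_n]
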