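"""Training: the multi-term loss and the full-batch Adam optimization loop.

The objective is a weighted sum of four terms over the training pairs —
binary cross-entropy, focal loss (alpha 0.5, gamma 2.0, the standard
symmetric two-class form), mean squared error, and a pairwise margin
ranking loss with one sampled unobserved pair per observed association per
epoch.  Training pairs are every cell of the training split of the
association matrix: observed associations are positives, every unobserved
cell is a negative; the focal term exists precisely to absorb that
imbalance.  Optimization is full-batch Adam at base learning rate 5e-4
under a triangular cyclic schedule, with optional early stopping on
validation AUPR.  Every source of randomness (initialization, validation
split, negative sampling, dropout) is replayed exactly from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score
from sklearn.model_selection import train_test_split

from ._autodiff import (Adam, Tensor, as_tensor, clamp, log, relu, reshape,
                        take_rows, tmean)
from .graph_data import HeteroBundle
from .interaction_ncf import EncoderConfig, ModelConfig, WMAGTModel

__all__ = [
    "TrainConfig",
    "TrainState",
    "bce_loss",
    "mse_loss",
    "focal_loss",
    "ranking_loss",
    "combined_loss",
    "cyclic_learning_rate",
    "train",
]

_PROB_EPS = 1e-7


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    dropout: float = 0.3
    focal_alpha: float = 0.5
    focal_gamma: float = 2.0
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    epochs: int = 300
    patience: int | None = 30
    val_fraction: float = 0.1
    seed: int = 0
    lr_min: float = 5e-5
    lr_max: float = 5e-4
    cycle_len: int = 20
    ranking_margin: float = 1.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be non-negative")
        if not 0.0 <= self.focal_alpha <= 1.0:
            raise ValueError("focal_alpha must be in [0, 1]")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss_weights must be non-negative")


@dataclass
class TrainState:
    """Everything a run produced: the fitted model plus its history."""

    model: WMAGTModel
    loss_history: list[dict] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    epoch: int = 0
    best_val_aupr: float | None = None
    diverged: bool = False


# -- loss terms -------------------------------------------------------------

def _prep(p, y):
    p = as_tensor(p)
    if p.ndim > 1:
        p = reshape(p, (-1,))
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    return clamp(p, _PROB_EPS, 1.0 - _PROB_EPS), y


def bce_loss(p, y) -> Tensor:
    p, y = _prep(p, y)
    return tmean(-(Tensor(y) * log(p) + Tensor(1.0 - y) * log(1.0 - p)))


def mse_loss(p, y) -> Tensor:
    p, y = _prep(p, y)
    return tmean((p - Tensor(y)) ** 2)


def focal_loss(p, y, alpha: float = 0.5, gamma: float = 2.0) -> Tensor:
    """Mean focal loss: -alpha (1-p)^gamma log p for positives and the
    symmetric -(1-alpha) p^gamma log(1-p) for negatives."""
    p, y = _prep(p, y)
    pos = Tensor(y) * (-alpha) * (1.0 - p) ** gamma * log(p)
    neg = Tensor(1.0 - y) * (-(1.0 - alpha)) * p**gamma * log(1.0 - p)
    return tmean(pos + neg)


def ranking_loss(pos_scores, neg_scores, margin: float = 1.0) -> Tensor:
    """Mean hinge max(0, margin - pos + neg) over all (pos, neg) pairs."""
    pos = as_tensor(pos_scores)
    neg = as_tensor(neg_scores)
    if pos.data.size == 0 or neg.data.size == 0:
        warnings.warn("ranking_loss called with an empty score set; returning 0")
        return Tensor(0.0)
    pos_col = reshape(pos, (-1, 1))
    neg_row = reshape(neg, (1, -1))
    return tmean(relu(margin - pos_col + neg_row))


def combined_loss(predictions, labels, config: TrainConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[Tensor, dict[str, float]]:
    """Weighted sum of the four loss terms with a per-term breakdown.

    The ranking term compares observed-pair scores against one unobserved
    pair sampled per positive (all unobserved pairs when no rng is given).
    """
    p, y = _prep(predictions, labels)
    w_bce, w_focal, w_mse, w_rank = config.loss_weights
    terms = {
        "bce": bce_loss(p, y),
        "focal": focal_loss(p, y, config.focal_alpha, config.focal_gamma),
        "mse": mse_loss(p, y),
    }
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) and len(neg_idx):
        if rng is not None:
            neg_idx = rng.choice(neg_idx, size=len(pos_idx), replace=True)
        terms["ranking"] = ranking_loss(take_rows(p, pos_idx),
                                        take_rows(p, neg_idx),
                                        config.ranking_margin)
    else:
        terms["ranking"] = Tensor(0.0)
    total = (w_bce * terms["bce"] + w_focal * terms["focal"]
             + w_mse * terms["mse"] + w_rank * terms["ranking"])
    breakdown = {k: float(v.data) for k, v in terms.items()}
    breakdown["total"] = float(total.data)
    if not all(np.isfinite(v) for v in breakdown.values()):
        raise FloatingPointError(f"non-finite loss term: {breakdown}")
    return total, breakdown


def cyclic_learning_rate(epoch: int, config: TrainConfig) -> float:
    """Triangular cycle between lr_min and lr_max, starting at lr_max."""
    cycle = max(config.cycle_len, 1)
    phase = (epoch + cycle // 2) % cycle
    tri = 1.0 - abs(2.0 * phase / cycle - 1.0)
    return config.lr_min + (config.lr_max - config.lr_min) * tri


# -- training loop ----------------------------------------------------------

def _all_pairs(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    return np.repeat(np.arange(n), m), np.tile(np.arange(m), n)


def train(bundle: HeteroBundle, config: TrainConfig,
          model_config: ModelConfig | None = None,
          pair_mask: np.ndarray | None = None) -> TrainState:
    """Fit the model on the bundle's association labels.

    `pair_mask` (boolean n x m) restricts the training pairs — used by
    cross-validation to exclude the held-out fold entirely.  The bundle's
    association matrix must already have held-out positives masked to 0.
    """
    if model_config is None:
        model_config = ModelConfig()
    enc = replace(model_config.encoder, dropout=config.dropout) \
        if isinstance(model_config.encoder, EncoderConfig) else model_config.encoder
    model_config = replace(model_config, encoder=enc)

    master = np.random.default_rng(config.seed)
    init_rng = np.random.default_rng(master.integers(2**31))
    split_rng_seed = int(master.integers(2**31))
    sample_rng = np.random.default_rng(master.integers(2**31))
    dropout_rng = np.random.default_rng(master.integers(2**31))

    model = WMAGTModel(bundle, model_config, init_rng)
    params = model.param_list()
    optimizer = Adam(params, lr=config.learning_rate)

    A = bundle.association.values
    n, m = A.shape
    drug_idx, dis_idx = _all_pairs(n, m)
    labels = A.ravel().astype(np.float64)
    if pair_mask is not None:
        keep = np.asarray(pair_mask, dtype=bool).ravel()
        drug_idx, dis_idx, labels = drug_idx[keep], dis_idx[keep], labels[keep]

    val_idx = None
    if config.patience is not None and labels.sum() >= 2:
        tr, va = train_test_split(
            np.arange(len(labels)), test_size=config.val_fraction,
            stratify=labels, random_state=split_rng_seed % (2**31))
        val_idx = va
        train_sel = tr
    else:
        train_sel = np.arange(len(labels))

    tr_drug, tr_dis, tr_y = drug_idx[train_sel], dis_idx[train_sel], labels[train_sel]

    state = TrainState(model=model)
    best_params = None
    best_val = -np.inf
    stall = 0
    for epoch in range(config.epochs):
        optimizer.lr = cyclic_learning_rate(epoch, config)
        optimizer.zero_grad()
        preds = model.forward_pairs(tr_drug, tr_dis, training=True,
                                    rng=dropout_rng)
        try:
            total, breakdown = combined_loss(preds, tr_y, config, rng=sample_rng)
        except FloatingPointError:
            state.diverged = True
            break
        total.backward()
        optimizer.step()
        state.loss_history.append(breakdown)
        state.lr_history.append(optimizer.lr)
        state.epoch = epoch + 1

        if val_idx is not None:
            val_scores = model.forward_pairs(
                drug_idx[val_idx], dis_idx[val_idx]).data.ravel()
            val_y = labels[val_idx]
            aupr = average_precision_score(val_y, val_scores) \
                if val_y.sum() > 0 else 0.0
            state.best_val_aupr = max(best_val, aupr) if np.isfinite(aupr) else best_val
            if aupr > best_val:
                best_val = aupr
                best_params = [p.data.copy() for p in params]
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
    if best_params is not None:
        for p, d in zip(params, best_params):
            p.data = d
    return state
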