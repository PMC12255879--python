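"""MSE training loop with Adam and plateau learning-rate decay, and the five
evaluation metrics (R, RMSE, MAE, SD, CI) implemented from their definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import ComplexRecord
from .model import AffinityModel, FeaturizedComplex, ModelConfig
from .nn import Adam

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "MetricsReport", "TrainHistory", "mse_loss",
           "train_model", "concordance_index", "sd_regression", "evaluate",
           "predict_dataset"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    lr_decay_factor: float = 0.1
    patience: int = 10  # epochs without val improvement before decay
    max_epochs: int = 500
    batch_size: int = 32
    val_fraction: float = 0.2  # used when no explicit validation set given
    min_lr: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.lr_decay_factor <= 0:
            raise ValueError("rates must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)


class PlateauScheduler:
    """Multiplies the learning rate by `factor` after `patience` epochs
    without validation-loss improvement."""

    def __init__(self, lr: float, factor: float = 0.1, patience: int = 10,
                 threshold: float = 1e-8):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.best = np.inf
        self.stale = 0

    def step(self, val_loss: float) -> float:
        """Record one epoch's validation loss; returns the current lr."""
        if val_loss < self.best - self.threshold:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.lr *= self.factor
                self.stale = 0
        return self.lr


def mse_loss(y: Sequence[float], yhat: Sequence[float]) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean((y - yhat) ** 2))


def _epoch_pass(model: AffinityModel, feats: list[FeaturizedComplex],
                order: np.ndarray, batch_size: int,
                optimizer: Optional[Adam]) -> float:
    total, count = 0.0, 0
    for start in range(0, len(order), batch_size):
        batch = order[start:start + batch_size]
        loss = None
        for idx in batch:
            f = feats[idx]
            pred = model.forward(f)
            term = (pred - f.label) ** 2
            loss = term if loss is None else loss + term
        loss = loss * (1.0 / len(batch))
        value = float(loss.data[0])
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss {value} in batch at {start}")
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        total += value * len(batch)
        count += len(batch)
    return total / count


def train_model(dataset: Sequence[ComplexRecord], model_cfg: ModelConfig,
                train_cfg: TrainConfig,
                validation: Optional[Sequence[ComplexRecord]] = None,
                ) -> tuple[AffinityModel, TrainHistory]:
    """Train an AffinityModel with Adam; on a validation plateau of
    `patience` epochs the learning rate is multiplied by the decay factor.
    Fully deterministic given train_cfg.seed on a single device.
    """
    if len(dataset) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(train_cfg.seed)
    records = list(dataset)
    if validation is None:
        n_val = max(1, int(round(train_cfg.val_fraction * len(records))))
        if n_val >= len(records):
            raise ValueError("dataset too small to hold out validation")
        perm = rng.permutation(len(records))
        val_records = [records[i] for i in perm[:n_val]]
        records = [records[i] for i in perm[n_val:]]
    else:
        val_records = list(validation)

    for r in records + val_records:
        if r.affinity_label is None:
            raise ValueError(f"record {r.complex_id} lacks an affinity label")

    model = AffinityModel(model_cfg, seed=train_cfg.seed)
    train_feats = [model.featurize(r) for r in records]
    val_feats = [model.featurize(r) for r in val_records]
    optimizer = Adam(model.parameters(), lr=train_cfg.learning_rate)
    scheduler = PlateauScheduler(train_cfg.learning_rate,
                                 train_cfg.lr_decay_factor, train_cfg.patience)
    history = TrainHistory()
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(train_feats))
        train_loss = _epoch_pass(model, train_feats, order,
                                 train_cfg.batch_size, optimizer)
        val_loss = _epoch_pass(model, val_feats,
                               np.arange(len(val_feats)),
                               train_cfg.batch_size, None) if val_feats else train_loss
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.learning_rates.append(optimizer.lr)
        new_lr = scheduler.step(val_loss)
        if new_lr != optimizer.lr:
            logger.info("epoch %d: plateau, lr -> %.2e", epoch, new_lr)
            optimizer.lr = new_lr
            if new_lr < train_cfg.min_lr:
                break
        if epoch % 50 == 0:
            logger.info("epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)
    return model, history


def predict_dataset(model: AffinityModel,
                    records: Sequence[ComplexRecord]) -> list[tuple[str, float]]:
    return [(r.complex_id, model.predict(r)) for r in records]


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    r: float  # Pearson correlation
    rmse: float
    mae: float
    sd: float  # residual std of least-squares regression of y on yhat
    ci: float  # concordance index
    n: int

    def to_dict(self) -> dict:
        return {"R": self.r, "RMSE": self.rmse, "MAE": self.mae,
                "SD": self.sd, "CI": self.ci, "n": self.n}


def concordance_index(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Fraction of comparable pairs (y_i != y_j) whose prediction ordering
    matches the label ordering; prediction ties count 0.5.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    dy = y[:, None] - y[None, :]
    dp = yhat[:, None] - yhat[None, :]
    comparable = dy > 0  # each unordered pair counted once via the larger y
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("concordance index undefined: all labels tied")
    concordant = (dp[comparable] > 0).sum() + 0.5 * (dp[comparable] == 0).sum()
    return float(concordant / n_comp)


def sd_regression(y: Sequence[float], yhat: Sequence[float]) -> float:
    """sqrt( sum (y - a - b*yhat)^2 / (n - 1) ) for the least-squares fit
    y = a + b*yhat."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(yhat) == 0:
        raise ValueError("constant predictions: regression is degenerate")
    b, a = np.polyfit(yhat, y, deg=1)
    resid = y - (a + b * yhat)
    return float(np.sqrt(np.sum(resid ** 2) / (y.size - 1)))


def evaluate(y: Sequence[float], yhat: Sequence[float]) -> MetricsReport:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    r = float(np.corrcoef(y, yhat)[0, 1])
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    mae = float(np.mean(np.abs(y - yhat)))
    return MetricsReport(r=r, rmse=rmse, mae=mae,
                         sd=sd_regression(y, yhat),
                         ci=concordance_index(y, yhat), n=int(y.size))
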