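"""Cross-validated training and evaluation.

Regression uses MSE loss with AdamW; classification uses cross-entropy;
multi-task training sums both losses and uses SGD at the stated rate 9e-3.
Every run steps a cosine-annealing-with-warm-restarts learning-rate schedule
(per epoch). Cross-validation supports KFold, GroupKFold (samples of one
subject never straddle train/test), StratifiedKFold and StratifiedGroupKFold,
with the robust-Aitchison-PCA embedding refit on each training fold and test
folds projected with the train loadings.

The regression target is standardized (z-scored on the training fold) inside
``train`` and un-standardized at prediction time; raw ages sit far from the
network's unit-scale outputs and would stall unit-step optimizers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import (
    GroupKFold,
    KFold,
    StratifiedGroupKFold,
    StratifiedKFold,
)

from ._autograd import Tensor, logsumexp
from .data_io import CountTable, SampleMetadata
from .model import ModelConfig, TrpcaModel
from .rpca import rpca_pipeline

logger = logging.getLogger("trpca")

__all__ = [
    "TrainConfig",
    "EvalReport",
    "TrainedModel",
    "make_splits",
    "train",
    "evaluate",
    "cross_validate",
    "CosineWarmRestarts",
]


@dataclass
class TrainConfig:
    cv_scheme: str = "group_kfold"
    n_folds: int = 10
    group_column: str = "subject_id"
    stratify_column: str | None = None
    loss: str = "mse"
    optimizer: str = "adamw"
    learning_rate: float | None = None  # None -> per-optimizer default
    scheduler_period: int = 10  # epochs to first warm restart
    scheduler_mult: int = 2
    eta_min: float = 0.0
    batch_size: int = 64
    epochs: int = 100
    weight_decay: float = 0.01
    seed: int = 0

    ADAMW_LR = 1e-3
    SGD_LR = 9e-3  # the stated SGD rate for multi-task models

    def __post_init__(self) -> None:
        if self.cv_scheme not in {"kfold", "group_kfold", "stratified_kfold",
                                  "stratified_group_kfold"}:
            raise ValueError(f"unknown cv_scheme {self.cv_scheme!r}")
        if self.optimizer not in {"adamw", "sgd"}:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @property
    def lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return self.SGD_LR if self.optimizer == "sgd" else self.ADAMW_LR


# -- optimizers & scheduler ------------------------------------------------

class AdamW:
    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)


class SGD:
    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.buf = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            if self.momentum:
                self.buf[i] = self.momentum * self.buf[i] + p.grad
                p.data -= self.lr * self.buf[i]
            else:
                p.data -= self.lr * p.grad


class CosineWarmRestarts:
    """Cosine annealing with warm restarts, stepped once per epoch.

    lr(t) = eta_min + (lr0 - eta_min)(1 + cos(pi * t_cur / period_i)) / 2,
    where the period grows by ``mult`` at every restart and t_cur resets to 0
    (so the learning rate returns exactly to lr0 at each restart boundary).
    """

    def __init__(self, base_lr: float, period: int = 10, mult: int = 2,
                 eta_min: float = 0.0):
        if period < 1:
            raise ValueError("period must be >= 1")
        self.base_lr = base_lr
        self.period = period
        self.mult = mult
        self.eta_min = eta_min
        self.t_cur = 0
        self.t_i = period

    def lr(self) -> float:
        return self.eta_min + (self.base_lr - self.eta_min) * (
            1 + np.cos(np.pi * self.t_cur / self.t_i)) / 2

    def step(self) -> None:
        self.t_cur += 1
        if self.t_cur >= self.t_i:
            self.t_cur = 0
            self.t_i *= self.mult


# -- splits ---------------------------------------------------------------

def make_splits(meta: SampleMetadata, config: TrainConfig,
                labels: np.ndarray | None = None) -> np.ndarray:
    """Assign each sample a test-fold index under the configured CV scheme.

    Grouped schemes keep all samples of one ``group_column`` value in a single
    fold; stratified schemes approximately preserve label proportions
    (``labels`` or the ``stratify_column``). Deterministic given the seed.
    """
    n = len(meta.sample_ids)
    scheme = config.cv_scheme
    groups = None
    if "group" in scheme:
        if config.group_column not in meta.frame.columns:
            raise ValueError(f"group column {config.group_column!r} missing")
        groups = meta.frame[config.group_column].astype(str).to_numpy()
        if pd.isna(meta.frame[config.group_column]).any():
            raise ValueError("group column has missing values")
        n_groups = len(np.unique(groups))
        if n_groups < config.n_folds:
            raise ValueError(f"{n_groups} groups < {config.n_folds} folds")
    if "stratified" in scheme:
        if labels is None:
            if config.stratify_column is None:
                raise ValueError("stratified scheme needs labels or stratify_column")
            labels = meta.frame[config.stratify_column].astype(str).to_numpy()
    splitter = {
        "kfold": lambda: KFold(config.n_folds, shuffle=True, random_state=config.seed),
        "group_kfold": lambda: GroupKFold(config.n_folds),
        "stratified_kfold": lambda: StratifiedKFold(
            config.n_folds, shuffle=True, random_state=config.seed),
        "stratified_group_kfold": lambda: StratifiedGroupKFold(
            config.n_folds, shuffle=True, random_state=config.seed),
    }[scheme]()
    folds = np.full(n, -1, dtype=int)
    X_dummy = np.zeros((n, 1))
    for f, (_, test_idx) in enumerate(splitter.split(X_dummy, labels, groups)):
        folds[test_idx] = f
    assert (folds >= 0).all()
    return folds


# -- training --------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted network plus the target-scaling constants to invert."""

    model: TrpcaModel
    y_mean: float = 0.0
    y_std: float = 1.0
    loss_history: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)

    def predict_age(self, X: np.ndarray) -> np.ndarray:
        out = self.model.predict(X)
        if self.model.config.task == "mtl":
            out = out[:, -1:]
        return out[:, 0] * self.y_std + self.y_mean

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        out = self.model.predict(X)
        n_classes = self.model.config.n_classes
        return np.argmax(out[:, :n_classes], axis=1)


def _mse_loss(pred: Tensor, y: np.ndarray) -> Tensor:
    diff = pred - Tensor(y.reshape(pred.shape))
    return (diff * diff).mean()


def _ce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels.astype(int)] = 1.0
    lse = logsumexp(logits, axis=-1)
    picked = (logits * Tensor(onehot)).sum(axis=-1, keepdims=True)
    return (lse - picked).mean()


def train(
    model_config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray | None = None,
    config: TrainConfig | None = None,
    y_class: np.ndarray | None = None,
) -> TrainedModel:
    """Train a TRPCA model on embeddings ``X``.

    ``y`` is the age target (regression / mtl); ``y_class`` integer labels
    (classification / mtl). Loss per epoch and the scheduled learning rate are
    recorded; a NaN loss aborts with an error suggesting a smaller learning
    rate or batch-size change, the usual response to unstable convergence.
    """
    config = config or TrainConfig()
    cfg = model_config
    task = cfg.task
    if task in {"regression", "mtl"}:
        if y is None or not np.isfinite(y).all():
            raise ValueError("finite age targets required for regression/mtl")
    if task in {"classification", "mtl"}:
        if y_class is None:
            raise ValueError("y_class required for classification/mtl")
    model = TrpcaModel(cfg, seed=config.seed)
    y_mean, y_std = 0.0, 1.0
    y_scaled = None
    if y is not None and task in {"regression", "mtl"}:
        y_mean = float(np.mean(y))
        y_std = float(np.std(y))
        if y_std == 0.0:
            y_std = 1.0
        y_scaled = (np.asarray(y, dtype=float) - y_mean) / y_std

    opt: AdamW | SGD
    if config.optimizer == "adamw":
        opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    else:
        opt = SGD(model.parameters(), lr=config.lr)
    sched = CosineWarmRestarts(config.lr, config.scheduler_period,
                               config.scheduler_mult, config.eta_min)
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    losses: list[float] = []
    lrs: list[float] = []
    model.training = True
    for epoch in range(config.epochs):
        opt.lr = sched.lr()
        lrs.append(opt.lr)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = X[idx]
            model.zero_grad()
            if task == "regression":
                loss = _mse_loss(model.forward(xb), y_scaled[idx])
            elif task == "classification":
                loss = _ce_loss(model.forward(xb), y_class[idx])
            else:
                logits, ages = model.forward_mtl(xb)
                loss = _ce_loss(logits, y_class[idx]) + _mse_loss(ages, y_scaled[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    "training loss diverged (NaN/inf); reduce the learning rate "
                    "or batch size — unstable convergence calls for modified "
                    "training hyperparameters")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / n_batches)
        sched.step()
    model.training = False
    return TrainedModel(model, y_mean, y_std, losses, lrs)


# -- evaluation ------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-fold and aggregate metrics plus per-sample predictions."""

    per_fold: pd.DataFrame  # one row per fold: mae, r2, accuracy, n_test
    per_sample: pd.DataFrame  # sample_id, fold, truth, prediction, residual
    aggregate: dict


def evaluate(predictions: np.ndarray, truth: np.ndarray, task: str = "regression",
             ) -> dict:
    """MAE / R² for regression, accuracy + confusion for classification.

    Residual convention: prediction − truth, so positive means predicted
    older than chronological age.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape[0] != truth.shape[0]:
        raise ValueError("predictions and truth differ in length")
    out: dict = {"n": int(truth.shape[0])}
    if task == "regression":
        resid = predictions - truth
        out["mae"] = float(np.mean(np.abs(resid)))
        sse = float(np.sum(resid ** 2))
        sst = float(np.sum((truth - truth.mean()) ** 2))
        out["r2"] = 1.0 - sse / sst if sst > 0 else float("nan")
        out["residuals"] = resid
    else:
        labels = np.unique(np.concatenate([truth, predictions]))
        out["accuracy"] = float(np.mean(predictions == truth))
        conf = pd.crosstab(pd.Series(truth, name="truth"),
                           pd.Series(predictions, name="pred"),
                           dropna=False).reindex(index=labels, columns=labels,
                                                 fill_value=0)
        out["confusion"] = conf
    return out


def cross_validate(
    model_config: ModelConfig,
    table: CountTable,
    meta: SampleMetadata,
    config: TrainConfig | None = None,
    min_prevalence: int = 25,
    rpca_fit: str = "train",
    labels: np.ndarray | None = None,
) -> EvalReport:
    """Full cross-validated pipeline: RPCA per fold, train, predict test fold.

    ``rpca_fit='train'`` (default, leakage-safe) refits the prevalence filter,
    robust CLR and PCA on every training fold; ``'all'`` fits the embedding
    once on all samples before splitting, matching pipelines that treat the
    unsupervised embedding as a fixed preprocessing step.
    """
    config = config or TrainConfig()
    task = model_config.task
    folds = make_splits(meta, config, labels=labels)
    ages = meta.ages if task in {"regression", "mtl"} else None
    n = table.n_samples
    preds = np.full(n, np.nan)
    cls_preds = np.full(n, -1, dtype=int) if task in {"classification", "mtl"} else None

    shared_rpca = None
    if rpca_fit == "all":
        shared_rpca, _ = rpca_pipeline(table, None, min_prevalence, model_config.pca_dim)
    elif rpca_fit != "train":
        raise ValueError("rpca_fit must be 'train' or 'all'")

    fold_rows = []
    for f in range(config.n_folds):
        test_mask = folds == f
        train_ids = [s for s, m in zip(table.sample_ids, test_mask) if not m]
        test_ids = [s for s, m in zip(table.sample_ids, test_mask) if m]
        if "group" in config.cv_scheme:
            g = meta.frame[config.group_column].astype(str).to_numpy()
            assert not set(g[~test_mask]) & set(g[test_mask]), \
                f"subject overlap between train and test in fold {f}"
        if shared_rpca is not None:
            emb_all = shared_rpca.embedding
            pos = {s: i for i, s in enumerate(table.sample_ids)}
            X_train = emb_all[[pos[s] for s in train_ids]]
            X_test = emb_all[[pos[s] for s in test_ids]]
        else:
            train_table = table.select_samples(train_ids)
            test_table = table.select_samples(test_ids)
            rpca, X_test = rpca_pipeline(train_table, test_table,
                                         min_prevalence, model_config.pca_dim)
            X_train = rpca.embedding
        if X_train.shape[1] != model_config.pca_dim:
            model_config = ModelConfig(**{**model_config.__dict__,
                                          "pca_dim": X_train.shape[1]})
        tr_idx = ~test_mask
        fitted = train(
            model_config, X_train,
            y=None if ages is None else ages[tr_idx],
            config=config,
            y_class=None if labels is None else labels[tr_idx],
        )
        row: dict = {"fold": f, "n_test": int(test_mask.sum())}
        if task in {"regression", "mtl"}:
            p = fitted.predict_age(X_test)
            preds[test_mask] = p
            m = evaluate(p, ages[test_mask], "regression")
            row["mae"], row["r2"] = m["mae"], m["r2"]
            row["null_mae"] = float(np.mean(np.abs(
                ages[tr_idx].mean() - ages[test_mask])))
        if task in {"classification", "mtl"}:
            cp = fitted.predict_class(X_test)
            cls_preds[test_mask] = cp
            row["accuracy"] = evaluate(cp, labels[test_mask], "classification")["accuracy"]
        fold_rows.append(row)
        logger.info("fold %d: %s", f, {k: v for k, v in row.items() if k != "fold"})

    per_fold = pd.DataFrame(fold_rows)
    per_sample = pd.DataFrame({
        "sample_id": table.sample_ids,
        "fold": folds,
    })
    if ages is not None:
        per_sample["truth"] = ages
        per_sample["prediction"] = preds
        per_sample["residual"] = preds - ages
    if cls_preds is not None:
        per_sample["class_truth"] = labels
        per_sample["class_prediction"] = cls_preds
    aggregate = {}
    for col in ("mae", "r2", "accuracy", "null_mae"):
        if col in per_fold:
            aggregate[f"{col}_mean"] = float(per_fold[col].mean())
            aggregate[f"{col}_sd"] = float(per_fold[col].std(ddof=1))
    if ages is not None:
        overall = evaluate(preds, ages, "regression")
        aggregate["mae_overall"] = overall["mae"]
        aggregate["r2_overall"] = overall["r2"]
    if cls_preds is not None:
        aggregate["accuracy_overall"] = float(np.mean(cls_preds == labels))
    return EvalReport(per_fold, per_sample, aggregate)
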