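"""Conventional-regressor benchmark suite.

Five standard models at their published benchmark hyperparameters — SVR (RBF,
C=1.0, epsilon=0.1), gradient boosting (100 estimators, random_state=42),
k-nearest neighbours (k=5), an MLP (one hidden layer of 100 ReLU units, Adam,
max_iter=1000) and random forest (100 trees, random_state=42) — evaluated
with 5-fold cross-validation on the same embedding and the same fold
assignments as the transformer, so comparisons are representation- and
split-controlled.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GroupKFold, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

logger = logging.getLogger("trpca")

__all__ = [
    "baseline_models",
    "run_baseline_suite",
    "percent_improvement",
    "best_reference",
]

BASELINE_NAMES = ("SVR", "GBR", "KNN", "NN", "RF")


def baseline_models(seed: int = 0) -> dict:
    """The five reference regressors with their fixed hyperparameters.

    GBR and RF carry their own stated random_state=42; the MLP's weights take
    the suite seed.
    """
    return {
        "SVR": SVR(kernel="rbf", C=1.0, epsilon=0.1),
        "GBR": GradientBoostingRegressor(n_estimators=100, random_state=42),
        "KNN": KNeighborsRegressor(n_neighbors=5),
        "NN": MLPRegressor(hidden_layer_sizes=(100,), activation="relu",
                           solver="adam", max_iter=1000, random_state=seed),
        "RF": RandomForestRegressor(n_estimators=100, random_state=42),
    }


def fold_hash(fold_indices: list[tuple[np.ndarray, np.ndarray]]) -> str:
    """Stable digest of fold assignments, to assert split identity."""
    h = hashlib.sha256()
    for train_idx, test_idx in fold_indices:
        h.update(np.asarray(train_idx, dtype=np.int64).tobytes())
        h.update(b"|")
        h.update(np.asarray(test_idx, dtype=np.int64).tobytes())
        h.update(b"#")
    return h.hexdigest()


def make_fold_indices(n: int, n_folds: int = 5, seed: int = 0,
                      groups: np.ndarray | None = None,
                      ) -> list[tuple[np.ndarray, np.ndarray]]:
    if groups is not None:
        splitter = GroupKFold(n_splits=n_folds)
        return [(tr, te) for tr, te in splitter.split(np.zeros((n, 1)), groups=groups)]
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros((n, 1)))]


def run_baseline_suite(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Cross-validated MAE for all five baselines on identical folds.

    Returns a tidy frame (model × fold, columns mae / null_mae) with the fold
    hash attached in ``.attrs`` for split-identity assertions. ``folds`` may
    be supplied to reuse another model's assignments.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"n={n} samples < n_folds={n_folds}")
    if folds is None:
        folds = make_fold_indices(n, n_folds, seed, groups)
    rows = []
    for name in BASELINE_NAMES:
        for f, (tr, te) in enumerate(folds):
            est = baseline_models(seed)[name]  # fresh estimator per fold
            est.fit(X[tr], y[tr])
            pred = est.predict(X[te])
            rows.append({
                "model": name,
                "fold": f,
                "mae": float(np.mean(np.abs(pred - y[te]))),
                "null_mae": float(np.mean(np.abs(y[tr].mean() - y[te]))),
                "n_test": len(te),
            })
    out = pd.DataFrame(rows)
    out.attrs["fold_hash"] = fold_hash(folds)
    return out


def percent_improvement(mae_reference, mae_trpca) -> float | tuple[float, float]:
    """100·(ref − trpca)/ref; arrays are treated per fold → (mean, sd).

    A positive value means the transformer's error is lower than the
    reference model's.
    """
    ref = np.atleast_1d(np.asarray(mae_reference, dtype=float))
    new = np.atleast_1d(np.asarray(mae_trpca, dtype=float))
    if (ref <= 0).any():
        raise ValueError("reference MAE must be positive")
    if ref.shape != new.shape:
        raise ValueError("per-fold inputs must have matching shapes")
    imp = 100.0 * (ref - new) / ref
    if imp.size == 1:
        return float(imp[0])
    return float(imp.mean()), float(imp.std(ddof=1))


def best_reference(suite: pd.DataFrame) -> tuple[str, float]:
    """Model with the lowest mean MAE; ties break alphabetically (logged)."""
    if len(suite) == 0:
        raise ValueError("empty baseline suite")
    means = suite.groupby("model")["mae"].mean()
    best_mae = means.min()
    tied = sorted(means.index[means == best_mae])
    if len(tied) > 1:
        logger.info("best_reference tie among %s; choosing %s", tied, tied[0])
    return tied[0], float(best_mae)
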