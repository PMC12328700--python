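"""Robust Aitchison PCA: prevalence filtering, robust CLR, PCA embedding.

The robust centered log-ratio (RCLR) transform takes the natural log of each
sample's *nonzero* counts and centers them by the mean log of that sample's
nonzero entries, leaving zeros out of the geometric mean. The resulting matrix
is treated as complete by filling absent entries with 0 — the least-informative
value after CLR centering — and embedded by ordinary PCA. Scores ("RPCA
embedding"), loadings and centering offsets are retained so that held-out
samples can be projected without refitting and so that Shapley values over
components can be back-projected into feature space.

Full matrix-completion RPCA (OptSpace-style) is deliberately not implemented;
the zero-fill-plus-PCA route is documented in docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .data_io import CountTable

logger = logging.getLogger("trpca")

__all__ = [
    "RclrMatrix",
    "RpcaResult",
    "filter_prevalence",
    "rclr_transform",
    "fit_rpca",
    "transform_new",
    "rpca_pipeline",
]

DEFAULT_MIN_PREVALENCE = 25
DEFAULT_N_COMPONENTS = 256
RCLR_FILL = 0.0  # value standing in for absent (zero-count) entries


@dataclass
class RclrMatrix:
    """RCLR-transformed table: values plus a mask of observed entries."""

    values: np.ndarray  # n × k, absent entries at RCLR_FILL
    present_mask: np.ndarray  # n × k bool, True where the count was nonzero
    sample_ids: list[str]
    feature_ids: list[str]


@dataclass
class RpcaResult:
    """PCA of the filled RCLR matrix with everything needed to re-project.

    ``embedding`` holds per-sample component scores (n × j), ``loadings`` the
    orthonormal component × feature matrix (j × k), ``feature_means`` the
    feature-wise centering offsets of the filled matrix.
    """

    embedding: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    feature_means: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def filter_prevalence(table: CountTable, min_samples: int = DEFAULT_MIN_PREVALENCE) -> CountTable:
    """Drop features nonzero in fewer than ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    prevalence = (table.counts > 0).sum(axis=0)
    keep = prevalence >= min_samples
    if not keep.any():
        raise ValueError(
            f"prevalence filter at min_samples={min_samples} removed every feature"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence filter: dropped %d/%d features (< %d samples)",
                    dropped, table.n_features, min_samples)
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    return table.select_features(kept_ids)


def rclr_transform(table: CountTable) -> RclrMatrix:
    """Robust CLR: log nonzero counts, center by each sample's mean log.

    Absent entries (zero counts) are excluded from the centering and left at
    ``RCLR_FILL`` with ``present_mask`` False. A sample with no nonzero count
    has no geometric mean and is rejected by name.
    """
    counts = table.counts
    present = counts > 0
    zero_rows = np.flatnonzero(~present.any(axis=1))
    if zero_rows.size:
        bad = [table.sample_ids[i] for i in zero_rows]
        raise ValueError(f"all-zero sample(s), RCLR undefined: {bad[:5]}")
    logs = np.zeros(counts.shape, dtype=float)
    np.log(counts, where=present, out=logs)
    sample_mean = logs.sum(axis=1) / present.sum(axis=1)
    values = np.where(present, logs - sample_mean[:, None], RCLR_FILL)
    return RclrMatrix(values, present, list(table.sample_ids), list(table.feature_ids))


def _fix_signs(loadings: np.ndarray, embedding: np.ndarray) -> None:
    """Flip each component so its largest-|loading| entry is positive (in place)."""
    for j in range(loadings.shape[0]):
        pivot = np.argmax(np.abs(loadings[j]))
        if loadings[j, pivot] < 0:
            loadings[j] *= -1.0
            embedding[:, j] *= -1.0


def fit_rpca(rclr: RclrMatrix, n_components: int = DEFAULT_N_COMPONENTS) -> RpcaResult:
    """PCA of the feature-centered filled RCLR matrix, top-j components.

    ``n_components`` is capped at ``n_samples - 1`` (with a warning) and at
    ``n_features`` — a cohort of n samples supports at most n−1 principal
    components, the reason the smallest real cohorts use 64 rather than 256.
    """
    X = rclr.values
    n, k = X.shape
    if n_components >= n:
        logger.warning("n_components=%d >= n_samples=%d; reducing to %d",
                       n_components, n, n - 1)
        n_components = n - 1
    n_components = min(n_components, k)
    if n_components < 1:
        raise ValueError("need at least 2 samples and 1 feature for PCA")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    _fix_signs(loadings, scores)
    return RpcaResult(
        embedding=scores,
        loadings=loadings,
        explained_variance=pca.explained_variance_ratio_.copy(),
        feature_means=pca.mean_.copy(),
        feature_ids=list(rclr.feature_ids),
        sample_ids=list(rclr.sample_ids),
    )


def transform_new(rpca: RpcaResult, rclr_new: RclrMatrix) -> np.ndarray:
    """Project held-out RCLR rows onto trained loadings: (X − mean)·Lᵀ.

    Keeping this separate from :func:`fit_rpca` lets cross-validation fit the
    embedding on training folds only, so test samples never shape the loadings.
    """
    if list(rclr_new.feature_ids) != list(rpca.feature_ids):
        raise ValueError("feature ids of new samples do not match the trained RPCA")
    return (rclr_new.values - rpca.feature_means) @ rpca.loadings.T


def rpca_pipeline(
    train_table: CountTable,
    test_table: CountTable | None = None,
    min_samples: int = DEFAULT_MIN_PREVALENCE,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> tuple[RpcaResult, np.ndarray | None]:
    """Prevalence-filter + RCLR + PCA on train; project test with train loadings.

    The prevalence filter is fit on the training table and its feature set is
    imposed on the test table (leakage-safe); returns the fitted
    :class:`RpcaResult` and, if a test table was given, its embedding.
    """
    filtered = filter_prevalence(train_table, min_samples)
    rpca = fit_rpca(rclr_transform(filtered), n_components)
    test_embedding = None
    if test_table is not None:
        test_filtered = test_table.select_features(filtered.feature_ids)
        test_embedding = transform_new(rpca, rclr_transform(test_filtered))
    return rpca, test_embedding
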