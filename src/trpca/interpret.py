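"""Shapley attribution over PCA components and back-projection to features.

Attributions are estimated with a model-agnostic interventional permutation
scheme: component values are switched one at a time from a background sample's
values to the explained sample's values along random feature orderings, and
the resulting prediction increments are averaged over orderings and background
rows. The estimator is additive by construction (base value + attributions =
prediction, exactly) and exact for models linear in the components.

Component-level attributions are mapped to the original microbial features by
the dot product with the PCA loading matrix:

    FeatureImportance (n × k) = ShapMatrix (n × j) · Loadings (j × k)

which distributes each component's credit over the features that define it,
retaining sign (positive = pushes the prediction up, toward older ages).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .data_io import CountTable, SampleMetadata
from .rpca import RpcaResult

logger = logging.getLogger("trpca")

__all__ = [
    "ShapMatrix",
    "FeatureImportanceMatrix",
    "compute_shap",
    "project_importances",
    "global_importances",
    "sample_heatmap_data",
    "importance_correlations",
    "feature_age_correlation",
]

DEFAULT_N_PERMUTATIONS = 10
MAX_BACKGROUND = 100


@dataclass
class ShapMatrix:
    """Per-sample, per-component attributions with the background base value."""

    values: np.ndarray  # n_test × j
    base_value: float
    background_size: int


@dataclass
class FeatureImportanceMatrix:
    """Signed per-sample feature importances after loading back-projection."""

    values: np.ndarray  # n_test × k
    sample_ids: list[str] | None = None
    feature_ids: list[str] | None = None


def compute_shap(
    predict_fn,
    X_test: np.ndarray,
    background: np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    batch_rows: int = 4096,
) -> ShapMatrix:
    """Interventional permutation-Shapley attributions of ``predict_fn``.

    ``predict_fn`` maps an (m, j) array to m scalar predictions. For each test
    sample and each of ``n_permutations`` random component orderings, the
    sample's components are inserted one by one into every background row; the
    averaged prediction increments are that sample's attributions. For a model
    linear in its inputs the result is exact for any number of permutations.
    """
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if background.shape[0] == 1:
        warnings.warn("background of size 1: the expected value is degenerate",
                      stacklevel=2)
    if background.shape[0] > MAX_BACKGROUND:
        rng_bg = np.random.default_rng(seed)
        keep = rng_bg.choice(background.shape[0], MAX_BACKGROUND, replace=False)
        background = background[np.sort(keep)]
    n, j = X_test.shape
    m = background.shape[0]
    rng = np.random.default_rng(seed)
    base_value = float(np.mean(predict_fn(background)))
    values = np.zeros((n, j))
    for i in range(n):
        x = X_test[i]
        acc = np.zeros(j)
        for _ in range(n_permutations):
            order = rng.permutation(j)
            # grid[s] = background with x substituted at order[:s]
            grid = np.repeat(background[None, :, :], j + 1, axis=0)  # (j+1, m, j)
            mask = np.zeros(j, dtype=bool)
            for s, comp in enumerate(order, start=1):
                mask[comp] = True
                grid[s:, :, comp] = x[comp]
            flat = grid.reshape((j + 1) * m, j)
            preds = np.empty((j + 1) * m)
            for start in range(0, flat.shape[0], batch_rows):
                preds[start:start + batch_rows] = np.asarray(
                    predict_fn(flat[start:start + batch_rows])).reshape(-1)
            step_means = preds.reshape(j + 1, m).mean(axis=1)
            acc[order] += np.diff(step_means)
        values[i] = acc / n_permutations
    return ShapMatrix(values=values, base_value=base_value, background_size=m)


def project_importances(shap: ShapMatrix, rpca: RpcaResult) -> FeatureImportanceMatrix:
    """Back-project component attributions through the PCA loadings."""
    if shap.values.shape[1] != rpca.loadings.shape[0]:
        raise ValueError(
            f"{shap.values.shape[1]} attribution components != "
            f"{rpca.loadings.shape[0]} loading rows")
    return FeatureImportanceMatrix(
        values=shap.values @ rpca.loadings,
        feature_ids=list(rpca.feature_ids),
    )


def global_importances(fi: FeatureImportanceMatrix) -> pd.Series:
    """Signed per-feature means over samples, sorted by |mean| descending.

    Positive mean importance marks features associated with older predicted
    age, negative with younger.
    """
    means = fi.values.mean(axis=0)
    idx = fi.feature_ids if fi.feature_ids is not None else list(range(len(means)))
    s = pd.Series(means, index=idx, name="mean_importance")
    return s.iloc[np.argsort(-np.abs(s.to_numpy()), kind="stable")]


def sample_heatmap_data(
    fi: FeatureImportanceMatrix,
    top_k: int = 50,
    normalization: str = "per_sample",
) -> dict:
    """Top-k features by |global mean|, normalized and hierarchically clustered.

    Normalization: ``per_sample`` divides each row by its own max |importance|
    (``global`` by the matrix-wide max), bounding magnitudes by 1. Rows and
    columns are ordered by average-linkage hierarchical clustering on
    Euclidean distance; dendrogram leaf orders are returned.
    """
    k = fi.values.shape[1]
    if top_k > k:
        raise ValueError(f"top_k={top_k} exceeds {k} features")
    ranked = global_importances(fi)
    feature_ids = fi.feature_ids if fi.feature_ids is not None else list(range(k))
    top_features = list(ranked.index[:top_k])
    pos = {f: i for i, f in enumerate(feature_ids)}
    sub = fi.values[:, [pos[f] for f in top_features]]
    if normalization == "per_sample":
        denom = np.abs(sub).max(axis=1, keepdims=True)
    elif normalization == "global":
        denom = np.abs(sub).max()
    else:
        raise ValueError("normalization must be 'per_sample' or 'global'")
    denom = np.where(denom == 0, 1.0, denom)
    norm = sub / denom

    def order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 2:
            return np.arange(mat.shape[0])
        return leaves_list(linkage(mat, method="average", metric="euclidean"))

    row_order = order(norm)
    col_order = order(norm.T)
    return {
        "matrix": norm[np.ix_(row_order, col_order)],
        "row_order": row_order,
        "col_order": col_order,
        "features": [top_features[i] for i in col_order],
        "sample_ids": ([fi.sample_ids[i] for i in row_order]
                       if fi.sample_ids is not None else list(row_order)),
    }


def importance_correlations(
    fi_by_model: dict[str, FeatureImportanceMatrix],
    level: str = "global",
) -> pd.DataFrame:
    """Pairwise Pearson agreement of importances across models.

    ``level='global'`` correlates per-feature mean importances (default);
    ``'per_sample'`` correlates the flattened sample × feature matrices.
    Zero-variance vectors give NaN (undefined), never 0.
    """
    names = list(fi_by_model)
    vecs = {}
    for nm, fi in fi_by_model.items():
        v = fi.values.mean(axis=0) if level == "global" else fi.values.ravel()
        vecs[nm] = np.asarray(v, dtype=float)
    lengths = {v.size for v in vecs.values()}
    if len(lengths) > 1:
        raise ValueError("importance matrices have mismatched shapes")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = vecs[a], vecs[b]
            if va.std() == 0 or vb.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def feature_age_correlation(
    table: CountTable, meta: SampleMetadata, feature_id: str,
) -> float:
    """Pearson correlation of ln(count + 1) with host age for one feature.

    Returns NaN when the feature is constant across samples (undefined
    correlation). The +1 pseudocount keeps zero counts in the analysis.
    """
    if feature_id not in table.feature_ids:
        raise KeyError(f"feature {feature_id!r} not in table")
    col = table.counts[:, table.feature_ids.index(feature_id)]
    logs = np.log(col + 1.0)
    ages = meta.select(table.sample_ids).ages
    if np.ptp(logs) == 0 or np.ptp(ages) == 0:  # constant -> undefined
        return float("nan")
    return float(np.corrcoef(logs, ages)[0, 1])
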