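"""Residual concordance and permutation sensitivity statistics.

Age residuals (prediction − truth) from paired modalities (e.g. 16S vs
shotgun stool, or oral vs gut) are compared subject-by-subject with the
squared Pearson correlation. Associations between residuals and metadata
variables are tested non-parametrically: Kruskal–Wallis H for categorical
variables (upper-tail permutation null, H is non-negative), Spearman rank
correlation for continuous ones (two-sided on |rho|), with empirical p-values
from B random permutations, p = (1 + #extreme) / (B + 1), and
Benjamini–Hochberg FDR adjustment across the variable set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ResidualTable",
    "SensitivityResult",
    "paired_residual_r2",
    "sensitivity_test",
    "sensitivity_scan",
    "bh_fdr",
]

DEFAULT_B = 1000


@dataclass
class ResidualTable:
    """Long-format residuals: one row per (subject, modality)."""

    frame: pd.DataFrame  # columns: subject_id, modality, residual

    def __post_init__(self) -> None:
        need = {"subject_id", "modality", "residual"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"residual table missing columns: {sorted(missing)}")
        if self.frame.duplicated(["subject_id", "modality"]).any():
            raise ValueError("more than one residual per (subject, modality)")


@dataclass
class SensitivityResult:
    variable: str
    kind: str  # categorical | continuous
    statistic: float  # Kruskal-Wallis H or Spearman rho
    p_value: float
    q_value: float | None
    n: int


def paired_residual_r2(
    res: ResidualTable, modality_a: str, modality_b: str,
) -> dict:
    """Squared Pearson correlation of paired per-subject residuals.

    Subjects lacking either modality are dropped (and counted). Note the
    estimator is sign-blind: perfectly anti-correlated residuals also give
    R² = 1.
    """
    df = res.frame
    wide = df.pivot(index="subject_id", columns="modality", values="residual")
    for m in (modality_a, modality_b):
        if m not in wide.columns:
            raise ValueError(f"modality {m!r} not present")
    pairs = wide[[modality_a, modality_b]].dropna()
    n_dropped = len(wide) - len(pairs)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(pairs)}")
    a = pairs[modality_a].to_numpy(dtype=float)
    b = pairs[modality_b].to_numpy(dtype=float)
    r = float(np.corrcoef(a, b)[0, 1])
    return {
        "r2": r * r,
        "r": r,
        "n_pairs": len(pairs),
        "n_dropped": n_dropped,
        "pairs": pairs.reset_index(),
    }


def _kruskal_h(ranks: np.ndarray, group_sizes: np.ndarray, tie_factor: float) -> float:
    """H from a rank vector ordered so groups are contiguous blocks."""
    n = ranks.size
    bounds = np.concatenate([[0], np.cumsum(group_sizes)])
    h = 0.0
    for g in range(group_sizes.size):
        rsum = ranks[bounds[g]:bounds[g + 1]].sum()
        h += rsum * rsum / group_sizes[g]
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_factor if tie_factor > 0 else float("nan")


def sensitivity_test(
    residuals: np.ndarray,
    values: np.ndarray | pd.Series,
    kind: str,
    B: int = DEFAULT_B,
    seed: int = 0,
    variable: str = "variable",
) -> SensitivityResult:
    """Permutation test of residual association with one metadata variable.

    Missing variable values (NaN / empty) are dropped pairwise with their
    residuals; the effective n is reported. Deterministic given the seed.
    """
    residuals = np.asarray(residuals, dtype=float)
    values = pd.Series(values)
    if kind not in {"categorical", "continuous"}:
        raise ValueError("kind must be 'categorical' or 'continuous'")
    mask = values.notna().to_numpy()
    if kind == "categorical":
        mask &= values.astype(object).ne("").fillna(False).to_numpy()
    else:
        values = pd.to_numeric(values, errors="coerce")
        mask = values.notna().to_numpy()
    mask &= np.isfinite(residuals)
    r = residuals[mask]
    v = values[mask]
    n = r.size
    rng = np.random.default_rng(seed)

    if n and (r == r[0]).all():
        # constant residuals carry no rank information: statistic 0, p = 1
        if kind == "categorical":
            groups = v.astype(str).to_numpy()
            if np.unique(groups).size < 2:
                raise ValueError(
                    f"variable {variable!r}: fewer than 2 groups after NA removal")
        return SensitivityResult(variable=variable, kind=kind, statistic=0.0,
                                 p_value=1.0, q_value=None, n=int(n))

    if kind == "categorical":
        groups = v.astype(str).to_numpy()
        uniq, counts = np.unique(groups, return_counts=True)
        if uniq.size < 2:
            raise ValueError(f"variable {variable!r}: fewer than 2 groups after NA removal")
        ranks = sps.rankdata(r)
        # tie correction is permutation-invariant: depends on ranks only
        _, tie_counts = np.unique(r, return_counts=True)
        tie_factor = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
        order = np.argsort(groups, kind="stable")
        obs = _kruskal_h(ranks[order], counts, tie_factor)
        perm_stats = np.empty(B)
        for b in range(B):
            perm_stats[b] = _kruskal_h(rng.permutation(ranks), counts, tie_factor)
        p = (1.0 + np.sum(perm_stats >= obs)) / (B + 1.0)
        stat = obs
    else:
        if n < 3:
            raise ValueError(f"variable {variable!r}: fewer than 3 complete pairs")
        x = sps.rankdata(r)
        y = sps.rankdata(v.to_numpy(dtype=float))
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"variable {variable!r}: constant after NA removal")
        obs = float(np.corrcoef(x, y)[0, 1])
        xc = (x - x.mean()) / x.std()
        yc = (y - y.mean()) / y.std()
        perm_stats = np.empty(B)
        for b in range(B):
            perm_stats[b] = np.mean(xc * rng.permutation(yc))
        p = (1.0 + np.sum(np.abs(perm_stats) >= abs(obs))) / (B + 1.0)
        stat = obs
    return SensitivityResult(variable=variable, kind=kind, statistic=float(stat),
                             p_value=float(p), q_value=None, n=int(n))


def sensitivity_scan(
    residuals: np.ndarray,
    meta: pd.DataFrame,
    variables: dict[str, str],
    B: int = DEFAULT_B,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`sensitivity_test` per variable and BH-adjust across them."""
    results = []
    for i, (var, kind) in enumerate(variables.items()):
        res = sensitivity_test(residuals, meta[var], kind, B=B, seed=seed + i,
                               variable=var)
        results.append(res)
    qs = bh_fdr(np.array([r.p_value for r in results]))
    rows = []
    for r, q in zip(results, qs):
        r.q_value = float(q)
        rows.append(r.__dict__)
    return pd.DataFrame(rows)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
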