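"""Count-table and metadata I/O.

Tables are sample × feature matrices of non-negative integer counts, read and
written as plain TSV (samples as rows, header row of feature ids) or BIOM
v2.1 (HDF5, features-as-rows per the BIOM convention). Metadata is a TSV with
one row per sample. Relative-abundance tables are converted to counts by
multiplying by per-sample sequencing depth and rounding half-to-even.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("trpca")

__all__ = [
    "CountTable",
    "SampleMetadata",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "relabund_to_counts",
    "align",
]


@dataclass
class CountTable:
    """Sample × feature non-negative integer count matrix.

    Parameters
    ----------
    sample_ids, feature_ids
        Unique, ordered identifiers for rows and columns.
    counts
        ``(n_samples, n_features)`` array of non-negative integers.
    taxonomy
        Optional per-feature label strings (same length as ``feature_ids``).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D sample × feature matrix")
        if counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.feature_ids)} features"
            )
        if np.issubdtype(counts.dtype, np.floating):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = np.round(counts)
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("negative count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.taxonomy is not None and len(self.taxonomy) != len(self.feature_ids):
            raise ValueError("taxonomy length must match feature_ids")
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)

    def select_samples(self, ids: list[str]) -> "CountTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return CountTable(list(ids), list(self.feature_ids), self.counts[idx], self.taxonomy)

    def select_features(self, ids: list[str]) -> "CountTable":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in ids]
        tax = [self.taxonomy[i] for i in idx] if self.taxonomy is not None else None
        return CountTable(list(self.sample_ids), list(ids), self.counts[:, idx], tax)


@dataclass
class SampleMetadata:
    """Per-sample metadata: subject grouping, age in years, covariates.

    Missing covariate values are kept as NA; ``age`` must be present and
    non-negative for every sample used in regression.
    """

    frame: pd.DataFrame = field(repr=False)

    SAMPLE_COL = "sample_id"
    SUBJECT_COL = "subject_id"
    AGE_COL = "age"

    def __post_init__(self) -> None:
        df = self.frame
        if self.SAMPLE_COL not in df.columns:
            raise ValueError(f"metadata must have a '{self.SAMPLE_COL}' column")
        df = df.copy()
        df[self.SAMPLE_COL] = df[self.SAMPLE_COL].astype(str)
        if df[self.SAMPLE_COL].duplicated().any():
            dups = df[self.SAMPLE_COL][df[self.SAMPLE_COL].duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups[:5]}")
        if self.AGE_COL in df.columns:
            ages = pd.to_numeric(df[self.AGE_COL], errors="coerce")
            if (ages.dropna() < 0).any():
                raise ValueError("negative age in metadata")
            df[self.AGE_COL] = ages
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame[self.SAMPLE_COL].tolist()

    @property
    def ages(self) -> np.ndarray:
        return self.frame[self.AGE_COL].to_numpy(dtype=float)

    @property
    def subjects(self) -> np.ndarray:
        return self.frame[self.SUBJECT_COL].astype(str).to_numpy()

    def select(self, ids: list[str]) -> "SampleMetadata":
        sub = self.frame.set_index(self.SAMPLE_COL).loc[ids].reset_index()
        return SampleMetadata(sub)


# -- readers / writers -----------------------------------------------------

def read_count_table(path: str | Path, format: str | None = None) -> CountTable:
    """Read a count table from TSV (samples as rows) or BIOM v2.1 (HDF5).

    ``format`` is inferred from the suffix (``.biom`` → biom, else tsv) when
    not given. Negative, non-numeric, or non-integral cells are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in count table {path}: {exc}") from exc
        if np.isnan(values).any():
            raise ValueError(f"non-numeric or missing cell in count table {path}")
        if (values < 0).any():
            raise ValueError(f"negative count in {path}")
        return CountTable(list(df.index.astype(str)), list(df.columns.astype(str)), values)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format!r} (expected 'biom' or 'tsv')")


def write_count_table(table: CountTable, path: str | Path, format: str | None = None) -> None:
    """Write a count table as TSV or BIOM v2.1; format inferred from suffix."""
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        table.to_frame().to_csv(path, sep="\t", index_label="sample_id")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={SampleMetadata.SAMPLE_COL: str}, na_values=["", "NA"])
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


# BIOM v2.1 stores the matrix twice (CSR by observation and by sample) plus
# id lists and format attributes; this is the minimal compliant subset.

def _write_biom(table: CountTable, path: Path) -> None:
    mat_sample = sp.csr_matrix(table.counts.astype(np.float64))
    mat_obs = sp.csr_matrix(table.counts.T.astype(np.float64))
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "No Table ID"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = "http://biom-format.org"
        h5.attrs["format-version"] = np.array([2, 1], dtype=np.int64)
        h5.attrs["generated-by"] = "trpca"
        h5.attrs["creation-date"] = datetime.datetime.now().isoformat()
        h5.attrs["shape"] = np.array([table.n_features, table.n_samples], dtype=np.int64)
        h5.attrs["nnz"] = int(mat_obs.nnz)
        obs = h5.create_group("observation")
        obs.create_dataset("ids", data=np.array(table.feature_ids, dtype="S"))
        og = obs.create_group("matrix")
        og.create_dataset("data", data=mat_obs.data)
        og.create_dataset("indices", data=mat_obs.indices.astype(np.int64))
        og.create_dataset("indptr", data=mat_obs.indptr.astype(np.int64))
        ometa = obs.create_group("metadata")
        if table.taxonomy is not None:
            ometa.create_dataset("taxonomy", data=np.array(table.taxonomy, dtype="S"))
        obs.create_group("group-metadata")
        sam = h5.create_group("sample")
        sam.create_dataset("ids", data=np.array(table.sample_ids, dtype="S"))
        sg = sam.create_group("matrix")
        sg.create_dataset("data", data=mat_sample.data)
        sg.create_dataset("indices", data=mat_sample.indices.astype(np.int64))
        sg.create_dataset("indptr", data=mat_sample.indptr.astype(np.int64))
        sam.create_group("metadata")
        sam.create_group("group-metadata")


def _read_biom(path: Path) -> CountTable:
    with h5py.File(path, "r") as h5:
        feature_ids = [x.decode() for x in h5["observation/ids"][:]]
        sample_ids = [x.decode() for x in h5["sample/ids"][:]]
        g = h5["sample/matrix"]
        mat = sp.csr_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]),
            shape=(len(sample_ids), len(feature_ids)),
        )
        taxonomy = None
        if "observation/metadata/taxonomy" in h5:
            raw = h5["observation/metadata/taxonomy"][:]
            taxonomy = [x.decode() if isinstance(x, bytes) else str(x) for x in raw]
    dense = np.asarray(mat.todense())
    if (dense < 0).any():
        raise ValueError(f"negative count in {path}")
    return CountTable(sample_ids, feature_ids, dense, taxonomy)


# -- conversions -----------------------------------------------------------

def relabund_to_counts(
    relabund: np.ndarray,
    depths: np.ndarray,
    sample_ids: list[str] | None = None,
    feature_ids: list[str] | None = None,
) -> CountTable:
    """Convert relative abundances to counts: ``round(relabund * depth)``.

    Each feature's fraction is multiplied by its sample's sequencing depth and
    rounded to the nearest whole number; exact halves round to even (numpy
    ``rint``). Row sums may therefore differ from the depth by at most half a
    count per feature.
    """
    relabund = np.asarray(relabund, dtype=float)
    depths = np.asarray(depths)
    if (relabund < 0).any():
        raise ValueError("negative fraction in relative-abundance table")
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    if relabund.ndim != 2 or depths.shape != (relabund.shape[0],):
        raise ValueError("relabund must be n×k with one depth per row")
    if (relabund.sum(axis=1) > 1 + 1e-6).any():
        raise ValueError("relative-abundance rows must sum to at most 1")
    counts = np.rint(relabund * depths[:, None]).astype(np.int64)
    n, k = counts.shape
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if feature_ids is None:
        feature_ids = [f"F{j}" for j in range(k)]
    return CountTable(sample_ids, feature_ids, counts)


def align(table: CountTable, meta: SampleMetadata) -> tuple[CountTable, SampleMetadata]:
    """Restrict table and metadata to their common samples, in table order.

    Samples appearing in only one input are dropped (logged). An all-zero
    sample row after alignment is an error: it carries no compositional
    information and would break the robust CLR transform downstream.
    """
    meta_ids = set(meta.sample_ids)
    shared = [s for s in table.sample_ids if s in meta_ids]
    if not shared:
        raise ValueError("no samples shared between count table and metadata")
    dropped_t = [s for s in table.sample_ids if s not in meta_ids]
    dropped_m = [s for s in meta.sample_ids if s not in set(table.sample_ids)]
    if dropped_t:
        logger.info("align: dropped %d table samples without metadata: %s%s",
                    len(dropped_t), dropped_t[:5], "..." if len(dropped_t) > 5 else "")
    if dropped_m:
        logger.info("align: dropped %d metadata samples without counts: %s%s",
                    len(dropped_m), dropped_m[:5], "..." if len(dropped_m) > 5 else "")
    sub_table = table.select_samples(shared)
    zero_rows = np.flatnonzero(sub_table.counts.sum(axis=1) == 0)
    if zero_rows.size:
        bad = [shared[i] for i in zero_rows]
        raise ValueError(f"all-zero sample rows after alignment: {bad[:5]}")
    return sub_table, meta.select(shared)
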