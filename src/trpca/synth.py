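"""Synthetic microbiome cohort generator.

Produces the statistical structures the pipeline assumes, without any real
data: overdispersed zero-rich compositional counts, a block of taxa whose
log-abundance trends monotonically with host age, repeated samples per
subject, country-like categorical group shifts on a disjoint taxon block, and
paired two-modality designs sharing a per-subject age-deviation latent delta.

Counts are multinomial draws over the softmax of Gaussian log-abundances with
a per-entry structural-zero Bernoulli mask — the simplest law that is
compositional, overdispersed and zero-inflated. It is a stand-in for testing,
not a model of real microbial ecology. The latent delta (years) shifts the
*effective* age driving the features but not the recorded chronological age,
so any accurate age model inherits delta in its residuals — the mechanism
that makes paired-residual concordance analyses testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CountTable, SampleMetadata

__all__ = ["SyntheticSpec", "generate_cohort", "generate_paired"]


@dataclass
class SyntheticSpec:
    """Cohort parameters. Defaults give a clearly learnable age signal.

    ``effect_size`` is the slope of an informative feature's expected natural-
    log abundance per decade of age; ``subject_deviation_sd`` the sd (years)
    of the shared per-subject age-deviation latent; ``dispersion`` the sd of
    per-observation log-abundance noise; ``zero_inflation`` the structural-
    zero probability per entry.
    """

    n_subjects: int = 150
    samples_per_subject: int = 2
    n_features: int = 300
    n_informative: int = 30
    age_range: tuple[float, float] = (18.0, 90.0)
    effect_size: float = 1.0
    n_groups: int = 0
    group_shift: float = 1.0
    n_group_features: int = 30
    subject_deviation_sd: float = 0.0
    depth_range: tuple[int, int] = (2000, 10000)
    dispersion: float = 0.5
    zero_inflation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if self.n_groups and self.n_informative + self.n_group_features > self.n_features:
            raise ValueError("informative + group feature blocks exceed n_features")
        if min(self.subject_deviation_sd, self.dispersion) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.samples_per_subject < 1:
            raise ValueError("samples_per_subject must be >= 1")


def _subject_frame(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = spec.age_range
    subjects = pd.DataFrame({
        "subject_id": [f"subj{i:04d}" for i in range(spec.n_subjects)],
        "age": rng.uniform(lo, hi, spec.n_subjects),
        "delta": (rng.normal(0.0, spec.subject_deviation_sd, spec.n_subjects)
                  if spec.subject_deviation_sd > 0 else np.zeros(spec.n_subjects)),
    })
    if spec.n_groups:
        subjects["group"] = rng.integers(0, spec.n_groups, spec.n_subjects)
    return subjects


def _sample_counts(
    spec: SyntheticSpec,
    subjects: pd.DataFrame,
    rng: np.random.Generator,
    prefix: str,
) -> tuple[CountTable, pd.DataFrame, dict]:
    n = spec.n_subjects * spec.samples_per_subject
    k = spec.n_features
    mid_age = float(np.mean(spec.age_range))
    baseline = rng.normal(0.0, 1.0, k)
    slopes = np.zeros(k)
    informative = np.arange(spec.n_informative)
    # half the informative block rises with age, half falls
    signs = np.where(np.arange(spec.n_informative) % 2 == 0, 1.0, -1.0)
    slopes[informative] = spec.effect_size * signs
    group_offsets = None
    group_block = None
    if spec.n_groups:
        group_block = np.arange(spec.n_informative, spec.n_informative + spec.n_group_features)
        group_offsets = rng.normal(0.0, spec.group_shift,
                                   (spec.n_groups, spec.n_group_features))

    rows = []
    sample_ids, logits = [], np.zeros((n, k))
    i = 0
    for _, subj in subjects.iterrows():
        eff_age = subj["age"] + subj["delta"]
        for rep in range(spec.samples_per_subject):
            sid = f"{prefix}{subj['subject_id']}_r{rep}"
            mu = baseline + slopes * (eff_age - mid_age) / 10.0
            if group_offsets is not None:
                mu = mu.copy()
                mu[group_block] += group_offsets[int(subj["group"])]
            logits[i] = mu + rng.normal(0.0, spec.dispersion, k)
            sample_ids.append(sid)
            row = {"sample_id": sid, "subject_id": subj["subject_id"],
                   "age": subj["age"]}
            if spec.n_groups:
                row["group"] = f"G{int(subj['group'])}"
            rows.append(row)
            i += 1

    if spec.zero_inflation > 0:
        structural = rng.random((n, k)) < spec.zero_inflation
        logits = np.where(structural, -np.inf, logits)
    # guard: keep at least one feature alive per sample
    dead = ~np.isfinite(logits).any(axis=1)
    logits[dead, 0] = 0.0
    expz = np.exp(logits - np.nanmax(np.where(np.isfinite(logits), logits, -np.inf),
                                     axis=1, keepdims=True))
    expz = np.where(np.isfinite(expz), expz, 0.0)
    probs = expz / expz.sum(axis=1, keepdims=True)
    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, n)
    counts = np.empty((n, k), dtype=np.int64)
    for s in range(n):
        counts[s] = rng.multinomial(depths[s], probs[s])
    feature_ids = [f"{prefix}F{j:04d}" for j in range(k)]
    table = CountTable(sample_ids, feature_ids, counts)
    meta = pd.DataFrame(rows)
    truth = {
        "informative_features": [feature_ids[j] for j in informative],
        "slopes": slopes[informative].tolist(),
        "delta": dict(zip(subjects["subject_id"], subjects["delta"])),
        "depths": depths.tolist(),
    }
    return table, meta, truth


def generate_cohort(spec: SyntheticSpec) -> tuple[CountTable, SampleMetadata, dict]:
    """One cohort: counts, metadata (chronological age, subject, group), truth.

    Deterministic given ``spec.seed``. Each sample's counts sum to its sampled
    sequencing depth; the returned truth record carries the per-subject delta,
    the informative feature ids and their slopes for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = _subject_frame(spec, rng)
    table, meta, truth = _sample_counts(spec, subjects, rng, prefix="")
    return table, SampleMetadata(meta), truth


def generate_paired(spec: SyntheticSpec) -> tuple[
        tuple[CountTable, SampleMetadata],
        tuple[CountTable, SampleMetadata],
        dict]:
    """Two modality tables with disjoint features but a shared subject delta.

    Feature dictionaries, baselines and noise are modality-specific; subjects,
    chronological ages and the age-deviation latent delta are shared, so an
    accurate age model's residuals correlate across modalities exactly insofar
    as ``subject_deviation_sd`` dominates the noise.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = _subject_frame(spec, rng)
    table_a, meta_a, truth_a = _sample_counts(spec, subjects, rng, prefix="modA_")
    table_b, meta_b, truth_b = _sample_counts(spec, subjects, rng, prefix="modB_")
    truth = {
        "delta": truth_a["delta"],
        "modA": truth_a,
        "modB": truth_b,
        "subjects": subjects["subject_id"].tolist(),
    }
    return (table_a, SampleMetadata(meta_a)), (table_b, SampleMetadata(meta_b)), truth
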