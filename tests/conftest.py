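import numpy as np
import pytest

from trpca import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small synthetic cohort shared across read-only tests."""
    spec = SyntheticSpec(n_subjects=40, samples_per_subject=2, n_features=80,
                         n_informative=12, seed=3)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_count_table(rng, n=12, k=20, max_count=50):
    """Dense-ish random count table with guaranteed nonzero rows."""
    from trpca import CountTable
    counts = rng.integers(0, max_count, size=(n, k))
    counts[np.arange(n), rng.integers(0, k, n)] += 1  # no all-zero row
    return CountTable([f"s{i}" for i in range(n)],
                      [f"f{j}" for j in range(k)], counts)
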