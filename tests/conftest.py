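import numpy as np
import pandas as pd
import pytest

from mirsig import CountMatrix, SampleAnnotation, SyntheticSpec, generate_dataset


@pytest.fixture
def small_counts() -> CountMatrix:
    """4 miRNAs x 4 samples with distinct library sizes."""
    df = pd.DataFrame(
        [[10, 20, 5, 40], [100, 210, 51, 420], [3, 7, 2, 11], [50, 99, 26, 198]],
        index=["miR-a", "miR-b", "miR-c", "miR-d"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return CountMatrix(df)


@pytest.fixture
def annotations_44():
    return [
        *(SampleAnnotation(f"S{i:03d}", "N0", gleason=6 + i % 4) for i in range(1, 25)),
        *(SampleAnnotation(f"S{i:03d}", "N1", gleason=6 + i % 4) for i in range(25, 45)),
    ]


@pytest.fixture
def random_count_matrix():
    """Factory for random NB count matrices with reproducible seeds."""

    def make(n_mirnas=20, n_samples=3, seed=0, mean=200.0, phi=0.3):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(np.log(mean), 1.0, n_mirnas)
        size = 1.0 / phi
        counts = rng.negative_binomial(
            size, size / (size + base[:, None] * rng.uniform(0.7, 1.4, n_samples)[None, :])
        )
        counts += 1  # keep RLE well-defined on small fixtures
        df = pd.DataFrame(
            counts,
            index=[f"miR-{i:03d}" for i in range(n_mirnas)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
        return CountMatrix(df)

    return make


@pytest.fixture
def default_dataset():
    """One synthetic dataset at generator defaults (fixed seed) with its truth."""
    return generate_dataset(SyntheticSpec(seed=11))
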