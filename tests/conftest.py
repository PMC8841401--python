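import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ptermark import (
    CountMatrix,
    SampleSheet,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 4 samples with lengths, hand-checkable."""
    counts = np.array([
        [10, 20, 5, 7],
        [40, 80, 20, 28],
        [0, 0, 0, 0],
    ])
    return CountMatrix(
        ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], counts,
        feature_lengths=np.array([1000, 2000, 500]),
    )


@pytest.fixture
def two_class_sheet() -> SampleSheet:
    frame = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "tissue_class": ["pterygium", "pterygium", "healthy", "healthy"],
        "cohort": ["training"] * 4,
    }).set_index("sample_id")
    return SampleSheet(frame, "pterygium")


def two_group_sheet(n1: int, n2: int, prefix: str = "s") -> SampleSheet:
    ids = [f"{prefix}{j}" for j in range(n1 + n2)]
    frame = pd.DataFrame({
        "sample_id": ids,
        "tissue_class": ["A"] * n1 + ["B"] * n2,
        "cohort": ["training"] * (n1 + n2),
    }).set_index("sample_id")
    return SampleSheet(frame, "A")


def nb_counts(rng, mu, alpha, n_samples):
    """NB draws with var = mu + alpha mu^2; mu is per-gene."""
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu[:, None], (mu.size, n_samples))
    size = 1.0 / alpha
    p = size / (size + mu[:, None])
    return rng.negative_binomial(size, p, (mu.size, n_samples))


@pytest.fixture(scope="session")
def default_simulation():
    """One default-config simulated dataset shared across read-only tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_simulation():
    """A faster, smaller dataset for pipeline-shape tests."""
    cfg = SimulationConfig(
        n_genes=400,
        classes=(("pterygium", 6), ("healthy", 6), ("scc", 5)),
        n_validation=4, n_markers=15, n_background_de=10, seed=3,
    )
    return simulate_dataset(cfg)
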