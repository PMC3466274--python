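import numpy as np
import pytest

from dcgnet import (
    Atlas,
    CohortDesign,
    CorrelationMatrix,
    SimilarityMatrix,
    WalkParams,
    simulate_cohort,
)


def block_correlation(sizes, within=0.9, between=0.1, noise_sd=0.0, seed=0):
    """Exact block-structured correlation matrix (test helper, no repair)."""
    n = sum(sizes)
    values = np.full((n, n), float(between))
    start = 0
    for s in sizes:
        values[start : start + s, start : start + s] = within
        start += s
    if noise_sd:
        rng = np.random.default_rng(seed)
        e = rng.normal(0, noise_sd, (n, n))
        values += (e + e.T) / np.sqrt(2)
        values = np.clip(values, -1, 1)
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(values=values, roi_ids=tuple(range(1, n + 1)))


def perfect_block_similarity(sizes):
    """Similarity matrix with within-block 1 and cross-block 0."""
    n = sum(sizes)
    values = np.zeros((n, n))
    start = 0
    for s in sizes:
        values[start : start + s, start : start + s] = 1.0
        start += s
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values=values, temperature=1.0)


@pytest.fixture(scope="session")
def atlas():
    return Atlas.bundled()


@pytest.fixture(scope="session")
def small_design():
    """Reduced two-region design for fast end-to-end tests."""
    return CohortDesign(
        n_per_group=4,
        trials=("green",),
        region_counts={"Subcortical": 6, "Parietal": 6},
        noise_sd=0.02,
        seed=9,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design)


@pytest.fixture(scope="session")
def walk_params():
    return WalkParams(n_walks=50, seed=0)
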