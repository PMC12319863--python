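import numpy as np
import pytest

from bodyrep.cohort import CohortConfig, generate_pattern_set
from bodyrep.rsa import DissimilarityMatrix, compute_split_half_rdm


@pytest.fixture
def noiseless_config():
    """Strong three-cluster structure, no run noise: the ideal-geometry cohort."""
    return CohortConfig(
        n_per_group=2,
        n_voxels=30,
        category_separation=3.0,
        condition_separation=0.5,
        run_noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def clustered_rdm(noiseless_config) -> DissimilarityMatrix:
    return compute_split_half_rdm(generate_pattern_set(noiseless_config, 0))


def random_rdm(rng: np.random.Generator, n: int = 8) -> DissimilarityMatrix:
    """A random valid symmetric dissimilarity matrix with zero diagonal."""
    a = rng.uniform(0.0, 2.0, size=(n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    conditions = tuple(f"c{i}" for i in range(n))
    from bodyrep.conditions import BODY_PARTS

    if n == 8:
        conditions = BODY_PARTS
    return DissimilarityMatrix(values=d, conditions=conditions)
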