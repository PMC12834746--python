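import numpy as np
import pytest

from metconn.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """10-ROI, 15-per-group null cohort used across modules."""
    names = tuple(f"R{i}" for i in range(10))
    cfg = CohortConfig(
        n_per_group=15,
        n_rois=10,
        region_names=names,
        seed_roi="R0",
        mean_shift_delta=0.0,
        decorrelated_edges=(),
        rng_seed=99,
    )
    return generate_cohort(cfg)


def random_graph(rng, n, p=0.3):
    """Random symmetric 0/1 adjacency with zero diagonal."""
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return a | a.T
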