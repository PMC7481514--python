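import numpy as np
import pytest

from ryenue.synthetic import (
    HarvestModel,
    generate_design,
    phase_end_areas,
    sample_growth_truth,
    simulate_harvests,
)


@pytest.fixture(scope="session")
def small_design():
    """6 genotypes x 2 N levels x 3 replicates, rows of 6."""
    return generate_design(n_genotypes=6, n_replicates=3, row_capacity=6, seed=11)


@pytest.fixture(scope="session")
def full_design():
    """The default 76 x 2 x 4 trial (608 pots)."""
    return generate_design(seed=11)


@pytest.fixture(scope="session")
def full_truth():
    return sample_growth_truth(seed=11)


@pytest.fixture(scope="session")
def full_harvests(full_design, full_truth):
    ends = phase_end_areas(full_design, full_truth)
    return simulate_harvests(ends, full_truth, HarvestModel(), seed=12)


def random_mask(rng, shape=(14, 14), density=0.3):
    """Small random pixel blob for geometry oracle checks (never empty)."""
    m = rng.random(shape) < density
    if not m.any():
        m[shape[0] // 2, shape[1] // 2] = True
    return m
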