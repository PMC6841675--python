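import numpy as np
import pytest

from samquant.synthetic import (
    IntervalWorldSpec,
    SamSpec,
    generate_interval_world,
    generate_sam,
)


@pytest.fixture(scope="session")
def default_sam():
    """One synthetic meristem at default noise (seed 1)."""
    return generate_sam(SamSpec(seed=1))


@pytest.fixture(scope="session")
def noisefree_sam():
    """Synthetic meristem with intensity noise switched off."""
    return generate_sam(SamSpec(seed=1, noise_mult_sigma=0.0, noise_add_sigma=0.0))


@pytest.fixture(scope="session")
def interval_world():
    """Toy genome at defaults (seed 7)."""
    return generate_interval_world(IntervalWorldSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
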