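import numpy as np
import pytest

from cregatlas.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_config():
    """A compact study: 300 regions on one 3 Mb chromosome."""
    return SimulationConfig(
        n_regions=300, n_chroms=1, chrom_length=3_000_000, seed=11
    )
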