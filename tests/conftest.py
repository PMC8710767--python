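import numpy as np
import pytest

from localbrainage import ArchitectureSpec, build_network
from localbrainage.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free 32-grid cohort: exact generating model, fast to predict on."""
    cfg = PhantomConfig(grid_side=32, n_participants=6, noise_sd=0.0, seed=11)
    volumes, records, truth = generate_cohort(cfg)
    return cfg, volumes, records, truth


@pytest.fixture(scope="session")
def tiny_net():
    """Thin (base 2) network with the full layer structure."""
    return build_network(ArchitectureSpec(base_channels=2), seed=0, output_bias=50.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
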