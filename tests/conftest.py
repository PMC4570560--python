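import numpy as np
import pytest

from phosphosig.synthetic_data import (
    SyntheticConfig,
    default_design,
    generate_phosphoproteome,
)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic proteome shared by read-only tests."""
    cfg = SyntheticConfig(seed=7, n_proteins=300)
    records, truth = generate_phosphoproteome(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Effect-only proteome: negligible noise, no missingness."""
    cfg = SyntheticConfig(
        seed=11,
        n_proteins=400,
        noise_a=1e-9,
        noise_b=0.0,
        missing_rate=0.0,
    )
    records, truth = generate_phosphoproteome(cfg)
    return cfg, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
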