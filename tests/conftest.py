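import numpy as np
import pytest

from metatrack.cohort_sim import SimConfig, generate_cohort, generate_msi_phantom


@pytest.fixture(scope="session")
def small_cohort():
    """Compact planted-effect cohort shared by read-only tests."""
    cfg = SimConfig(
        n_tko=8,
        n_ctrl=8,
        n_features_per_class={"SM": 4, "Cer": 4, "LPC": 4, "sterol": 3, "polar": 3},
        n_noise_features=10,
        effect_scale=1.0,
        seed=42,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def phantom():
    ds, truth = generate_msi_phantom(width=20, height=20, n_features=30, seed=7)
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
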