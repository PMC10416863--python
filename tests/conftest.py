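import numpy as np
import pytest

from flockgrowth import GeneratorConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """A moderate synthetic dataset under the default generating conditions."""
    cfg = GeneratorConfig(n_flocks_per_group=40, seed=20260929)
    records, truth = simulate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Flocks lying exactly on their group growth curves (all noise off)."""
    cfg = GeneratorConfig(
        n_flocks_per_group=2, bw_cv=0.0, fcr35_sd=0.0, fcr_shape_cv=0.0,
        mort_weekly_mean=0.0, seed=7,
    )
    records, truth = simulate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
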