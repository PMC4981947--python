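import numpy as np
import pandas as pd
import pytest

from bloomkit.synthetic import GeneratorConfig, generate_lake, generate_multilake_dataset


@pytest.fixture(scope="session")
def small_lake():
    """One 40-week lake with defaults, plus its ground truth."""
    cfg = GeneratorConfig(n_weeks=40, n_lakes=1, seed=11)
    ts, truth = generate_lake(cfg)
    return cfg, ts, truth


@pytest.fixture(scope="session")
def noise_free_lake():
    """Noise-free dynamics: egg-ratio and death-rate jitter switched off."""
    cfg = GeneratorConfig(n_weeks=40, n_lakes=1, seed=19,
                          egg_noise_sd=0.0, d_noise_sd=0.0)
    ts, truth = generate_lake(cfg)
    return cfg, ts, truth


@pytest.fixture(scope="session")
def seven_lakes():
    """The seven-lake monitoring corpus at default settings."""
    cfg = GeneratorConfig(n_weeks=60, n_lakes=7, seed=5)
    ds, truth = generate_multilake_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def simple_egg_data():
    """Two weekly egg observations with large, low-noise counts."""
    return pd.DataFrame({
        "day": [0.0, 7.0],
        "eggs": [30_000.0, 36_000.0],
        "females": [100_000.0, 105_000.0],
        "temp_c": [25.0, 25.0],
    })
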