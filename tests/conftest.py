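import numpy as np
import pandas as pd
import pytest

from qcindex.synthetic import SyntheticConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """12-country, 8-year noisy world shared by read-only tests."""
    cfg = SyntheticConfig(n_countries=12, year_start=2000, year_end=2007,
                          seed=11)
    table, truth = generate_world(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def noise_free_world():
    """Noise-free world: every rate is an exact function of latent q."""
    cfg = SyntheticConfig(n_countries=10, year_start=2000, year_end=2004,
                          seed=5, noise_sigma=0.0)
    table, truth = generate_world(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_index_frame(rng, n, latent=None):
    """Random four-index table; optionally driven by a latent quality so
    that higher latent → better care (mir, ylr decreasing)."""
    if latent is None:
        return pd.DataFrame({
            "pir": rng.lognormal(1.0, 0.4, n),
            "mir": rng.uniform(0.1, 0.9, n),
            "dpr": rng.lognormal(0.5, 0.3, n),
            "ylr": rng.lognormal(0.8, 0.5, n),
        })
    noise = rng.normal(0, 0.02, (n, 4))
    return pd.DataFrame({
        "pir": 1 + 9 * latent + noise[:, 0],
        "mir": 0.9 - 0.8 * latent + noise[:, 1],
        "dpr": 2.0 - 1.0 * latent + noise[:, 2],
        "ylr": 5.0 - 4.5 * latent + noise[:, 3],
    })
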