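import numpy as np
import pandas as pd
import pytest

from mirpair import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signal cohort shared by read-only tests."""
    cfg = SyntheticConfig(
        n_healthy=50, n_sarcoma=60, n_genes=60, n_abundant=40,
        n_differential=8, effect_size=1.5, noise_sd=1.0,
        n_planted_pairs=4, flip_prob=0.95, missing_rate=0.03, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_expression():
    """A tiny deterministic genes-by-samples matrix, no missing values."""
    return pd.DataFrame(
        [[8.0, 9.5, 7.1], [9.0, 9.0, 6.0], [10.5, 8.2, 6.0], [7.7, 11.0, 12.0]],
        index=["mir-a", "mir-b", "mir-c", "mir-d"],
        columns=["s1", "s2", "s3"],
    )
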