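import numpy as np
import pytest

from gxesum import estimate_ld_scores, simulate_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """Shared 500 x 200 block-LD panel for fast unit tests."""
    return simulate_genotypes(
        n=500, m=200, ld_block_size=10, within_block_r=0.4, seed=42
    )


@pytest.fixture(scope="session")
def small_ldscores(small_panel):
    return estimate_ld_scores(small_panel, window=30, adjusted=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
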