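import numpy as np
import pytest

from ucevar import SyntheticConfig, simulate_dataset


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A scaled-down scenario for fast unit tests (same structure as defaults)."""
    base = dict(
        chrom_sizes={"chrS": 400_000},
        n_elements=40,
        element_length_range=(200, 400),
        element_min_gap=1000,
        n_rare=200,
        n_intermediate=200,
        n_prevalent=200,
        n_se_regions=8,
        se_length_range=(1000, 3000),
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
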