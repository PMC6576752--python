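import numpy as np
import pandas as pd
import pytest

from aeqtl.simulate import SimConfig, make_toy_fixture, simulate_cohort, toy_golden


@pytest.fixture(scope="session")
def toy():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def golden():
    return toy_golden()


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-sample, 2-gene cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_samples=80, n_genes=2, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def fraction_table(rng):
    """A seeded 40-sample fraction table with a real group effect."""
    g = rng.integers(0, 3, 40)
    y = 0.5 - 0.06 * g + rng.normal(0, 0.03, 40)
    return pd.DataFrame({
        "sample": [f"S{i:03d}" for i in range(40)],
        "group": g,
        "fraction_p1": y,
    })
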