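import numpy as np
import pandas as pd
import pytest

import laywise as lw


@pytest.fixture(scope="session")
def default_dataset():
    """One default-sized synthetic dataset (145 clutches, 5 years)."""
    eggs, temps, truth = lw.generate_dataset(lw.SyntheticConfig(seed=11))
    return eggs, temps, truth


@pytest.fixture(scope="session")
def default_frame(default_dataset):
    eggs, temps, _ = default_dataset
    return lw.build_model_frame(eggs, temps)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset (30 clutches) for fast model-fitting unit tests."""
    cfg = lw.SyntheticConfig(n_years=2, clutches_per_year=15, seed=5)
    eggs, temps, truth = lw.generate_dataset(cfg)
    return eggs, temps, truth


@pytest.fixture(scope="session")
def small_frame(small_dataset):
    eggs, temps, _ = small_dataset
    return lw.build_model_frame(eggs, temps)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
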