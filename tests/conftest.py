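import numpy as np
import pandas as pd
import pytest

import localadapt as la


@pytest.fixture(scope="session")
def small_truth():
    """A compact but fully-featured synthetic study shared across tests."""
    cfg = la.SimulationConfig(
        n_neutral_loci=800, n_clinal_loci=30, n_threshold_loci=20,
        n_families=192, n_effect_loci=5, seed=7)
    return la.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_freqs(small_truth):
    """Empirical locality frequencies from the small study's mother trees."""
    return la.dosages_to_freqs(small_truth.dosages, small_truth.membership)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def null_freqs(rng):
    """Locality frequencies with no spatial or climatic structure."""
    return pd.DataFrame(rng.uniform(0.2, 0.8, size=(64, 1500)),
                        index=[f"L{i:02d}" for i in range(64)])


@pytest.fixture()
def null_climate(rng):
    return pd.DataFrame(rng.normal(size=(64, 11)), columns=la.CLIMATE_VARS,
                        index=[f"L{i:02d}" for i in range(64)])
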