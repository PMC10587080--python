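import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Small neutral synthetic dataset shared by integration-ish tests."""
    import stomacomm as sc

    cfg = sc.SyntheticConfig(
        n_species=80,
        n_sites=10,
        plots_per_site=4,
        species_per_plot_mean=8,
        filtering_strength=0.0,
        seed=42,
    )
    return sc.generate_dataset(cfg)


@pytest.fixture
def tiny_community():
    """Hand-sized trait + composition tables for moment tests."""
    species_traits = pd.DataFrame(
        {
            "species_id": ["a", "b", "c", "d"],
            "site_id": ["s1"] * 4,
            "SD": [100.0, 200.0, 300.0, 150.0],
            "SL": [20.0, 25.0, 30.0, 22.0],
            "SPI": [4.0, 12.5, 27.0, 7.26],
        }
    )
    plots = pd.DataFrame(
        {
            "plot_id": ["p1"] * 3 + ["p2"],
            "site_id": ["s1"] * 4,
            "vegetation": ["forest"] * 4,
            "species_id": ["a", "b", "c", "d"],
            "weight": [2.0, 3.0, 5.0, 4.0],
        }
    )
    return species_traits, plots
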