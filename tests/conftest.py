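import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_colony() -> pd.DataFrame:
    """Deterministic 20-box colony on a 400 m square."""
    rng = np.random.default_rng(11)
    return pd.DataFrame({
        "box_id": [f"B{i:02d}" for i in range(20)],
        "x": rng.uniform(0, 400, 20),
        "y": rng.uniform(0, 400, 20),
    })


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated colony shared by processing-level tests."""
    from nestprospect.simulate import SimConfig, generate_dataset

    cfg = SimConfig(n_boxes=40, area_ha=12, n_years=2, n_floaters_per_year=15,
                    prospect_kernel_sd=70.0, distance_decay=60.0, seed=7)
    ds, truth = generate_dataset(cfg)
    return cfg, ds, truth
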