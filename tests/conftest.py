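import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_particles(
    n_prey=6,
    n_predator=4,
    sample_id="S01",
    station_id="ST001",
    cruise_id="CR01",
    n_carnivores=0,
    seed=0,
) -> pd.DataFrame:
    """Small hand-checkable particle table (axes in um, weights ind. m^-3)."""
    r = np.random.default_rng(seed)
    rows = []
    for i in range(n_prey):
        minor = r.uniform(5, 20)
        rows.append(("prey", False, minor * r.uniform(1.0, 1.5), minor))
    for i in range(n_predator):
        minor = r.uniform(100, 400)
        rows.append(("predator", i < n_carnivores, minor * r.uniform(2, 6), minor))
    df = pd.DataFrame(rows, columns=["group", "is_carnivore", "major_um", "minor_um"])
    df.insert(0, "cruise_id", cruise_id)
    df.insert(0, "station_id", station_id)
    df.insert(0, "sample_id", sample_id)
    df["weight_per_m3"] = r.integers(1, 6, size=len(df)).astype(float)
    return df


@pytest.fixture
def particles():
    return make_particles()
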