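import pytest

from cerealcast.preprocessing import standardize_monthly_anomalies
from cerealcast.synthetic import (
    SyntheticConfig,
    generate_ensemble_hindcasts,
    generate_monthly_climate,
    generate_yield_records,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Compact but complete study system: one region per climate regime,
    shortened record, thin ensemble."""
    return SyntheticConfig(
        seed=7,
        start_year=2000,
        end_year=2015,
        regions={"region1": 2, "region2": 2},
        ensemble_size=5,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Climate + anomalies, hindcasts and yield records for the small system."""
    climate = generate_monthly_climate(small_config)
    return {
        "config": small_config,
        "climate": climate,
        "climate_anoms": standardize_monthly_anomalies(climate),
        "hindcasts": generate_ensemble_hindcasts(climate, small_config),
        "yields": generate_yield_records(climate, small_config),
    }
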