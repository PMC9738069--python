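import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import gutqs


@pytest.fixture
def small_config():
    """Two-phenotype cohort small enough for per-test simulation."""
    return gutqs.SimConfig(
        seed=11,
        n_samples_per_group={"non-IBD": 15, "CD": 15},
        dysbiosis_fraction={"non-IBD": 0.0, "CD": 1.0},
        n_species=60,
        reads_mean=100_000,
        marker_spec=(
            gutqs.MarkerSpec("Species_0010", 10.0, "dysbiosis-depleted"),
            gutqs.MarkerSpec("Species_0015", 12.0, "dysbiosis-depleted"),
            gutqs.MarkerSpec("Species_0020", 15.0, "dysbiosis-depleted"),
            gutqs.MarkerSpec("Species_0025", 9.1, "dysbiosis-enriched"),
        ),
        marker_shares=(0.0045, 0.0028, 0.0016, 0.0010),
    )


@pytest.fixture
def null_config():
    """No planted effects: dysbiotic and healthy samples exchangeable."""
    return gutqs.SimConfig(
        seed=23,
        n_samples_per_group={"non-IBD": 10, "CD": 10},
        dysbiosis_fraction={"non-IBD": 0.5, "CD": 0.5},
        n_species=40,
        reads_mean=60_000,
        marker_spec=(),
        marker_shares=(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
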