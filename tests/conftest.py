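import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale cross: 3 chromosomes, ~600 markers."""
    from pyroqtl.synthetic_cross import GenomeSpec

    return GenomeSpec(n_markers=600, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """One simulated study small enough for unit tests (8-sector bulks)."""
    from pyroqtl.synthetic_cross import simulate_dataset

    return simulate_dataset(
        small_spec, n_tetrads=60, bulk_sizes={"RT8": 8, "WT8": 8}, mean_depth=60.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
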