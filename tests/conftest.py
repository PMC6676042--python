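import numpy as np
import pytest

from lesiongrad import CohortSpec, make_latent_layout, simulate_cohort


@pytest.fixture(scope="session")
def small_layout():
    """Full-mask 8x8x6 layout with one smooth latent gradient."""
    return make_latent_layout((8, 8, 6), G=1, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny patient cohort reused by pipeline-level tests."""
    spec = CohortSpec(n_controls=6, n_patients=6, n_timepoints=60)
    return simulate_cohort(spec, seed=5, grid_dims=(8, 8, 6), G=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
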