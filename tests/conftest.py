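import pytest

from adsev import (CohortSpec, default_acquisition, default_grid,
                   default_phantom_spec, generate_cohort, generate_phantom)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default geometry, no signal noise: every recovery should be near-exact."""
    return generate_phantom(default_phantom_spec(), default_acquisition(0.0),
                            default_grid(), seed=1)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default geometry with 2% signal noise and partial-volume arteries."""
    return generate_phantom(default_phantom_spec(), default_acquisition(2.0),
                            default_grid(), seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def null_cohort():
    """Zero effects everywhere: features, ages and cognition carry no signal."""
    return generate_cohort(CohortSpec(
        n_per_group=(50, 50, 50, 50), disease_effects=(0.0, 0.0, 0.0, 0.0),
        beta_age=0.0, cog_effects=(0.0, 0.0), seed=0))
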