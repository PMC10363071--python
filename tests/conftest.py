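import numpy as np
import pytest

from synthce.phantom import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four 32^3 phantom subjects with default noise/variability."""
    return generate_cohort(PhantomSpec(grid_size=32, n_subjects=4, seed=42))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Two subjects with no acquisition noise and no uplift variability, so
    enhancement is exactly the configured mean."""
    spec = PhantomSpec(grid_size=32, n_subjects=2, seed=7, noise_sd_hu=0.0)
    spec = PhantomSpec(grid_size=32, n_subjects=2, seed=7, noise_sd_hu=0.0,
                       uplift_sd={k: 0.0 for k in spec.uplift_mean})
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
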