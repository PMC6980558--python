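import numpy as np
import pytest

from striascope import CohortParams, PhantomSpec, StriatumParams, generate_phantom

#: smaller grid used in tests where full PPMI-scale volumes would be slow;
#: the geometry still fits with the same mm-based defaults
SMALL_GRID = (64, 80, 64)


@pytest.fixture(scope="session")
def nc_phantom_clean():
    """Noise-free NC phantom (comma morphology) with the default blur."""
    return generate_phantom(PhantomSpec(
        group="NC", grid_shape=SMALL_GRID, noise_scale=0.0, seed=0,
    ))


@pytest.fixture(scope="session")
def pd_phantom_clean():
    """Noise-free PD phantom (putaminal loss) with the default blur."""
    return generate_phantom(PhantomSpec(
        group="PD", grid_shape=SMALL_GRID,
        striatum_params=StriatumParams(putamen_intensity_fraction=0.25),
        uptake_contrast=2.4, noise_scale=0.0, seed=0,
    ))


@pytest.fixture()
def flat_spec():
    """Blur-free, noise-free spec: intensities are exact by construction."""
    return PhantomSpec(
        grid_shape=SMALL_GRID, uptake_contrast=3.0, occipital_level=1.0,
        fwhm_mm=0.0, noise_scale=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort_params():
    return CohortParams(grid_shape=SMALL_GRID)
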