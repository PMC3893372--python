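import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def annulus_field():
    """Solved potential on the 40/70 px annulus phantom (10 um/px)."""
    from fcdmap.ribbon import rasterize_ribbon, solve_laplace
    from fcdmap.synthetic import make_annulus_phantom

    ph = make_annulus_phantom(40.0, 70.0, 720, pixel_size=10.0)
    grid = rasterize_ribbon(ph.contour_pair)
    return ph, grid, solve_laplace(grid)


@pytest.fixture(scope="session")
def annulus_profile(annulus_field):
    from fcdmap.ribbon import midline_profile

    _, _, fld = annulus_field
    return midline_profile(fld, sample_step=20.0)


@pytest.fixture(scope="session")
def band_field():
    """Parallel-band ribbon, width 20 px at 10 um/px."""
    from fcdmap.ribbon import rasterize_ribbon, solve_laplace
    from fcdmap.synthetic import make_gyral_ribbon

    n = 200
    cl = np.column_stack([np.arange(n, dtype=float) + 5, np.full(n, 40.0)])
    ph = make_gyral_ribbon(cl, np.full(n, 20.0), pixel_size=10.0)
    grid = rasterize_ribbon(ph.contour_pair)
    return ph, grid, solve_laplace(grid)


@pytest.fixture(scope="session")
def boolean_field_small():
    """One modest Boolean realization plus its truth (600 px window)."""
    from fcdmap.synthetic import DiskGrainSpec, simulate_boolean_field

    img, truth = simulate_boolean_field(
        0.003, DiskGrainSpec(6.0), (600, 600), noise_sd=10.0, seed=7
    )
    return img, truth
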