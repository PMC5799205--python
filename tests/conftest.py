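import numpy as np
import pytest
from hypothesis import settings

import wellcount as wc

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def default_geometry() -> wc.ArrayGeometry:
    """The reference device: 36 panels of 30x30 wells, 20 um x 25 um,
    imaged at 1 um per pixel."""
    return wc.ArrayGeometry()


@pytest.fixture(scope="session")
def fast_geometry() -> wc.ArrayGeometry:
    """Same device imaged at 2 um per pixel — the reduced resolution used
    for Monte-Carlo-heavy tests (well radius 5 px, panel 600x600 px)."""
    return wc.ArrayGeometry(pixel_scale_um_per_px=2.0)


@pytest.fixture(scope="session")
def clean_panel(default_geometry):
    """A noise-free bright-field panel with known occupancy."""
    g = default_geometry
    truth = wc.seed_particles(g, 0.7 / g.well_volume_ul, rng_seed=11)
    img = wc.render_panel(
        g, truth, noise=wc.NoiseSpec(additive_sigma=0.0, illumination_gradient=0.0,
                                     rng_seed=12)
    )
    return truth, img


@pytest.fixture(scope="session")
def noisy_panel(default_geometry):
    """A bright-field panel under the generator's default noise model."""
    g = default_geometry
    truth = wc.seed_particles(g, 0.7 / g.well_volume_ul, rng_seed=21)
    img = wc.render_panel(g, truth, noise=wc.NoiseSpec(rng_seed=22))
    return truth, img


@pytest.fixture(scope="session")
def fitted_grid(default_geometry, noisy_panel):
    truth, img = noisy_panel
    smooth = wc.denoise(img)
    circles = wc.find_wells(smooth, default_geometry)
    return wc.fit_grid(circles, default_geometry), smooth


def exact_lattice_circles(geometry: wc.ArrayGeometry, drop: int = 0, seed: int = 0):
    """Detected-circle list lying exactly on the ground-truth lattice."""
    from wellcount.synthetic import well_center_px

    circles = []
    for r in range(geometry.rows):
        for c in range(geometry.cols):
            x, y = well_center_px(geometry, r, c)
            circles.append(wc.DetectedCircle(x, y, geometry.well_radius_px))
    if drop:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(circles), size=len(circles) - drop, replace=False)
        circles = [circles[i] for i in sorted(idx)]
    return circles
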