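import math

import numpy as np
import pytest
from scipy import stats

import wellcount as wc
from wellcount.synthetic import panel_shape_px, well_center_px


class TestSeedParticles:
    def test_zero_density_empty(self, default_geometry):
        truth = wc.seed_particles(default_geometry, 0.0, rng_seed=1)
        assert truth.particles.sum() == 0
        assert truth.n_occupied == 0

    def test_negative_density_rejected(self, default_geometry):
        with pytest.raises(wc.DomainError):
            wc.seed_particles(default_geometry, -1.0)

    def test_same_seed_bit_identical(self, default_geometry):
        a = wc.seed_particles(default_geometry, 5e4, aggregation=0.3, rng_seed=9)
        b = wc.seed_particles(default_geometry, 5e4, aggregation=0.3, rng_seed=9)
        assert np.array_equal(a.particles, b.particles)
        assert a.missing_wells == b.missing_wells

    def test_half_occupancy_at_lambda_ln2(self):
        # lambda = ln 2 makes p = 1 - e^-lambda = 0.5 exactly; over a whole
        # device (14,400 wells) the occupied fraction stays within 3 sigma
        # of the binomial expectation
        g = wc.ArrayGeometry(rows=120, cols=120, panels=1)
        density = math.log(2) / g.well_volume_ul
        truth = wc.seed_particles(g, density, rng_seed=5)
        frac = truth.n_occupied / g.wells_per_panel
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / g.wells_per_panel)

    @pytest.mark.parametrize("lam", [0.1, 0.7, 2.0])
    def test_counts_are_poisson_without_aggregation(self, lam):
        # chi-square goodness of fit at the 1% level on 14,400 wells
        g = wc.ArrayGeometry(rows=120, cols=120, panels=1)
        truth = wc.seed_particles(g, lam / g.well_volume_ul, rng_seed=int(lam * 10))
        counts = np.bincount(truth.particles.ravel())
        kmax = len(counts) - 1
        expected = stats.poisson.pmf(np.arange(kmax + 1), lam) * g.wells_per_panel
        # pool the tail so every expected cell count is >= 5
        while len(expected) > 2 and expected[-1] < 5:
            expected[-2] += expected[-1]
            counts[-2] += counts[-1]
            expected, counts = expected[:-1], counts[:-1]
        expected = expected * counts.sum() / expected.sum()
        _, p = stats.chisquare(counts, expected)
        assert p > 0.01

    def test_aggregation_depresses_occupancy(self, default_geometry):
        # one-sided comparison against the Poisson closed form over 20 seeds
        g = default_geometry
        lam = 3.0
        density = lam / g.well_volume_ul
        p_poisson = 1 - math.exp(-lam)
        fracs = [
            wc.seed_particles(g, density, aggregation=0.9, rng_seed=s).n_occupied
            / g.wells_per_panel
            for s in range(20)
        ]
        assert all(f < p_poisson for f in fracs)

    def test_aggregation_preserves_mean_particle_count(self):
        # clumping changes occupancy, not the expected number of particles
        g = wc.ArrayGeometry(rows=120, cols=120, panels=1)
        lam = 2.0
        means = [
            wc.seed_particles(g, lam / g.well_volume_ul, aggregation=0.8,
                              rng_seed=s).particles.mean()
            for s in range(10)
        ]
        assert np.mean(means) == pytest.approx(lam, rel=0.05)

    def test_missing_wells_hold_no_particles(self, default_geometry):
        truth = wc.seed_particles(
            default_geometry, 1e5, rng_seed=3, missing_wells=60
        )
        assert len(truth.missing_wells) == 60
        assert len(truth.centers) == 840
        for r, c in truth.missing_wells:
            assert truth.particles[r, c] == 0


class TestRenderPanel:
    def test_frame_holds_full_grid(self, default_geometry, clean_panel):
        _, img = clean_panel
        h, w = img.shape
        g = default_geometry
        assert h >= g.pitch_px * g.rows and w >= g.pitch_px * g.cols
        assert img.pixels.min() >= 0 and img.pixels.max() <= 1

    def test_same_seed_bit_identical(self, default_geometry):
        g = default_geometry
        truth = wc.seed_particles(g, 5e4, rng_seed=4)
        a = wc.render_panel(g, truth, noise=wc.NoiseSpec(rng_seed=8))
        b = wc.render_panel(g, truth, noise=wc.NoiseSpec(rng_seed=8))
        assert np.array_equal(a.pixels, b.pixels)

    def test_unoccupied_wells_identical_without_noise(self, default_geometry):
        g = default_geometry
        truth = wc.seed_particles(g, 0.0, rng_seed=1)
        img = wc.render_panel(
            g, truth, noise=wc.NoiseSpec(0.0, 0.0, 1)
        )
        means = []
        rad = int(g.well_radius_px * 0.7)
        for r in range(0, g.rows, 7):
            for c in range(0, g.cols, 7):
                x, y = (int(v) for v in well_center_px(g, r, c))
                means.append(img.pixels[y - rad : y + rad, x - rad : x + rad].mean())
        assert np.ptp(means) < 1e-12

    def test_modality_polarity(self, default_geometry):
        # occupied wells darken the interior in bright-field and brighten
        # it in fluorescence
        g = default_geometry
        truth = wc.seed_particles(g, 0.7 / g.well_volume_ul, rng_seed=6)
        occ = next(zip(*np.where(truth.occupied)))
        emp = next(zip(*np.where(~truth.occupied & ~np.array(
            [[(r, c) in truth.missing_wells for c in range(g.cols)]
             for r in range(g.rows)]))))

        def interior_mean(img, rc):
            x, y = (int(v) for v in well_center_px(g, *rc))
            rad = int(g.well_radius_px * 0.6)
            return img.pixels[y - rad : y + rad, x - rad : x + rad].mean()

        bf = wc.render_panel(g, truth, "brightfield", wc.NoiseSpec(0, 0, 1))
        fl = wc.render_panel(g, truth, "fluorescence", wc.NoiseSpec(0, 0, 1))
        assert interior_mean(bf, occ) < interior_mean(bf, emp)
        assert interior_mean(fl, occ) > interior_mean(fl, emp)

    def test_contrast_resolvable_over_noise(self, default_geometry):
        # occupied/unoccupied interior separation must exceed 5x the noise
        # sigma so the intensity histogram stays bimodal
        g = default_geometry
        noise = wc.NoiseSpec()
        truth = wc.seed_particles(g, 0.7 / g.well_volume_ul, rng_seed=13)
        img = wc.render_panel(g, truth, noise=wc.NoiseSpec(0.0, 0.0, 2))
        rad = int(g.well_radius_px * 0.6)
        occ_means, emp_means = [], []
        for r in range(g.rows):
            for c in range(g.cols):
                x, y = (int(v) for v in well_center_px(g, r, c))
                m = img.pixels[y - rad : y + rad, x - rad : x + rad].mean()
                (occ_means if truth.occupied[r, c] else emp_means).append(m)
        separation = min(emp_means) - max(occ_means)
        assert separation >= 5 * noise.additive_sigma

    def test_geometry_mismatch_rejected(self, default_geometry):
        other = wc.ArrayGeometry(rows=10, cols=10)
        truth = wc.seed_particles(other, 0.0, rng_seed=1)
        with pytest.raises(wc.ConsistencyError):
            wc.render_panel(default_geometry, truth)

    def test_missing_wells_not_rendered(self, default_geometry):
        g = default_geometry
        truth = wc.seed_particles(g, 0.0, rng_seed=2, missing_wells={(4, 5)})
        img = wc.render_panel(g, truth, noise=wc.NoiseSpec(0, 0, 1))
        x, y = (int(v) for v in well_center_px(g, 4, 5))
        rad = int(g.well_radius_px + 2)
        patch = img.pixels[y - rad : y + rad, x - rad : x + rad]
        assert np.ptp(patch) < 1e-12  # pure background, no rim

    def test_noise_spec_validation(self):
        with pytest.raises(wc.DomainError):
            wc.NoiseSpec(additive_sigma=-0.1)
        with pytest.raises(wc.DomainError):
            wc.NoiseSpec(illumination_gradient=0.9)


class TestImageIO:
    @pytest.mark.parametrize("fmt", ["png", "tif"])
    def test_round_trip(self, tmp_path, fmt):
        g = wc.ArrayGeometry(rows=5, cols=5, pitch_um=40)
        truth = wc.seed_particles(g, 0.5 / g.well_volume_ul, rng_seed=3)
        img = wc.render_panel(g, truth, noise=wc.NoiseSpec(rng_seed=4))
        path = tmp_path / f"panel.{fmt}"
        wc.save_image(img, path)
        back = wc.load_image(path, "brightfield", g.pixel_scale_um_per_px)
        tol = 1 / 255 if fmt == "png" else 1 / 65535
        assert back.shape == img.shape
        assert np.abs(back.pixels - img.pixels).max() <= tol

    def test_ground_truth_csv(self, tmp_path, default_geometry):
        g = default_geometry
        truths = {0: wc.seed_particles(g, 5e4, rng_seed=1)}
        wc.save_ground_truth(truths, tmp_path / "gt.csv", tmp_path / "gt.json")
        import pandas as pd

        df = pd.read_csv(tmp_path / "gt.csv")
        assert len(df) == g.wells_per_panel
        assert df["occupied"].sum() == truths[0].n_occupied
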