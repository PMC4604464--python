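"""Rendering, z-sectioning, line profiles, label density, Nyquist and FRC."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_table
from cryopalm.geometry import circle_polyline
from cryopalm.metrics import (frc_from_images, frc_resolution, label_density,
                              nyquist_resolution)
from cryopalm.rendering import (fit_gaussian_histogram, line_profile, render,
                                split_z_sections, z_extent)
from cryopalm.synthetic import simulate_multiring_scene


class TestSplitZSections:
    def test_uniform_z_eight_sections_of_30nm(self, rng):
        tbl = make_table(rng.uniform(0, 100, 1000), 0.0,
                         z=rng.uniform(-120, 120, 1000))
        tbl.loc[tbl.index[:2], "z_nm"] = [-120.0, 120.0]  # pin the span
        parts, edges = split_z_sections(tbl, 8)
        assert len(parts) == 8
        assert np.allclose(np.diff(edges), 30.0)

    def test_single_section_is_identity(self, rng):
        tbl = make_table(rng.uniform(0, 100, 50), 0.0, z=rng.uniform(-50, 50, 50))
        parts, _ = split_z_sections(tbl, 1)
        assert len(parts) == 1 and len(parts[0]) == 50

    def test_counts_conserved(self, rng):
        tbl = make_table(rng.uniform(0, 100, 100), 0.0, z=rng.normal(0, 40, 100))
        parts, _ = split_z_sections(tbl, 7)
        assert sum(len(p) for p in parts) == 100


class TestRender:
    def test_single_molecule_unit_mass(self):
        img = render(make_table([100.0], 100.0, precision=10.0), pixel_nm=2.0)
        assert img.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_mass_equals_molecule_count(self, rng):
        tbl = make_table(rng.uniform(0, 500, 57), rng.uniform(0, 500, 57),
                         precision=rng.uniform(5, 20, 57))
        img = render(tbl, pixel_nm=5.0)
        assert img.data.sum() == pytest.approx(57.0, rel=1e-6)

    def test_rendered_fwhm_tracks_precision(self):
        """A 10 nm precision molecule renders with FWHM 23.5 nm."""
        img = render(make_table([100.0], 100.0, precision=10.0), pixel_nm=2.0,
                     bounds_nm=(0.0, 200.0, 0.0, 200.0))
        _, _, fit = line_profile(img, (60.0, 100.0), (140.0, 100.0), width_nm=8.0)
        assert fit.fwhm == pytest.approx(23.5, abs=1.5)

    def test_empty_table_renders_zero_image(self):
        tbl = make_table(np.array([]), np.array([]))
        img = render(tbl, pixel_nm=5.0, bounds_nm=(0, 100, 0, 100))
        assert img.data.sum() == 0.0


class TestLineProfile:
    def test_line_of_molecules_with_13nm_spread(self, rng):
        """Molecules scattered sigma = 13 nm across a line profile back at
        sigma ~ 13 nm (small rendering blur adds in quadrature)."""
        n = 4000
        tbl = make_table(500.0 + rng.normal(0, 13.0, n), rng.uniform(0, 2000, n),
                         precision=3.0)
        img = render(tbl, pixel_nm=2.0, bounds_nm=(400.0, 600.0, 0.0, 2000.0))
        _, _, fit = line_profile(img, (430.0, 1000.0), (570.0, 1000.0),
                                 width_nm=1500.0)
        expected = np.hypot(13.0, 3.0)
        assert fit.sigma == pytest.approx(expected, abs=1.5)

    def test_delta_source_profile_equals_render_kernel(self):
        img = render(make_table([100.0], 100.0, precision=10.0), pixel_nm=2.0,
                     bounds_nm=(0.0, 200.0, 0.0, 200.0))
        _, _, fit = line_profile(img, (60.0, 100.0), (140.0, 100.0), width_nm=8.0)
        assert fit.sigma == pytest.approx(10.0, abs=0.5)

    def test_flat_image_flagged_degenerate(self):
        tbl = make_table(np.array([]), np.array([]))
        img = render(tbl, pixel_nm=2.0, bounds_nm=(0, 100, 0, 100))
        _, _, fit = line_profile(img, (20.0, 50.0), (80.0, 50.0))
        assert fit.degenerate

    def test_segment_outside_image_rejected(self):
        img = render(make_table([100.0], 100.0), pixel_nm=2.0)
        with pytest.raises(ValueError):
            line_profile(img, (-500.0, 0.0), (500.0, 0.0))


class TestLabelDensity:
    def test_counts_over_mask_area(self, rng):
        # 100 molecules inside a 1 um^2 mask region
        tbl = make_table(rng.uniform(0, 1000, 100), rng.uniform(0, 1000, 100))
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True            # 10x10 px of 100 nm = 1 um^2
        out = label_density(tbl, mask, pixel_nm=100.0)
        assert out["mean_per_um2"] == pytest.approx(100.0)

    def test_mean_median_arithmetic(self, rng):
        """Region densities {100, 700, 4750} per um^2 summarize to mean 1850
        and median 700."""
        curves, xs = [], []
        for i, dens in enumerate([100, 700, 4750]):
            c = circle_polyline((i * 5000.0, 0.0), 318.3)  # length ~2 um
            area = c.length * 50.0 * 1e-6
            n = int(round(dens * area))
            dense = c.resample(2.0)
            pts = dense[rng.integers(0, len(dense), n)]
            xs.append(pts)
            curves.append(c)
        pts = np.vstack(xs)
        tbl = make_table(pts[:, 0], pts[:, 1])
        out = label_density(tbl, curves, band_width_nm=50.0)
        assert out["mean_per_um2"] == pytest.approx(1850.0, rel=0.02)
        assert out["median_per_um2"] == pytest.approx(700.0, rel=0.02)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            label_density(make_table([0.0], 0.0), np.zeros((4, 4), dtype=bool),
                          pixel_nm=100.0)


class TestNyquist:
    @pytest.mark.parametrize("density,expected", [
        (1850.0, 46.5), (744.0, 73.3), (4.0, 1000.0)])
    def test_known_values(self, density, expected):
        assert nyquist_resolution(density) == pytest.approx(expected, abs=0.05)

    def test_rejects_nonpositive_density(self):
        with pytest.raises(ValueError):
            nyquist_resolution(0.0)

    @settings(max_examples=30, deadline=None)
    @given(rho=st.floats(1.0, 1e5))
    def test_halving_density_scales_by_sqrt2(self, rho):
        assert nyquist_resolution(rho / 2) == pytest.approx(
            np.sqrt(2) * nyquist_resolution(rho), rel=1e-9)

    def test_strictly_decreasing_in_density(self):
        r = nyquist_resolution(np.array([10.0, 100.0, 1000.0, 10000.0]))
        assert np.all(np.diff(r) < 0)


class TestFRC:
    def test_identical_halves_never_cross_threshold(self, rng):
        img = rng.poisson(5, (128, 128)).astype(float)
        res = frc_from_images(img, img, pixel_nm=5.0)
        assert not res.resolved
        assert np.all(res.correlation > 0.9)

    def test_independent_noise_not_resolved(self, rng):
        a = rng.poisson(2, (128, 128)).astype(float)
        b = rng.poisson(2, (128, 128)).astype(float)
        res = frc_from_images(a, b, pixel_nm=5.0)
        assert not res.resolved

    def test_needs_enough_molecules(self):
        with pytest.raises(ValueError):
            frc_resolution(make_table(np.zeros(50), 0.0), seed=0)

    def test_resolution_improves_with_density(self):
        """FRC resolution decreases monotonically over increasing label
        density (fixed structure, fixed seed)."""
        res = []
        for dens in [100.0, 400.0, 1600.0]:
            tbl, _, _ = simulate_multiring_scene(n_rings=16, field_nm=6000.0,
                                                 density_per_um2=dens, seed=4)
            res.append(frc_resolution(tbl, pixel_nm=5.0, seed=4).resolution_nm)
        assert res[0] > res[1] > res[2]


class TestZExtent:
    def test_gaussian_z_fwhm(self, rng):
        tbl = make_table(np.zeros(10000), 0.0, z=rng.normal(0, 101.9, 10000))
        fit = z_extent(tbl)
        assert fit.fwhm == pytest.approx(240.0, abs=5.0)

    def test_constant_z_degenerate(self):
        tbl = make_table(np.zeros(100), 0.0, z=np.full(100, 10.0))
        fit = z_extent(tbl)
        assert fit.degenerate

    def test_boxcar_z_fit_with_quality_warning(self, rng):
        """A uniform 200 nm slab fitted by a Gaussian: the least-squares
        optimum has FWHM ~ 172 nm (continuum oracle) and a poor R^2 that
        flags the non-Gaussian shape."""
        tbl = make_table(np.zeros(10000), 0.0, z=rng.uniform(-100, 100, 10000))
        fit = z_extent(tbl)
        assert 150.0 <= fit.fwhm <= 200.0
        assert fit.r_squared < 0.95
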