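"""Unit tests of the three polarity engines on analytic profiles and on the
standard simulated cell."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import polaritykit as pk
from polaritykit.pca import _eigen_split

from conftest import dense_profile


class TestFourier:
    def test_uniform_profile_is_unpolarized(self):
        prof = dense_profile(lambda th: np.full_like(th, 3.0))
        r = pk.fourier_polarity(prof)
        assert r.magnitude == pytest.approx(0.0, abs=1e-12)
        assert r.angle_deg is None

    def test_pure_second_harmonic(self):
        prof = dense_profile(lambda th: 1.0 + np.cos(2 * th))
        r = pk.fourier_polarity(prof)
        assert r.magnitude == pytest.approx(0.5, abs=1e-6)
        assert r.angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_phase_shift_moves_angle_only(self):
        shift = np.radians(30.0)
        prof = dense_profile(lambda th: 1.0 + np.cos(2 * (th - shift)))
        r = pk.fourier_polarity(prof)
        assert r.magnitude == pytest.approx(0.5, abs=1e-6)
        assert r.angle_deg == pytest.approx(30.0, abs=1e-6)

    def test_brightness_invariance(self):
        prof = dense_profile(lambda th: 2.0 + np.cos(2 * th))
        r1 = pk.fourier_polarity(prof)
        r2 = pk.fourier_polarity(prof.with_intensities(prof.intensities * 37.5))
        assert r2.magnitude == pytest.approx(r1.magnitude, rel=1e-12)
        assert r2.angle_deg == pytest.approx(r1.angle_deg, abs=1e-12)

    def test_all_zero_signal_is_degenerate(self):
        prof = dense_profile(lambda th: np.zeros_like(th))
        with pytest.raises(pk.DegenerateSignalError):
            pk.fourier_polarity(prof)


class TestRatio:
    def test_uniform_profile_has_unit_asymmetry(self):
        prof = dense_profile(lambda th: np.full_like(th, 5.0))
        r = pk.ratio_polarity(prof)
        assert r.magnitude == pytest.approx(1.0)
        assert r.angle_deg is None

    def test_quadrant_aligned_two_level_matches_pair_ratio(self):
        # peak exactly filling the horizontal quadrant pair
        def f(th):
            d = np.degrees(np.abs(np.angle(np.exp(1j * th))))
            return np.where((d < 45) | (d > 135), 255.0, 40.0)
        r = pk.ratio_polarity(dense_profile(f))
        assert r.magnitude == pytest.approx(255.0 / 40.0, rel=0.02)
        assert abs(r.angle_deg) < 1.0

    def test_axis_maps_to_vertical_pattern(self):
        def f(th):
            d = np.degrees(np.abs(np.angle(np.exp(1j * th))))
            return np.where((d > 45) & (d < 135), 255.0, 40.0)
        r = pk.ratio_polarity(dense_profile(f))
        assert pk.axial_difference_deg(r.angle_deg, 90.0) < 1.0

    def test_brightness_invariance(self):
        def f(th):
            return np.where(np.cos(2 * th) > 0.3, 200.0, 50.0)
        prof = dense_profile(f)
        r1 = pk.ratio_polarity(prof)
        r2 = pk.ratio_polarity(prof.with_intensities(prof.intensities * 12.0))
        assert r2.magnitude == pytest.approx(r1.magnitude, abs=1e-12)

    def test_asymmetries_rounded_to_milli(self):
        scan = pk.ratio_scan(dense_profile(lambda th: 10 + np.cos(2 * th) ** 2))
        assert np.allclose(scan.asymmetries, np.round(scan.asymmetries, 3))

    def test_scan_covers_a_quarter_turn(self):
        scan = pk.ratio_scan(dense_profile(lambda th: 1 + th * 0), angle_step=5.0)
        assert len(scan.axes_deg) == 18


class TestPcaPieces:
    def test_compress_circle_is_identity(self):
        prof = dense_profile(lambda th: np.ones_like(th), n=200, radius=10.0)
        fit = pk.fit_ellipse(prof.xy)
        out = pk.compress_cell(prof, fit=fit)
        np.testing.assert_allclose(np.sort(out.xy[:, 0]),
                                   np.sort(prof.xy[:, 0]), atol=1e-6)

    def test_compress_ellipse_circularizes(self):
        fit0 = pk.EllipseFit(a=20.0, b=10.0, theta_deg=35.0, center=(0, 0))
        xy = fit0.sample(300)
        prof = pk.BoundaryProfile.from_points(xy, np.ones(300))
        out = pk.compress_cell(prof, fit=pk.fit_ellipse(xy))
        refit = pk.fit_ellipse(out.xy)
        assert refit.eccentricity < 0.05

    def test_invalid_alpha_rejected(self):
        prof = dense_profile(lambda th: np.ones_like(th), n=50)
        fit = pk.EllipseFit(a=10.0, b=5.0, theta_deg=0.0, center=(0, 0))
        with pytest.raises(ValueError):
            pk.compress_cell(prof, fit=fit, alpha=1.5)

    def test_normalize_constant_profile_maps_to_k(self):
        prof = dense_profile(lambda th: np.full_like(th, 7.0))
        out = pk.normalize_intensities(prof, k=1e3)
        np.testing.assert_allclose(out.intensities, 1e3)

    def test_normalize_scale_invariance(self):
        prof = dense_profile(lambda th: 5 + np.cos(2 * th))
        a = pk.normalize_intensities(prof).intensities
        b = pk.normalize_intensities(prof.with_intensities(prof.intensities * 10)).intensities
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_normalize_zero_signal_degenerate(self):
        prof = dense_profile(lambda th: np.zeros_like(th))
        with pytest.raises(pk.DegenerateSignalError):
            pk.normalize_intensities(prof)

    def test_intensity_coords_cardinal_points(self):
        xy = np.c_[[1.0, 0.0, -1.0, 0.0], [0.0, 1.0, 0.0, -1.0]]
        prof = pk.BoundaryProfile.from_points(xy, [5.0, 5.0, 5.0, 5.0])
        pts = pk.intensity_coords(prof, embedding="linear")
        for p in ([5, 0], [0, 5], [-5, 0], [0, -5]):
            assert np.min(np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1])) < 1e-9

    def test_weighted_covariance_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = rng.integers(3, 50)
            pts = rng.normal(0, 3, (n, 2))
            w = rng.uniform(0.1, 2.0, n)
            sigma = pk.weighted_covariance(pts, w)
            mx = np.sum(w * pts[:, 0]) / w.sum()
            my = np.sum(w * pts[:, 1]) / w.sum()
            brute = np.zeros((2, 2))
            for (x, y), wi in zip(pts, w):
                d = np.array([x - mx, y - my])
                brute += wi * np.outer(d, d)
            brute /= w.sum()
            np.testing.assert_allclose(sigma, brute, atol=1e-12)

    def test_homogeneous_distribution_gives_equal_eigenvalues(self):
        prof = dense_profile(lambda th: np.full_like(th, 9.0))
        pts = pk.intensity_coords(pk.normalize_intensities(prof))
        sigma = pk.weighted_covariance(pts, prof.weights)
        l1, l2 = _eigen_split(sigma)
        assert l1 == pytest.approx(l2, abs=1e-9)


class TestPcaReadout:
    def test_uniform_cell_unpolarized(self):
        prof = dense_profile(lambda th: np.full_like(th, 9.0))
        r = pk.pca_polarity(prof)
        assert r.magnitude == pytest.approx(0.0, abs=1e-9)
        assert r.angle_deg is None

    def test_bipolar_pattern_oriented_along_x(self):
        def f(th):
            d = np.degrees(np.abs(np.angle(np.exp(1j * th))))
            return np.where((d < 60) | (d > 120), 255.0, 40.0)
        r = pk.pca_polarity(dense_profile(f))
        assert r.magnitude > 0
        assert abs(r.angle_deg) < 0.5

    def test_rotation_equivariance(self):
        def f(th):
            return 40 + 215 * (np.cos(2 * th) > 0)
        p0 = dense_profile(f)
        delta = np.radians(25.0)
        rot = np.array([[np.cos(delta), -np.sin(delta)],
                        [np.sin(delta), np.cos(delta)]])
        p1 = pk.BoundaryProfile.from_points(p0.xy @ rot.T, p0.intensities)
        r0, r1 = pk.pca_polarity(p0), pk.pca_polarity(p1)
        assert r1.magnitude == pytest.approx(r0.magnitude, rel=1e-6)
        assert pk.axial_difference_deg(r1.angle_deg, r0.angle_deg + 25.0) < 1e-6

    def test_brightness_and_format_invariance(self):
        def f(th):
            return 40 + 215 * (np.cos(2 * th) > 0)
        prof = dense_profile(f)
        r8 = pk.pca_polarity(prof)
        r12 = pk.pca_polarity(prof.with_intensities(prof.intensities * 4095 / 255))
        assert r12.magnitude == pytest.approx(r8.magnitude, rel=1e-12)

    def test_magnitude_increases_with_contrast(self):
        mags = []
        for peak in (60.0, 120.0, 255.0):
            prof = dense_profile(lambda th, p=peak: 40 + (p - 40) * (np.cos(2 * th) > 0))
            mags.append(pk.pca_polarity(prof).magnitude)
        assert mags[0] < mags[1] < mags[2]

    def test_standard_cell_angles_agree_across_methods(self, hexagon_readouts):
        for m, r in hexagon_readouts.items():
            assert pk.axial_difference_deg(r.angle_deg, 0.0) < 2.0, m


@given(st.floats(0.1, 0.5))
def test_pca_coverage_complement_symmetry(frac):
    """Complementary peak-coverage patterns polarize equally strongly."""
    def pattern(th, f):
        d = np.abs(np.angle(np.exp(1j * th)))  # distance to 0/180 poles
        d = np.minimum(d, np.pi - d)
        return np.where(d <= f * np.pi / 2, 255.0, 40.0)
    p1 = pk.pca_polarity(dense_profile(lambda th: pattern(th, frac)))
    p2 = pk.pca_polarity(dense_profile(lambda th: pattern(th, 1.0 - frac)))
    assert p2.magnitude == pytest.approx(p1.magnitude, rel=0.2)
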