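import numpy as np
import pytest

import polaritykit as pk
from polaritykit.synthetic import (GeneratorError, _material_angles,
                                   paint_puncta, paint_two_level)


def boundary_of(cell):
    lat = pk.label_cells(cell.skeleton)
    return pk.trace_boundary(lat, lat.interior_ids()[0])


class TestGeometryTargets:
    def test_regular_hexagon_is_nearly_circular(self):
        cell = pk.make_cell(pk.SyntheticCellSpec(area=14000.0, perimeter=None))
        assert cell.truth["eccentricity"] < 0.05

    @pytest.mark.parametrize("target", [0.4, 0.6, 0.8])
    def test_eccentricity_targets_hit(self, target):
        cell = pk.make_cell(pk.SyntheticCellSpec(area=14000.0, perimeter=None,
                                                 eccentricity=target))
        assert cell.truth["eccentricity"] == pytest.approx(target, abs=0.02)

    @pytest.mark.parametrize("target", [1500.0, 14000.0, 46000.0])
    def test_area_targets_hit(self, target):
        cell = pk.make_cell(pk.SyntheticCellSpec(area=target, perimeter=None))
        assert cell.truth["area"] == pytest.approx(target, rel=0.05)

    @pytest.mark.parametrize("target", [0.5, 0.7, 0.85])
    def test_regularity_targets_hit(self, target):
        cell = pk.make_cell(pk.SyntheticCellSpec(area=14000.0, perimeter=None,
                                                 regularity=target, seed=4))
        assert cell.truth["regularity"] == pytest.approx(target, abs=0.02)

    def test_perimeter_spec_close_to_target(self):
        cell = pk.make_cell(pk.SyntheticCellSpec(perimeter=440.0))
        assert cell.truth["perimeter"] == pytest.approx(440.0, rel=0.05)

    def test_unreachable_regularity_raises(self):
        with pytest.raises(GeneratorError):
            pk.make_cell(pk.SyntheticCellSpec(area=14000.0, perimeter=None,
                                              regularity=0.05))

    def test_spec_determinism(self):
        spec = pk.SyntheticCellSpec(area=8000.0, perimeter=None,
                                    regularity=0.7, seed=11)
        c1, c2 = pk.make_cell(spec), pk.make_cell(spec)
        assert np.array_equal(c1.image, c2.image)
        assert np.array_equal(c1.skeleton, c2.skeleton)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            pk.SyntheticCellSpec(peak=10.0, base=40.0).validate()
        with pytest.raises(ValueError):
            pk.SyntheticCellSpec(eccentricity=1.5).validate()
        with pytest.raises(ValueError):
            pk.SyntheticCellSpec(placement=("coverage", 500.0)).validate()
        with pytest.raises(ValueError):
            pk.SyntheticCellSpec(intensity_model="stripes").validate()


class TestTwoLevelPainting:
    def test_sector_covers_vertical_junction_pairs(self, hexagon_cell):
        b = hexagon_cell.boundary
        psi = _material_angles(b, s=1.0)
        I = hexagon_cell.loop_intensities
        inner = (np.abs(psi) < 55) | (np.abs(psi) > 125)   # clear of the edges
        outer = (np.abs(psi) > 65) & (np.abs(psi) < 115)
        assert np.all(I[inner] == 255.0)
        assert np.all(I[outer] == 40.0)

    def test_zero_coverage_all_base_and_unpolarized(self):
        cell = pk.make_cell(pk.SyntheticCellSpec(perimeter=440.0,
                                                 placement=("coverage", 0.0)))
        assert np.all(cell.loop_intensities == 40.0)
        r = pk.measure_cell(cell)
        assert r["fourier"].magnitude == pytest.approx(0.0, abs=1e-4)
        assert r["ratio"].magnitude == pytest.approx(1.0)

    def test_full_coverage_all_peak_and_unpolarized(self):
        cell = pk.make_cell(pk.SyntheticCellSpec(perimeter=440.0,
                                                 placement=("coverage", 440.0)))
        assert np.all(cell.loop_intensities == 255.0)
        r = pk.measure_cell(cell)
        assert r["pca"].magnitude == pytest.approx(0.0, abs=1e-3)

    def test_coverage_mass_scales_with_units(self, hexagon_cell):
        b = hexagon_cell.boundary
        for units in (40.0, 200.0, 400.0):
            I = paint_two_level(b, ("coverage", units), nominal_perimeter=440.0)
            span = (b.step_lengths + np.roll(b.step_lengths, 1)) / 2.0
            frac = ((I - 40.0) / 215.0 * span).sum() / b.perimeter
            assert frac == pytest.approx(units / 440.0, abs=0.02)

    def test_horizontal_placement_flips_axis(self):
        cell = pk.make_cell(pk.SyntheticCellSpec(
            perimeter=440.0, placement="horizontal_junctions"))
        assert cell.truth["axis_deg"] == 90.0
        r = pk.measure_cell(cell)
        for m in ("pca", "fourier", "ratio"):
            assert pk.axial_difference_deg(r[m].angle_deg, 90.0) < 2.0


class TestPuncta:
    def test_punctum_count_matches_spacing(self):
        cell = pk.make_cell(pk.SyntheticCellSpec(
            perimeter=440.0, intensity_model="puncta",
            placement=("sector", 90.0)))   # uniform bright puncta
        I = cell.loop_intensities
        peaks = 0
        n = len(I)
        for i in range(n):
            if I[i] > I[i - 1] and I[i] >= I[(i + 1) % n] and I[i] > 150:
                peaks += 1
        assert peaks == 360 // 15

    def test_punctum_center_reaches_peak_value(self, ):
        cell = pk.make_cell(pk.SyntheticCellSpec(
            perimeter=440.0, intensity_model="puncta",
            placement=("sector", 90.0)))
        assert cell.loop_intensities.max() == pytest.approx(255.0, abs=2.0)

    def test_far_field_relaxes_to_base(self):
        cell = pk.make_cell(pk.SyntheticCellSpec(
            perimeter=440.0, intensity_model="puncta", puncta_spacing_deg=90.0,
            placement=("sector", 90.0)))
        assert cell.loop_intensities.min() == pytest.approx(40.0, abs=1.0)

    def test_profile_matches_bruteforce_evaluation(self, hexagon_cell):
        b = hexagon_cell.boundary
        I = paint_puncta(b, placement="vertical_junctions", spacing_deg=15.0,
                         sigma=4.47, sigma_units="deg")
        psi = _material_angles(b, 1.0)
        for i in range(0, len(I), 37):
            centers = np.arange(-180.0, 180.0, 15.0)
            d = np.abs((psi[i] - centers + 180) % 360 - 180)
            j = np.argmin(d)
            amp = 255.0 if (abs(centers[j]) <= 60 or abs(centers[j]) >= 120) else 40.0
            expected = 40.0 + (amp - 40.0) * np.exp(-d[j] ** 2 / (2 * 4.47 ** 2))
            assert I[i] == pytest.approx(expected, abs=1e-9)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            pk.SyntheticCellSpec(intensity_model="puncta", puncta_sigma=-1.0).validate()


class TestNoise:
    def test_fixed_seed_is_bit_identical(self, hexagon_cell):
        n1 = pk.add_noise(hexagon_cell, snr=5.0, seed=3)
        n2 = pk.add_noise(hexagon_cell, snr=5.0, seed=3)
        assert np.array_equal(n1.image, n2.image)

    def test_different_seeds_differ(self, hexagon_cell):
        n1 = pk.add_noise(hexagon_cell, snr=5.0, seed=3)
        n2 = pk.add_noise(hexagon_cell, snr=5.0, seed=4)
        assert not np.array_equal(n1.image, n2.image)

    def test_infinite_snr_is_identity(self, hexagon_cell):
        out = pk.add_noise(hexagon_cell, snr=1e12, seed=0)
        assert np.array_equal(out.image, hexagon_cell.image)

    def test_noise_sd_matches_spec(self):
        # 12-bit container, peak below full range and mild noise: boundary
        # pixels never clip, so the empirical sd pooled over many seeds must
        # match the requested level closely
        cell = pk.make_cell(pk.SyntheticCellSpec(area=30000.0, perimeter=None,
                                                 peak=200.0, bit_depth=12))
        snr = 20.0
        rc = cell.boundary.points_rc
        clean = cell.image[rc[:, 0], rc[:, 1]].astype(float)
        resid = []
        for seed in range(20):
            noisy = pk.add_noise(cell, snr=snr, seed=seed)
            resid.append(noisy.image[rc[:, 0], rc[:, 1]].astype(float) - clean)
        resid = np.concatenate(resid)
        assert resid.size > 1e4
        assert resid.std() == pytest.approx(clean.mean() / snr, rel=0.02)

    def test_invalid_snr_rejected(self, hexagon_cell):
        with pytest.raises(ValueError):
            pk.add_noise(hexagon_cell, snr=0.0)


class TestBitDepth:
    def test_format_invariance_of_readouts(self):
        r8 = pk.measure_cell(pk.make_cell(pk.SyntheticCellSpec(perimeter=440.0,
                                                               bit_depth=8)))
        r12 = pk.measure_cell(pk.make_cell(pk.SyntheticCellSpec(perimeter=440.0,
                                                                bit_depth=12)))
        for m in r8:
            assert r12[m].magnitude == pytest.approx(r8[m].magnitude, rel=0.01)

    def test_container_dtype(self):
        assert pk.make_cell(pk.SyntheticCellSpec(perimeter=440.0,
                                                 bit_depth=8)).image.dtype == np.uint8
        assert pk.make_cell(pk.SyntheticCellSpec(perimeter=440.0,
                                                 bit_depth=16)).image.dtype == np.uint16
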