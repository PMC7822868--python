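"""Colour transforms: cone excitations, von Kries scaling, tristimulus,
CIELAB, CIECAM02 (against the CIE worked example), S-CIELAB filtering,
daylight illuminants, and illuminant substitution."""

import numpy as np
import pytest

from chromascene import colorimetry as cm
from chromascene.errors import DomainError, FormatError
from chromascene.io import RadianceCube

WL = cm.DEFAULT_WAVELENGTHS


class TestConeExcitations:
    def test_zero_spectrum_maps_to_zero(self):
        assert np.array_equal(cm.cone_excitations(np.zeros(WL.size)), np.zeros(3))

    def test_linearity(self, rng):
        a = rng.uniform(0, 1, WL.size)
        b = rng.uniform(0, 1, WL.size)
        assert np.allclose(
            cm.cone_excitations(a + b),
            cm.cone_excitations(a) + cm.cone_excitations(b),
        )

    def test_monochromatic_spike_reads_fundamentals(self):
        spike = np.zeros(WL.size)
        i550 = int(np.nonzero(WL == 550.0)[0][0])
        spike[i550] = 1.0
        expected = cm.lms_fundamentals(WL)[i550] * 10.0  # 10-nm bin width
        assert np.allclose(cm.cone_excitations(spike), expected)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(FormatError):
            cm.cone_excitations(np.ones(10), WL)


class TestVonKries:
    def test_scaled_means_are_unity(self, rng):
        q = rng.uniform(0.1, 5, (200, 3))
        scaled = cm.von_kries_scale(q)
        assert np.allclose(scaled.mean(axis=0), 1.0, atol=1e-12)

    def test_identical_triplets_map_to_ones(self):
        q = np.tile([0.4, 1.2, 0.09], (50, 1))
        assert np.allclose(cm.von_kries_scale(q), 1.0)

    def test_global_scale_invariance(self, rng):
        q = rng.uniform(0.1, 5, (100, 3))
        assert np.allclose(cm.von_kries_scale(q), cm.von_kries_scale(7.3 * q))


class TestDeltaE:
    def test_identical_triplets_give_zero(self):
        t = np.array([1.0, 1.0, 1.0])
        assert cm.delta_e_cones(t, t) == 0.0

    def test_three_four_five(self):
        assert cm.delta_e_cones(
            np.array([1.0, 1.0, 1.0]), np.array([1.3, 1.4, 1.0])
        ) == pytest.approx(0.5)

    def test_matches_brute_force(self, rng):
        t1, t2 = rng.uniform(0, 2, (2, 40, 3))
        brute = np.sqrt(((t1 - t2) ** 2).sum(axis=1))
        assert np.allclose(cm.delta_e_cones(t1, t2), brute)


class TestTristimulus:
    def test_zero_and_linearity(self, rng):
        assert np.array_equal(cm.tristimulus(np.zeros(WL.size)), np.zeros(3))
        a, b = rng.uniform(0, 1, (2, WL.size))
        assert np.allclose(
            cm.tristimulus(a + b), cm.tristimulus(a) + cm.tristimulus(b)
        )

    def test_equal_energy_nearly_achromatic(self):
        xyz = cm.tristimulus(np.ones(WL.size))
        assert np.all(np.abs(xyz / xyz[1] - 1.0) < 0.02)

    def test_white_normalisation(self, rng):
        white = rng.uniform(0.5, 1.5, WL.size)
        xyz = cm.tristimulus(white, WL, white_spectrum=white)
        assert xyz[1] == pytest.approx(100.0)


class TestCielab:
    WHITE = np.array([95.05, 100.0, 108.88])

    def test_white_maps_to_lightness_100(self):
        assert np.allclose(cm.cielab_coords(self.WHITE, self.WHITE), [100.0, 0.0, 0.0])

    def test_black_maps_to_origin(self):
        assert np.allclose(cm.cielab_coords(np.zeros(3), self.WHITE), 0.0)

    def test_mid_grey_lightness(self):
        lab = cm.cielab_coords(0.18 * self.WHITE, self.WHITE)
        assert lab[0] == pytest.approx(49.50, abs=0.1)

    def test_zero_white_rejected(self):
        with pytest.raises(DomainError):
            cm.cielab_coords(np.ones(3), np.zeros(3))


class TestCiecam02:
    VC = cm.ViewingConditions(
        white_point=np.array([95.05, 100.0, 108.88]),
        adapting_luminance=318.31,
        background_relative_luminance=0.2,
        surround="average",
    )

    def test_cie_worked_example(self):
        out = cm.ciecam02_coords(np.array([19.01, 20.00, 21.78]), self.VC)
        j, chroma, hue = out[0], np.hypot(out[1], out[2]), np.degrees(
            np.arctan2(out[2], out[1])
        ) % 360
        assert j == pytest.approx(41.73, abs=0.05)
        assert chroma == pytest.approx(0.1047, abs=0.005)
        assert hue == pytest.approx(219.0, abs=0.5)

    def test_white_point_maps_to_ceiling(self):
        out = cm.ciecam02_coords(self.VC.white_point, self.VC)
        assert out[0] == pytest.approx(100.0, abs=0.5)
        assert np.hypot(out[1], out[2]) < 1.0

    def test_relative_colorimetry_invariance(self):
        # scaling stimulus and white together leaves appearance unchanged
        xyz = np.array([19.01, 20.00, 21.78])
        scaled_vc = cm.ViewingConditions(
            white_point=self.VC.white_point * 3.0,
            adapting_luminance=self.VC.adapting_luminance,
        )
        out1 = cm.ciecam02_coords(xyz, self.VC)
        out2 = cm.ciecam02_coords(xyz * 3.0, scaled_vc)
        assert np.allclose(out1, out2)

    def test_j_comonotone_with_lstar_on_neutral_ramp(self):
        fracs = np.linspace(0.02, 1.0, 12)
        ramp = fracs[:, None] * self.VC.white_point[None, :]
        j = cm.ciecam02_coords(ramp, self.VC)[:, 0]
        lstar = cm.cielab_coords(ramp, self.VC.white_point)[:, 0]
        assert np.all(np.diff(j) > 0) and np.all(np.diff(lstar) > 0)

    def test_negative_xyz_rejected(self):
        with pytest.raises(DomainError):
            cm.ciecam02_coords(np.array([-1.0, 0.5, 0.5]), self.VC)


class TestScielab:
    WHITE = np.array([95.05, 100.0, 108.88])

    def test_uniform_field_reduces_to_cielab(self):
        xyz = np.tile([40.0, 45.0, 38.0], (32, 32, 1))
        filtered = cm.scielab_transform(xyz, 200.0, self.WHITE)
        plain = cm.cielab_coords(np.array([40.0, 45.0, 38.0]), self.WHITE)
        assert np.max(np.abs(filtered - plain)) < 1e-6

    def test_impulse_spread_in_pixels_grows_with_resolution(self):
        # kernels are fixed in visual angle, so the blur spans more
        # pixels when each degree covers more pixels
        img = np.tile([20.0, 20.0, 20.0], (33, 33, 1))
        img[16, 16] = [60.0, 60.0, 60.0]

        def spread(ppd):
            lab = cm.scielab_transform(img, ppd, self.WHITE)
            resp = lab[:, :, 0] - lab[0, 0, 0]
            resp = np.abs(resp) / np.abs(resp).sum()
            yy, xx = np.mgrid[:33, :33]
            return np.sqrt((resp * ((yy - 16) ** 2 + (xx - 16) ** 2)).sum())

        assert spread(200.0) > spread(50.0)

    def test_nonpositive_ppd_rejected(self):
        with pytest.raises(DomainError):
            cm.scielab_transform(np.zeros((4, 4, 3)), 0.0, self.WHITE)


class TestDaylight:
    @pytest.mark.parametrize("cct", [4000.0, 6500.0, 10000.0])
    def test_chromaticity_on_daylight_locus(self, cct):
        spd = cm.daylight_spd(cct)
        xyz = cm.tristimulus(spd.power)
        x, y = xyz[0] / xyz.sum(), xyz[1] / xyz.sum()
        xd, yd = cm.daylight_locus_chromaticity(cct)
        assert abs(x - xd) < 1e-3 and abs(y - yd) < 1e-3

    def test_warm_illuminant_is_red_heavy(self):
        spd = cm.daylight_spd(4000.0)
        p700 = spd.power[np.nonzero(WL == 700.0)[0][0]]
        p450 = spd.power[np.nonzero(WL == 450.0)[0][0]]
        assert p700 > p450

    def test_power_nonnegative_and_unit_mean(self):
        for cct in (4000.0, 25000.0):
            spd = cm.daylight_spd(cct)
            assert spd.power.min() >= 0.0
            assert spd.power.mean() == pytest.approx(1.0)

    def test_out_of_range_cct_rejected(self):
        with pytest.raises(DomainError):
            cm.daylight_spd(3000.0)


class TestReilluminate:
    def _cube(self, rng):
        return RadianceCube(rng.uniform(0.1, 1, (8, 8, WL.size)), WL)

    def test_identity(self, rng):
        cube = self._cube(rng)
        e = cm.daylight_spd(6500.0)
        out = cm.reilluminate(cube, e, e)
        assert np.allclose(out.values, cube.values)

    def test_doubling(self, rng):
        cube = self._cube(rng)
        e = cm.daylight_spd(6500.0)
        e2 = cm.IlluminantSpectrum(e.wavelengths, 2.0 * e.power)
        out = cm.reilluminate(cube, e, e2)
        assert np.allclose(out.values, 2.0 * cube.values)

    def test_round_trip(self, rng):
        cube = self._cube(rng)
        e65, e40 = cm.daylight_spd(6500.0), cm.daylight_spd(4000.0)
        back = cm.reilluminate(cm.reilluminate(cube, e65, e40), e40, e65)
        assert np.max(np.abs(back.values - cube.values)) < 1e-10
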