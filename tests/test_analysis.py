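"""Surface-count analyses: zero-interval reduction, monotonicities,
time-course regression, strip profiles, the Rice SD estimator, and BCa
aggregation across scenes."""

import math

import numpy as np
import pytest

from chromascene.analysis import (
    ColourSample,
    aggregate_ci,
    n_distinguishable,
    n_identifiable,
    relative_sd_profile,
    rice_sd,
    time_course_fit,
)
from chromascene.errors import (
    DomainError,
    InsufficientDataError,
    PairingError,
)
from chromascene.information import NoiseModel, noise_width_from_threshold
from chromascene.io import RadianceCube

WL3 = np.array([450.0, 550.0, 650.0])


def _colour_sample(rng, n=4000, spread=20.0):
    vals = rng.normal(0, spread, (n, 3)) + np.array([50.0, 0.0, 0.0])
    return ColourSample(vals, "CIECAM02")


class TestZeroIntervalReduction:
    def test_identifiable_at_zero_interval_equals_distinguishable(self, rng):
        s = _colour_sample(rng)
        noise = noise_width_from_threshold(0.5, "gaussian", seed=4)
        d = n_distinguishable(s, noise, seed=21)
        i = n_identifiable(s, s, noise, interval_dt=0.0, seed=21)
        assert d.mi.bits == i.mi.bits  # bit-identical under shared seeds
        assert d.n_surfaces == i.n_surfaces


class TestSurfaceCounts:
    def test_reshuffled_partner_destroys_information(self, rng):
        s1 = _colour_sample(rng, n=3000)
        perm = rng.permutation(len(s1))
        s2 = ColourSample(s1.values[perm], s1.space)
        noise = noise_width_from_threshold(0.5, "gaussian", seed=1)
        est = n_identifiable(s1, s2, noise, interval_dt=5.0, seed=2)
        assert est.n_surfaces == pytest.approx(1.0, abs=0.15)

    def test_count_shrinks_with_noise_width(self, rng):
        s = _colour_sample(rng)
        small = NoiseModel("gaussian", width_w=1.0, seed=3)
        large = NoiseModel("gaussian", width_w=2.0, seed=3)
        n_small = n_distinguishable(s, small, seed=3).mi.bits
        n_large = n_distinguishable(s, large, seed=3).mi.bits
        assert n_large < n_small - 0.1

    def test_perturbation_amplitude_reduces_identifiability(self, rng):
        s1 = _colour_sample(rng)
        noise = noise_width_from_threshold(0.5, "gaussian", seed=5)
        bits = []
        for amp in (1.0, 2.0):
            s2 = ColourSample(s1.values + rng.normal(0, amp, s1.values.shape), s1.space)
            bits.append(n_identifiable(s1, s2, noise, interval_dt=1.0, seed=5).mi.bits)
        assert bits[1] < bits[0] - 0.1

    def test_identifiable_not_above_distinguishable(self, rng):
        s1 = _colour_sample(rng)
        s2 = ColourSample(s1.values + rng.normal(0, 0.5, s1.values.shape), s1.space)
        noise = noise_width_from_threshold(0.5, "gaussian", seed=6)
        d = n_distinguishable(s1, noise, seed=7)
        i = n_identifiable(s1, s2, noise, interval_dt=1.0, seed=7)
        assert i.mi.bits <= d.mi.bits + 0.1

    def test_unpaired_samples_rejected(self, rng):
        s1 = _colour_sample(rng, n=100)
        s2 = _colour_sample(rng, n=101)
        noise = NoiseModel("gaussian", 1.0, seed=0)
        with pytest.raises(PairingError):
            n_identifiable(s1, s2, noise)


class TestTimeCourse:
    def test_exact_power_law_recovered_to_machine_precision(self):
        c, b = 500.0, -0.5
        obs = [(dt, c * dt**b) for dt in (1.0, 2.0, 8.0, 32.0, 128.0)]
        fit = time_course_fit(obs)
        assert fit.slope == pytest.approx(b, abs=1e-12)
        assert 2.0**fit.intercept == pytest.approx(c, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.predictions[10.0] == pytest.approx(c * 10.0**b, rel=1e-10)

    def test_constant_counts_give_flat_regression(self):
        obs = [(dt, 300.0) for dt in (1.0, 4.0, 16.0)]
        fit = time_course_fit(obs)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(InsufficientDataError):
            time_course_fit([(1.0, 10.0), (2.0, 9.0)])

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(DomainError):
            time_course_fit([(0.0, 10.0), (1.0, 9.0), (2.0, 8.0)])


class TestRelativeSdProfile:
    def _flat_cube(self, value=0.5, h=60, w=40):
        return RadianceCube(np.full((h, w, 3), value), WL3)

    def test_identical_cubes_give_zero_profile(self, rng):
        vals = rng.uniform(0.1, 1.0, (60, 40, 3))
        cube = RadianceCube(vals, WL3)
        _, prof = relative_sd_profile(cube, cube, strip_height=10, strip_step=10)
        assert np.allclose(prof, 0.0)

    def test_global_rescaling_gives_zero_profile(self, rng):
        vals = rng.uniform(0.1, 1.0, (60, 40, 3))
        c1 = RadianceCube(vals, WL3)
        c2 = RadianceCube(3.0 * vals, WL3)
        _, prof = relative_sd_profile(c1, c2, strip_height=10, strip_step=10)
        assert np.max(prof) < 1e-9

    def test_injected_gain_contrast_recovered(self, rng):
        # uniform reflectance; 5% multiplicative gain noise in the lower
        # half only.  With identical spectra everywhere the scaled cone
        # triplet is (1,1,1), so Delta-e = sqrt(3) * 0.05 * |Z| with Z
        # standard normal; the strip SD of that half-normal variate is
        # sqrt(3) * 5% * sqrt(1 - 2/pi).
        h, w = 80, 64
        c1 = self._flat_cube(h=h, w=w)
        gain = np.ones((h, w, 1))
        gain[h // 2 :] = 1.0 + 0.05 * rng.standard_normal((h // 2, w, 1))
        c2 = RadianceCube(c1.values * gain, WL3)
        tops, prof = relative_sd_profile(c1, c2, strip_height=10, strip_step=10)
        upper = prof[tops + 10 <= h // 2]
        lower = prof[tops >= h // 2]
        expected = math.sqrt(3.0) * 5.0 * math.sqrt(1.0 - 2.0 / math.pi)  # percent
        assert np.max(upper) < 0.1
        assert np.mean(lower) == pytest.approx(expected, rel=0.2)

    def test_shape_mismatch_rejected(self, rng):
        c1 = self._flat_cube(h=20)
        c2 = self._flat_cube(h=24)
        with pytest.raises(PairingError):
            relative_sd_profile(c1, c2)


class TestRiceSd:
    def test_constant_series_has_zero_sd(self):
        assert rice_sd(np.full(100, 7.0)) == 0.0

    def test_recovers_white_noise_sd(self, rng):
        s = 0.35
        series = 10.0 + rng.normal(0, s, 10_000)
        assert rice_sd(series) == pytest.approx(s, rel=0.03)

    def test_slow_trend_suppressed(self, rng):
        s = 0.2
        t = np.arange(10_000)
        series = 50.0 + 5.0 * np.sin(2 * np.pi * t / 10_000) + rng.normal(0, s, t.size)
        assert rice_sd(series) == pytest.approx(s, rel=0.05)

    def test_relative_form_divides_by_mean(self, rng):
        series = 20.0 + rng.normal(0, 0.1, 5000)
        assert rice_sd(series, relative=True) == pytest.approx(
            rice_sd(series) / series.mean()
        )

    def test_nonpositive_mean_rejected_for_relative(self):
        with pytest.raises(DomainError):
            rice_sd(np.array([-1.0, 1.0, -1.0, 0.5]), relative=True)

    def test_short_series_rejected(self):
        with pytest.raises(DomainError):
            rice_sd(np.array([1.0, 2.0]))


class TestAggregateCi:
    def test_identical_scenes_collapse_to_point(self):
        agg = aggregate_ci([5.0, 5.0, 5.0], bootstrap_reps=100, seed=0)
        assert agg.ci_low == agg.mean_n == agg.ci_high == pytest.approx(32.0)

    def test_mean_on_bits_scale_is_geometric_mean_of_counts(self):
        bits = [2.0, 4.0, 6.0]
        agg = aggregate_ci(bits, bootstrap_reps=200, seed=1)
        counts = 2.0 ** np.array(bits)
        assert agg.mean_n == pytest.approx(np.exp(np.mean(np.log(counts))))

    def test_interval_brackets_mean(self, rng):
        bits = rng.normal(8.0, 0.5, 10)
        agg = aggregate_ci(bits, bootstrap_reps=1000, seed=2)
        assert agg.ci_low <= agg.mean_n <= agg.ci_high

    def test_bca_coverage_near_nominal(self, rng):
        mu, sigma, n_scenes = 8.0, 0.6, 8
        hits = 0
        reps = 200
        for i in range(reps):
            bits = rng.normal(mu, sigma, n_scenes)
            agg = aggregate_ci(bits, bootstrap_reps=999, seed=i)
            hits += agg.ci_low <= 2.0**mu <= agg.ci_high
        # BCa on 8 scenes undercovers slightly; accept a broad band
        assert 0.82 <= hits / reps <= 0.99

    def test_single_scene_rejected(self):
        with pytest.raises(DomainError):
            aggregate_ci([3.0], bootstrap_reps=100, seed=0)
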