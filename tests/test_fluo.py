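"""Tests for fluorescence preprocessing, spike inference and ROI growing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import nnls
from scipy.signal import lfilter

from swimencode import synthgen
from swimencode.fluo import (
    PixelMovie,
    estimate_noise,
    infer_spike_rate,
    mask_and_interpolate,
    neuropil_correct_and_dff,
    segment_rois_by_correlation,
    smooth_trace,
)


class TestDff:
    def test_constant_trace_gives_zero_dff(self):
        dff, f0 = neuropil_correct_and_dff(
            np.full(100, 100.0), np.zeros(100), inactivity_interval=(0, 50)
        )
        assert f0 == 100.0
        assert np.allclose(dff, 0.0)

    def test_doubling_plateau_gives_dff_one(self):
        f = np.concatenate([np.full(50, 100.0), np.full(50, 200.0)])
        dff, _ = neuropil_correct_and_dff(f, np.zeros(100), inactivity_interval=(0, 50))
        assert np.allclose(dff[50:], 1.0)

    def test_low_percentile_baseline_matches_arithmetic_oracle(self, rng):
        f_raw = 100 + 10 * rng.random(500)
        f_np = 20 + 5 * rng.random(500)
        dff, f0 = neuropil_correct_and_dff(f_raw, f_np, 0.7, baseline_mode="low_percentile")
        f = f_raw - 0.7 * f_np
        f0_oracle = np.median(f[f <= np.percentile(f, 10)])
        assert f0 == pytest.approx(f0_oracle)
        assert np.allclose(dff, (f - f0_oracle) / f0_oracle)

    def test_degenerate_baseline_raises(self):
        with pytest.raises(ValueError, match="degenerate baseline"):
            neuropil_correct_and_dff(
                np.zeros(50), np.zeros(50), inactivity_interval=(0, 10)
            )

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_dff_invariant_to_common_rescaling(self, scale):
        rng = np.random.default_rng(0)
        f_raw = 100 + 10 * rng.random(200)
        f_np = 20 + 2 * rng.random(200)
        dff1, _ = neuropil_correct_and_dff(f_raw, f_np, 0.7, inactivity_interval=(0, 100))
        dff2, _ = neuropil_correct_and_dff(
            scale * f_raw, scale * f_np, 0.7, inactivity_interval=(0, 100)
        )
        assert np.allclose(dff1, dff2, atol=1e-9)


class TestEstimateNoise:
    def test_zero_on_interval_gives_zero(self):
        assert estimate_noise(np.zeros(100), (0, 50), rate_hz=10) == 0.0

    def test_gaussian_sigma_recovered(self, rng):
        dff = rng.normal(0, 0.05, 300)
        s = estimate_noise(dff, (0, 300), rate_hz=10)
        assert 0.04 < s < 0.06

    def test_linear_ramp_matches_closed_form(self):
        n = 30
        ramp = np.linspace(0, 0.1, n)
        # sample s.d. of an arithmetic progression: step * sqrt(n(n+1)/12)
        step = 0.1 / (n - 1)
        expected = step * np.sqrt(n * (n + 1) / 12.0)
        assert estimate_noise(ramp, (0, n), rate_hz=30) == pytest.approx(expected)

    def test_interval_outside_trace_raises(self):
        with pytest.raises(ValueError):
            estimate_noise(np.zeros(10), (5, 20), rate_hz=10)


class TestSmoothTrace:
    def test_impulse_spreads_to_thirds(self):
        out = smooth_trace(np.array([0.0, 0.0, 1.0, 0.0, 0.0]))
        assert np.allclose(out[1:4], 1 / 3)
        # edges shrink to the available neighbors (2-frame mean)
        assert out[0] == 0.0 and out[-1] == 0.0

    def test_constant_unchanged(self):
        assert np.allclose(smooth_trace(np.full(10, 2.5)), 2.5)

    def test_white_noise_variance_reduced(self, rng):
        x = rng.normal(0, 1, 2000)
        assert smooth_trace(x).var() < x.var() / 2

    def test_low_pass_is_zero_phase(self):
        t = np.arange(0, 10, 0.1)
        x = np.sin(2 * np.pi * 0.2 * t)
        y = smooth_trace(x, mode="low_pass", cutoff_hz=1.0, rate_hz=10.0)
        # zero-phase filtering: peak position preserved
        assert abs(np.argmax(y) - np.argmax(x)) <= 1


class TestMaskAndInterpolate:
    def test_middle_frame_interpolated(self):
        out = mask_and_interpolate(np.array([0.0, 99.0, 2.0]), [1])
        assert out[1] == pytest.approx(1.0)

    def test_no_bad_frames_is_identity(self):
        x = np.arange(5.0)
        assert np.array_equal(mask_and_interpolate(x, []), x)

    def test_unmasked_frames_bit_identical_and_error_bounded(self, rng):
        t = np.arange(0, 30, 0.1)
        x = np.sin(2 * np.pi * 0.3 * t)
        bad = rng.choice(np.arange(1, t.size - 1), size=t.size // 20, replace=False)
        out = mask_and_interpolate(x, bad)
        good = np.setdiff1d(np.arange(t.size), bad)
        assert np.array_equal(out[good], x[good])
        # linear interpolation error bound: h^2/8 * max|f''|
        h = 0.1 * 2  # worst case: two adjacent bad frames never drawn here
        bound = (2 * h) ** 2 / 8 * (2 * np.pi * 0.3) ** 2
        assert np.max(np.abs(out[bad] - x[bad])) < bound

    def test_all_bad_raises(self):
        with pytest.raises(ValueError, match="all frames"):
            mask_and_interpolate(np.zeros(3), [0, 1, 2])


class TestInferSpikeRate:
    rate = 10.0

    def _kernel_conv(self, spikes, decay=1.8):
        gamma = np.exp(-1 / (decay * self.rate))
        return lfilter([1.0], [1.0, -gamma], spikes)

    def test_zero_trace_gives_zero_rate(self):
        assert np.all(infer_spike_rate(np.zeros(100), 1.8, self.rate) == 0)

    def test_single_transient_concentrates_mass_at_onset(self):
        spikes = np.zeros(200)
        spikes[40] = 1.0
        r = infer_spike_rate(self._kernel_conv(spikes), 1.8, self.rate)
        assert r[40] / r.sum() >= 0.90

    def test_matches_dense_nnls_oracle_on_small_system(self, rng):
        n = 80
        spikes = np.zeros(n)
        spikes[[10, 50]] = [1.0, 0.7]
        dff = self._kernel_conv(spikes) + rng.normal(0, 0.01, n)
        gamma = np.exp(-1 / (1.8 * self.rate))
        kmat = np.zeros((n, n))
        for j in range(n):
            kmat[j:, j] = gamma ** np.arange(n - j)
        oracle, _ = nnls(kmat, dff)
        r = infer_spike_rate(dff, 1.8, self.rate)
        assert np.allclose(r, oracle, atol=1e-6)

    def test_two_separated_transients_recovered(self):
        spikes = np.zeros(300)
        spikes[[30, 200]] = [1.0, 2.0]
        r = infer_spike_rate(self._kernel_conv(spikes), 1.8, self.rate)
        for j, amp in [(30, 1.0), (200, 2.0)]:
            mass = r[j - 1 : j + 2].sum()
            assert mass == pytest.approx(amp, rel=0.1)

    def test_ar_solver_exact_on_noise_free_input(self):
        spikes = np.zeros(500)
        spikes[[10, 100, 300]] = [0.5, 1.0, 0.2]
        r = infer_spike_rate(self._kernel_conv(spikes), 1.8, self.rate, solver="ar")
        assert np.allclose(r, spikes, atol=1e-12)

    def test_known_spikes_total_mass_within_10pct(self, rng):
        spikes = np.zeros(400)
        idx = rng.choice(400, 8, replace=False)
        spikes[idx] = rng.uniform(0.5, 2.0, 8)
        r = infer_spike_rate(self._kernel_conv(spikes), 1.8, self.rate)
        assert r.sum() == pytest.approx(spikes.sum(), rel=0.1)
        # peak locations within 1 frame
        for j in idx:
            assert r[max(j - 1, 0) : j + 2].sum() > 0.5 * spikes[j]


class TestRoiSegmentation:
    def test_pure_noise_movie_yields_no_rois(self, rng):
        movie, _ = synthgen.synth_pixel_movie([], rng, shape=(30, 30), n_frames=400)
        assert segment_rois_by_correlation(movie) == []

    def test_two_planted_disks_recovered(self, rng):
        movie, planted = synthgen.synth_pixel_movie(
            [((10, 10), 12.0), ((30, 30), 12.0)], rng
        )
        rois = segment_rois_by_correlation(movie)
        assert len(rois) == 2
        for roi in rois:
            overlap = max(len(set(roi.pixels) & p) / len(p) for p in planted)
            assert overlap >= 0.9
            assert 9.0 <= roi.area_um2 <= 28.0

    def test_oversized_region_rejected(self, rng):
        movie, _ = synthgen.synth_pixel_movie(
            [((20, 20), 40.0)], rng, signal_amp=6.0, noise_sigma=0.5
        )
        rois = segment_rois_by_correlation(movie)
        assert rois == []

    def test_masks_pairwise_disjoint(self, rng):
        movie, _ = synthgen.synth_pixel_movie(
            [((8, 8), 12.0), ((8, 30), 14.0), ((30, 15), 10.0)], rng
        )
        rois = segment_rois_by_correlation(movie)
        seen = set()
        for roi in rois:
            assert not (set(roi.pixels) & seen)
            seen |= set(roi.pixels)

    def test_too_small_movie_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            segment_rois_by_correlation(
                PixelMovie(frames=rng.random((10, 2, 5)), pixel_size_um=0.66, rate_hz=10)
            )
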