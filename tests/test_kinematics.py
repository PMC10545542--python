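"""Unit and property tests for tail-kinematics segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimencode import synthgen
from swimencode.kinematics import (
    Bend,
    Bout,
    Episode,
    StimTrial,
    TailTrace,
    classify_bout,
    cycle_kinematics,
    detect_bends,
    extract_bouts,
    forward_index,
    segment_episodes,
    site_median_forward_index,
    tag_provenance,
)
from conftest import make_sine_trace


class TestTailTrace:
    def test_rejects_empty_and_nonuniform(self):
        with pytest.raises(ValueError, match="empty"):
            TailTrace(np.array([]), np.array([]))
        with pytest.raises(ValueError, match="non-uniform"):
            TailTrace(np.array([0.0, 0.1, 0.3]), np.zeros(3))
        with pytest.raises(ValueError, match="finite"):
            TailTrace(np.array([0.0, 0.1]), np.array([0.0, np.nan]), rate_hz=10)


class TestDetectBends:
    def test_pure_sine_has_analytic_extrema(self, sine_trace):
        # 20 Hz sine over 0.25 s -> 10 half-cycle extrema of 15 degrees
        bends = detect_bends(sine_trace, min_amp_deg=5.0)
        assert len(bends) == 10
        # grid sampling + median prefilter attenuate the peak slightly
        assert np.allclose([abs(b.amp_deg) for b in bends], 15.0, atol=1.0)
        signs = np.sign([b.amp_deg for b in bends])
        assert np.all(signs[:-1] != signs[1:])

    def test_flat_trace_yields_no_bends(self):
        t = np.arange(0, 1, 1 / 300)
        assert detect_bends(TailTrace(t, np.zeros(t.size))) == []

    def test_noisy_sine_matches_brute_force_extrema(self):
        # oracle: per analytic half-period window, the extremum of the clean sine
        trace = make_sine_trace(noise_sigma=0.5, seed=7)
        clean = make_sine_trace()
        bends = detect_bends(trace, min_amp_deg=5.0)
        oracle = detect_bends(clean, min_amp_deg=5.0)
        assert len(bends) == len(oracle) == 10
        for b, o in zip(bends, oracle):
            assert abs(b.t_s - o.t_s) <= 1.0 / 300 + 1e-9


class TestExtractBouts:
    @staticmethod
    def _two_bursts(gap_s):
        rate = 300.0
        burst = 15 * np.sin(2 * np.pi * 20 * np.arange(0, 0.3, 1 / rate))
        gap = np.zeros(int(gap_s * rate))
        pad = np.zeros(150)
        angle = np.concatenate([pad, burst, gap, burst, pad])
        t = np.arange(angle.size) / rate
        return TailTrace(t, angle, rate)

    def test_separated_bursts_are_two_bouts(self):
        assert len(extract_bouts(self._two_bursts(1.0))) == 2

    def test_close_bursts_merge_into_one_bout(self):
        assert len(extract_bouts(self._two_bursts(0.05), min_quiet_s=0.1)) == 1

    def test_recovers_scheduled_bouts_with_timing(self):
        rng = np.random.default_rng(3)
        sched = synthgen.make_schedule(50, rng)
        trace, truth = synthgen.synth_session(sched, rng)
        bouts = extract_bouts(trace)
        assert len(bouts) == 50
        for b, tb in zip(bouts, truth.bouts):
            assert abs(b.start_s - tb.start_s) <= 0.010


class TestCycleKinematics:
    def test_constant_25ms_spacing_gives_20hz(self):
        bends = [Bend(0.025 * i, 15.0 * (-1) ** i) for i in range(8)]
        itbf, itba, n_osc = cycle_kinematics(bends)
        assert np.allclose(itbf, 20.0)
        assert np.allclose(itba, 15.0)
        assert n_osc == 4

    def test_seven_bends_is_three_oscillations(self):
        bends = [Bend(0.03 * i, 10.0 * (-1) ** i) for i in range(7)]
        assert cycle_kinematics(bends)[2] == 3

    def test_single_bend_yields_empty_series(self):
        itbf, _, n = cycle_kinematics([Bend(0.0, 10.0)])
        assert itbf.size == 0 and n == 0

    def test_chirp_tracks_instantaneous_frequency(self):
        # bend spacing ramping 15 -> 30 Hz; iTBF must be monotone increasing
        # and match the local same-side spacing within 10%
        freqs = np.linspace(15, 30, 20)
        t, times = 0.0, []
        for f in freqs:
            times.append(t)
            t += 1.0 / (2 * f)
        bends = [Bend(tt, 12.0 * (-1) ** i) for i, tt in enumerate(times)]
        itbf, _, _ = cycle_kinematics(bends)
        assert np.all(np.diff(itbf) > 0)
        local = 1.0 / (np.array(times[2:]) - np.array(times[:-2]))
        assert np.allclose(itbf, local, rtol=1e-9)


def _bout_from_amps(amps, spacing_s=0.03, gaps=None):
    times = np.cumsum([0.0] + [spacing_s] * (len(amps) - 1))
    if gaps:
        for idx, extra in gaps.items():
            times[idx:] += extra
    bends = [Bend(t, a) for t, a in zip(times, amps)]
    return Bout(start_s=times[0] - 0.01, end_s=times[-1] + 0.01, bends=bends)


class TestSegmentEpisodes:
    def test_five_small_oscillations_form_one_forward_episode(self):
        amps = [15.0 * (-1) ** i for i in range(10)]
        eps = segment_episodes(_bout_from_amps(amps))
        assert [e.label for e in eps] == ["forward"]
        assert eps[0].n_oscillations == 5

    def test_consecutive_large_bends_form_one_struggle(self):
        eps = segment_episodes(_bout_from_amps([40.0, -45.0, 40.0], spacing_s=0.05))
        assert [e.label for e in eps] == ["struggle"]

    def test_struggle_splits_at_gaps_over_100ms(self):
        # 4 osc at 15, then 3 large bends with a 150-ms internal gap, then 4 osc
        amps = [15.0 * (-1) ** i for i in range(8)]
        amps += [40.0, -45.0, 40.0]
        amps += [-15.0 * (-1) ** i for i in range(8)]
        gaps = {10: 0.12}  # 150 ms total between 2nd and 3rd large bend
        eps = segment_episodes(_bout_from_amps(amps, gaps=gaps))
        assert [e.label for e in eps] == ["forward", "struggle", "struggle", "forward"]

    def test_rare_isolated_large_bend_kept_in_forward_episode(self):
        amps = [15.0 * (-1) ** i for i in range(12)]
        amps += [30.0] + [-15.0 * (-1) ** i for i in range(12)]
        eps = segment_episodes(_bout_from_amps(amps))
        assert [e.label for e in eps] == ["forward"]
        assert len(eps[0].absorbed) == 1

    def test_forward_episodes_respect_amplitude_and_oscillation_contract(self):
        rng = np.random.default_rng(11)
        sched = synthgen.make_schedule(40, rng, bout_types=("forward", "mixed", "struggle"))
        trace, _ = synthgen.synth_session(sched, rng)
        for i, b in enumerate(extract_bouts(trace)):
            for e in segment_episodes(b, bout_id=i):
                if e.label == "forward":
                    kept = [x for k, x in enumerate(e.bends) if k not in set(e.absorbed)]
                    assert all(abs(x.amp_deg) <= 25.0 for x in kept)
                    assert e.n_oscillations >= 3

    def test_episode_bends_partition_bout_bends(self):
        amps = [15.0 * (-1) ** i for i in range(8)] + [40.0, -45.0]
        bout = _bout_from_amps(amps)
        eps = segment_episodes(bout)
        all_times = sorted(b.t_s for e in eps for b in e.bends)
        assert all_times == sorted(b.t_s for b in bout.bends)


class TestClassifyBout:
    @pytest.mark.parametrize(
        "amps,expected",
        [
            ([20.0, -18.0, 16.0], "forward"),
            ([40.0, -18.0, 16.0], "left_turn"),
            ([-40.0, 18.0, -16.0], "right_turn"),
            ([70.0, -65.0], "discarded"),
            ([24.9, -24.9], "forward"),
            ([25.0, -20.0], "left_turn"),
        ],
    )
    def test_threshold_rules(self, amps, expected):
        assert classify_bout(_bout_from_amps(amps)) == expected


class TestForwardIndex:
    @staticmethod
    def _eps(nf, ns):
        eps = [Episode(0, i, i + 0.1, "forward") for i in range(nf)]
        eps += [Episode(0, 10 + i, 10.1 + i, "struggle") for i in range(ns)]
        return eps

    @pytest.mark.parametrize("nf,ns,expected", [(5, 0, 1.0), (0, 4, -1.0), (3, 1, 0.5)])
    def test_arithmetic(self, nf, ns, expected):
        assert forward_index(self._eps(nf, ns)) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no episodes"):
            forward_index([])

    @given(nf=st.integers(0, 20), ns=st.integers(0, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetric_under_label_swap(self, nf, ns):
        if nf + ns == 0:
            return
        assert forward_index(self._eps(nf, ns)) == pytest.approx(
            -forward_index(self._eps(ns, nf))
        )


class TestSiteMedianForwardIndex:
    @staticmethod
    def _trial(freq, ua):
        return StimTrial(0.0, 1.0, pulse_freq_hz=freq, intensity_ua=ua)

    def test_median_over_qualifying_trials(self):
        trials = [(self._trial(10, 1.0), 1.0), (self._trial(10, 2.0), 0.5), (self._trial(10, 1.5), -1.0)]
        assert site_median_forward_index(trials) == pytest.approx(0.5)

    def test_no_qualifying_trials_is_nan(self):
        trials = [(self._trial(20, 1.0), 1.0), (self._trial(20, 2.0), 0.5)]
        assert np.isnan(site_median_forward_index(trials))

    def test_matches_brute_force_filter_and_median(self, rng):
        trials = []
        for _ in range(60):
            freq = float(rng.choice([5, 10, 20]))
            ua = float(rng.uniform(0.5, 3.0))
            trials.append((self._trial(freq, ua), float(rng.uniform(-1, 1))))
        oracle = [fi for tr, fi in trials if tr.pulse_freq_hz == 10 and 1 <= tr.intensity_ua <= 2]
        expected = float(np.median(oracle)) if oracle else float("nan")
        got = site_median_forward_index(trials)
        assert got == pytest.approx(expected, nan_ok=True)


class TestProvenance:
    def test_evoked_excluded_and_spontaneous_windows(self):
        trials = [StimTrial(10.0, 14.0, pulse_freq_hz=10, intensity_ua=1.0, stim_id=3)]
        bouts = [
            Bout(start_s=5.0, end_s=5.3),
            Bout(start_s=11.0, end_s=11.3),
            Bout(start_s=30.0, end_s=30.3),
            Bout(start_s=80.0, end_s=80.3),
        ]
        tag_provenance(bouts, trials)
        assert [b.provenance for b in bouts] == ["spontaneous", "evoked", "excluded", "spontaneous"]
        assert bouts[1].stim_id == 3
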