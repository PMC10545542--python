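"""Tests for pulse-response detection, reliability, slopes and clustering."""

import numpy as np
import pytest
from scipy.signal import lfilter

from swimencode.fluo import FluoTrace
from swimencode.kinematics import Episode
from swimencode.recruitment import (
    classify_reliability,
    cluster_forward,
    corrected_episode_max,
    detect_pulse_response,
    episode_recruitment,
    forward_activity_index,
    onset_peak_detect,
    rising_slope,
)

RATE = 10.0


def make_trace(dff, noise_sigma=0.02, roi_id=0):
    dff = np.asarray(dff, dtype=float)
    t = np.arange(dff.size) / RATE
    tr = FluoTrace(
        roi_id=roi_id, t_s=t, f_raw=100 * (1 + dff), f_neuropil=np.zeros(dff.size), rate_hz=RATE
    )
    tr.dff = dff
    tr.noise_sigma = noise_sigma
    return tr


def transient_dff(n, onset, amp, decay=1.8):
    s = np.zeros(n)
    s[onset] = amp
    gamma = np.exp(-1 / (decay * RATE))
    return lfilter([1.0], [1.0, -gamma], s)


class TestDetectPulseResponse:
    def test_4sigma_transient_responds(self):
        tr = make_trace(transient_dff(100, 55, 4 * 0.02))
        assert detect_pulse_response(tr, 5.0).responded

    def test_flat_trace_does_not_respond(self):
        tr = make_trace(np.zeros(100))
        assert not detect_pulse_response(tr, 5.0).responded

    def test_truncated_window_errors(self):
        tr = make_trace(np.zeros(100))
        with pytest.raises(ValueError, match="incomplete window"):
            detect_pulse_response(tr, 9.0)  # needs 3 s after stim

    def test_null_false_positive_rate_matches_monte_carlo(self):
        # detection on 400 pure-noise traces vs an independent simulation of
        # the same 3-sigma windowed-max exceedance probability
        sigma = 0.05
        rng = np.random.default_rng(21)
        hits = 0
        n_tr = 400
        for _ in range(n_tr):
            tr = make_trace(rng.normal(0, sigma, 100), noise_sigma=sigma)
            hits += detect_pulse_response(tr, 5.0).responded
        obs = hits / n_tr
        rng2 = np.random.default_rng(900)
        mc = 0
        n_mc = 4000
        for _ in range(n_mc):
            x = rng2.normal(0, sigma, 100)
            base = x[35:50].mean()
            mc += x[50:80].max() > base + 3 * sigma
        p_mc = mc / n_mc
        ci = 1.96 * np.sqrt(p_mc * (1 - p_mc) / n_tr)
        assert abs(obs - p_mc) <= ci + 1e-9


class TestClassifyReliability:
    @pytest.mark.parametrize(
        "pattern,label,thr",
        [
            ([0, 0, 1, 1, 1], "reliable", 3.0),
            ([0, 1, 0, 1, 1], "unreliable", None),
            ([0, 0, 0, 0, 0], "non_recruited", None),
            ([1, 1, 1, 1, 1], "reliable", 1.0),
        ],
    )
    def test_patterns(self, pattern, label, thr):
        resp = [(float(i + 1), [bool(v)]) for i, v in enumerate(pattern)]
        lab = classify_reliability(resp)
        assert lab.label == label
        assert lab.threshold_intensity_ua == thr

    def test_monotone_adding_high_intensity_response(self):
        base = [(1.0, [False]), (2.0, [True])]
        before = classify_reliability(base).label
        after = classify_reliability(base + [(3.0, [True])]).label
        assert before != "non_recruited" and after != "non_recruited"

    def test_multiple_trials_per_intensity(self):
        resp = [(1.0, [False, False]), (2.0, [True, True]), (3.0, [True, True])]
        assert classify_reliability(resp).label == "reliable"
        resp2 = [(1.0, [False, False]), (2.0, [True, False]), (3.0, [True, True])]
        assert classify_reliability(resp2).label == "unreliable"


class TestRisingSlope:
    def test_arithmetic(self):
        tr = make_trace(np.zeros(100))
        tr.dff = np.zeros(100)
        tr.dff[20:] = 0.1  # t=2.0 s
        tr.dff[25:] = 1.1  # t=2.5 s
        assert rising_slope(tr, 2.0, 2.5) == pytest.approx(2.0)

    def test_flat_trace_zero_slope(self):
        tr = make_trace(np.full(50, 0.3))
        assert rising_slope(tr, 1.0, 2.0) == 0.0

    def test_kernel_transient_matches_finite_difference(self):
        dff = transient_dff(100, 50, 1.0)
        tr = make_trace(dff)
        t_on, t_pk = 5.0, 5.1
        expected = (dff[51] - dff[50]) / 0.1
        assert rising_slope(tr, t_on, t_pk) == pytest.approx(expected)

    def test_reversed_times_error(self):
        tr = make_trace(np.zeros(50))
        with pytest.raises(ValueError):
            rising_slope(tr, 2.0, 1.0)


class TestOnsetPeakDetect:
    def test_clean_transient_onset_within_one_frame(self):
        dff = transient_dff(100, 52, 0.5)
        tr = make_trace(dff)
        t_on, t_pk = onset_peak_detect(tr, 5.0)
        assert abs(t_on - 5.2) <= 1.0 / RATE + 1e-9
        assert t_pk >= t_on

    def test_flat_trace_raises(self):
        with pytest.raises(ValueError, match="no transient"):
            onset_peak_detect(make_trace(np.zeros(100)), 5.0)

    def test_first_of_two_transients_selected(self):
        dff = transient_dff(200, 55, 0.5) + transient_dff(200, 75, 0.8)
        t_on, _ = onset_peak_detect(make_trace(dff), 5.0)
        assert abs(t_on - 5.5) <= 1.0 / RATE + 1e-9


class TestEpisodeRecruitment:
    def _episode(self, start=5.0, end=5.5):
        return Episode(bout_id=0, start_s=start, end_s=end, label="forward")

    def test_6sigma_transient_recruited(self):
        tr = make_trace(transient_dff(120, 52, 6 * 0.02))
        act = episode_recruitment(tr, self._episode())
        assert act.recruited

    def test_plateau_equal_to_max_not_recruited(self):
        tr = make_trace(np.full(120, 0.5))
        act = episode_recruitment(tr, self._episode())
        assert act.corrected_max_dff == pytest.approx(0.0)
        assert not act.recruited

    def test_batch_matches_hand_oracle(self, rng):
        sigma = 0.03
        for _ in range(30):
            dff = rng.normal(0, sigma, 150) + transient_dff(150, 60, float(rng.uniform(0, 0.4)))
            tr = make_trace(dff, noise_sigma=sigma)
            ep = self._episode(6.0, 6.4)
            act = episode_recruitment(tr, ep)
            t = tr.t_s
            win = dff[(t >= 5.5) & (t < 8.4)]
            base = np.median(dff[(t >= 5.7) & (t < 6.0)])
            oracle = win.max() - base
            assert act.corrected_max_dff == pytest.approx(oracle)
            assert act.recruited == (oracle >= 5 * sigma)


class TestForwardActivityIndex:
    def _traces(self, amp_f, amp_s):
        # forward episodes at 5 s and 15 s, struggle at 25 s and 35 s
        dff = (
            transient_dff(500, 52, amp_f)
            + transient_dff(500, 152, amp_f)
            + transient_dff(500, 252, amp_s)
            + transient_dff(500, 352, amp_s)
        )
        fw = [Episode(0, 5.0, 5.5, "forward"), Episode(1, 15.0, 15.5, "forward")]
        st = [Episode(2, 25.0, 25.5, "struggle"), Episode(3, 35.0, 35.5, "struggle")]
        return make_trace(dff), fw, st

    def test_forward_only_gives_one(self):
        tr, fw, st = self._traces(1.0, 0.0)
        # a tiny residual of the decaying forward transients reaches the
        # struggle windows, so the index sits just below the ideal 1.0
        assert forward_activity_index(tr, fw, st) == pytest.approx(1.0, abs=0.01)

    def test_equal_amplitudes_give_zero(self):
        tr, fw, st = self._traces(0.5, 0.5)
        assert forward_activity_index(tr, fw, st) == pytest.approx(0.0, abs=0.02)

    def test_three_to_one_ratio_gives_half(self):
        tr, fw, st = self._traces(0.3, 0.1)
        assert forward_activity_index(tr, fw, st) == pytest.approx(0.5, abs=0.02)

    def test_antisymmetric_under_class_swap(self):
        tr, fw, st = self._traces(0.4, 0.15)
        a = forward_activity_index(tr, fw, st)
        b = forward_activity_index(tr, st, fw)
        assert a == pytest.approx(-b)


class TestClusterForward:
    def _population(self, rng, n_fwd=6, n_str=6, noise=0.05):
        fw = [Episode(0, 5.0, 5.5, "forward"), Episode(1, 15.0, 15.5, "forward")]
        st = [Episode(2, 25.0, 25.5, "struggle"), Episode(3, 35.0, 35.5, "struggle")]
        fwd_motif = transient_dff(500, 52, 1.0) + transient_dff(500, 152, 1.0)
        str_motif = transient_dff(500, 252, 1.0) + transient_dff(500, 352, 1.0)
        traces = []
        for i in range(n_fwd):
            traces.append(make_trace(fwd_motif + rng.normal(0, noise, 500), roi_id=i))
        for i in range(n_str):
            traces.append(make_trace(str_motif + rng.normal(0, noise, 500), roi_id=n_fwd + i))
        return traces, fw, st

    def test_planted_motifs_separate_at_k2(self, rng):
        traces, fw, st = self._population(rng)
        labels, fwd_id, fai = cluster_forward(traces, fw, st, n_clusters=2)
        assert set(labels[:6]) == {fwd_id}
        assert fwd_id not in set(labels[6:])
        assert np.all(fai[:6] > 0) and np.all(fai[6:] < 0)

    def test_partition_invariant_to_roi_order(self, rng):
        traces, fw, st = self._population(rng)
        labels, _, _ = cluster_forward(traces, fw, st, n_clusters=2)
        perm = rng.permutation(len(traces))
        labels2, _, _ = cluster_forward([traces[i] for i in perm], fw, st, n_clusters=2)
        # same partition up to label renaming
        for i in range(len(traces)):
            for j in range(len(traces)):
                same1 = labels[perm[i]] == labels[perm[j]]
                same2 = labels2[i] == labels2[j]
                assert same1 == same2

    def test_constant_row_rejected(self, rng):
        traces, fw, st = self._population(rng)
        traces[0].dff = np.full(500, 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            cluster_forward(traces, fw, st, n_clusters=2)
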