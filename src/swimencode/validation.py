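"""Closed-loop validation experiments against synthetic ground truth.

Each function generates data with :mod:`swimencode.synthgen`, runs the
corresponding analysis stage, scores it against the generator's ground truth
(or an independent brute-force oracle) and returns summary rates.  These
drivers back both the validation test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from . import synthgen
from .fluo import infer_spike_rate
from .kinematics import (
    StimTrial,
    classify_bout,
    extract_bouts,
    forward_index,
    segment_episodes,
    site_median_forward_index,
)
from .kinematics import Episode
from .recruitment import classify_reliability, detect_pulse_response
from .regression import fit_encoding_model, permutation_significance

__all__ = [
    "closed_loop_kinematics",
    "forward_index_bruteforce",
    "recruitment_archetype_accuracy",
    "pulse_null_rates",
    "encoding_model_rates",
    "spike_inference_accuracy",
    "bouttype_null_rate",
    "bouttype_group_accuracy",
    "roi_recovery",
    "stim_pipeline_determinism",
]

BOUT_MIX = ("forward", "left_turn", "right_turn", "struggle", "mixed")


def closed_loop_kinematics(
    n_bouts: int = 1000,
    noise_sigma_deg: float = 0.0,
    seed: int = 0,
    chunk: int = 250,
) -> dict[str, float]:
    """Bout classification and episode segmentation vs generator truth.

    Sessions are rendered in chunks of ``chunk`` scheduled bouts; agreement
    requires the detected bout label to equal the scheduled label, and the
    detected episode sequence to match the scheduled one in both labels and
    oscillation counts.
    """
    rng = np.random.default_rng(seed)
    n_lab = n_ep = n_done = 0
    while n_done < n_bouts:
        m = min(chunk, n_bouts - n_done)
        sched = synthgen.make_schedule(m, rng, bout_types=BOUT_MIX)
        trace, truth = synthgen.synth_session(sched, rng, noise_sigma_deg=noise_sigma_deg)
        bouts = extract_bouts(trace)
        if len(bouts) != len(truth.bouts):
            # count mismatch scores every scheduled bout in the chunk wrong
            n_done += m
            continue
        for i, (b, tb) in enumerate(zip(bouts, truth.bouts)):
            n_lab += b.label == tb.label
            eps = segment_episodes(b, bout_id=i)
            te = tb.episodes
            n_ep += len(eps) == len(te) and all(
                e.label == x.label and e.n_oscillations == x.n_oscillations
                for e, x in zip(eps, te)
            )
        n_done += m
    return {
        "label_agreement_pct": 100.0 * n_lab / n_bouts,
        "episode_agreement_pct": 100.0 * n_ep / n_bouts,
        "n": n_bouts,
    }


def forward_index_bruteforce(n_sets: int = 500, seed: int = 0) -> dict[str, float]:
    """forward_index vs direct counting, and the site median vs a
    hand-filtered median, over random episode multisets / trial sets."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_sets):
        nf, ns = int(rng.integers(0, 10)), int(rng.integers(0, 10))
        if nf + ns == 0:
            nf = 1
        eps = [Episode(0, i, i + 0.1, "forward") for i in range(nf)]
        eps += [Episode(0, 100 + i, 100.1 + i, "struggle") for i in range(ns)]
        order = rng.permutation(len(eps))
        eps = [eps[i] for i in order]
        exact += forward_index(eps) == (nf - ns) / (nf + ns)

    site_exact = 0
    for _ in range(n_sets):
        trials = []
        for _ in range(int(rng.integers(1, 12))):
            freq = float(rng.choice([5.0, 10.0, 20.0]))
            ua = float(rng.uniform(0.5, 3.0))
            fi = float(rng.uniform(-1, 1))
            trials.append((StimTrial(0.0, 1.0, freq, ua), fi))
        oracle = [fi for t, fi in trials if t.pulse_freq_hz == 10.0 and 1.0 <= t.intensity_ua <= 2.0]
        got = site_median_forward_index(trials)
        if oracle:
            site_exact += got == float(np.median(oracle))
        else:
            site_exact += bool(np.isnan(got))
    return {
        "forward_index_exact_rate": exact / n_sets,
        "site_median_exact_rate": site_exact / n_sets,
        "n": n_sets,
    }


def _single_pulse_trials(intensities=(1.0, 2.0, 3.0, 4.0, 5.0), period_s=20.0):
    return [
        StimTrial(10.0 + period_s * i, 10.002 + period_s * i, 1.0, ua, stim_id=i)
        for i, ua in enumerate(intensities)
    ]


def recruitment_archetype_accuracy(n_neurons: int = 200, seed: int = 0) -> dict[str, float]:
    """Reliability classification of noise-free planted archetypes."""
    rng = np.random.default_rng(seed)
    trials = _single_pulse_trials()
    archetypes = []
    expected = []
    for _ in range(n_neurons):
        kind = rng.choice(["reliable", "unreliable", "non"])
        if kind == "reliable":
            thr = float(rng.integers(1, 6))
            archetypes.append({"kind": "stim_reliable", "threshold_ua": thr})
            expected.append(("reliable", thr))
        elif kind == "unreliable":
            # a response pattern with a hole above the first response
            respond_at = sorted(rng.choice([1.0, 2.0, 3.0, 4.0, 5.0], 3, replace=False))
            while respond_at[-1] - respond_at[0] == 2.0:  # contiguous block = step
                respond_at = sorted(rng.choice([1.0, 2.0, 3.0, 4.0, 5.0], 3, replace=False))
            archetypes.append({"kind": "stim_unreliable", "respond_at": respond_at})
            expected.append(("unreliable", None))
        else:
            archetypes.append({"kind": "non_recruited"})
            expected.append(("non_recruited", None))
    truth = synthgen.GroundTruth(seed=seed, stim_trials=trials)
    traces = synthgen.synth_neurons(truth, archetypes, rng, duration_s=120.0, noise_sigma_dff=0.0)
    correct = 0
    for fl, (exp_label, exp_thr) in zip(traces, expected):
        from .fluo import estimate_noise, neuropil_correct_and_dff

        fl.dff, fl.f0 = neuropil_correct_and_dff(
            fl.f_raw, fl.f_neuropil, 0.7, inactivity_interval=(0, 30)
        )
        fl.noise_sigma = estimate_noise(fl.dff, (0, 30), fl.rate_hz)
        per_int = []
        for tr in trials:
            pr = detect_pulse_response(fl, tr.train_start_s, intensity_ua=tr.intensity_ua)
            per_int.append((tr.intensity_ua, [pr.responded]))
        lab = classify_reliability(per_int, roi_id=fl.roi_id)
        ok = lab.label == exp_label
        if exp_label == "reliable":
            ok = ok and lab.threshold_intensity_ua == exp_thr
        correct += ok
    return {"accuracy_pct": 100.0 * correct / n_neurons, "n": n_neurons}


def pulse_null_rates(
    n_traces: int = 1000, n_mc: int = 20000, sigma: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Observed per-pulse responded rate on pure-noise traces vs the
    Monte-Carlo exceedance probability of the 3σ windowed-max rule."""
    rng = np.random.default_rng(seed)
    rate = 10.0
    n = 100
    hits = 0
    for _ in range(n_traces):
        from .fluo import FluoTrace

        dff = rng.normal(0, sigma, n)
        fl = FluoTrace(0, np.arange(n) / rate, np.zeros(n), np.zeros(n), rate)
        fl.dff = dff
        fl.noise_sigma = sigma
        hits += detect_pulse_response(fl, 5.0).responded
    observed = hits / n_traces

    rng2 = np.random.default_rng(seed + 10_000)
    x = rng2.normal(0, sigma, (n_mc, n))
    base = x[:, 35:50].mean(axis=1)
    mc = float(np.mean(x[:, 50:80].max(axis=1) > base + 3 * sigma))
    half_ci = 1.96 * np.sqrt(mc * (1 - mc) / n_traces)
    return {
        "observed_rate": observed,
        "mc_rate": mc,
        "within_binomial_ci": float(abs(observed - mc) <= half_ci + 1e-12),
        "n": n_traces,
    }


def _smooth_design(rng, n):
    x = lfilter([1.0], [1.0, -0.85], rng.normal(0, 1, (n, 4)), axis=0)
    return (x - x.mean(axis=0)) / x.std(axis=0)


def encoding_model_rates(
    n_planted: int = 200,
    n_null: int = 500,
    n_frames: int = 3000,
    n_perm: int = 199,
    seed: int = 0,
) -> dict[str, float]:
    """Power on planted iTBF coupling (α3 = 0.5·σ_dff) and type-I rate on
    null neurons, both with circular-shift permutation significance."""
    rng = np.random.default_rng(seed)
    x = _smooth_design(rng, n_frames)
    power_hits = 0
    for i in range(n_planted):
        dff = 1.0 * x[:, 2] + rng.normal(0, np.sqrt(3.0), n_frames)  # alpha3 = 0.5*sigma_dff
        fit = fit_encoding_model(dff, x)
        fit = permutation_significance(dff, x, fit, n_perm=n_perm, seed=seed + 1000 + i)
        power_hits += bool(fit.significant[2])
    null_hits = null_tests = 0
    for i in range(n_null):
        dff = lfilter([1.0], [1.0, -0.85], rng.normal(0, 1, n_frames))
        fit = fit_encoding_model(dff, x)
        fit = permutation_significance(dff, x, fit, n_perm=n_perm, seed=seed + 50_000 + i)
        null_hits += int(fit.significant.sum())
        null_tests += 4
    return {
        "power_rate": power_hits / n_planted,
        "null_sig_rate": null_hits / null_tests,
        "n_planted": n_planted,
        "n_null": n_null,
    }


def spike_inference_accuracy(n_traces: int = 100, seed: int = 0) -> dict[str, float]:
    """Noise-free single-kernel transients: fraction of inferred mass within
    one frame of the true spike."""
    rng = np.random.default_rng(seed)
    rate, decay, n = 10.0, 1.8, 300
    gamma = np.exp(-1 / (decay * rate))
    ok = 0
    for _ in range(n_traces):
        j = int(rng.integers(10, n - 10))
        spikes = np.zeros(n)
        spikes[j] = float(rng.uniform(0.3, 2.0))
        dff = lfilter([1.0], [1.0, -gamma], spikes)
        r = infer_spike_rate(dff, decay, rate)
        ok += r[j - 1 : j + 2].sum() >= 0.90 * r.sum()
    return {"mass_within_1_frame_rate": ok / n_traces, "n": n_traces}


def bouttype_null_rate(n_neurons: int = 1000, seed: int = 0) -> dict[str, float]:
    """Type-I error of the bout-activity rank-sum rule on null neurons whose
    bout and rest spike rates come from one distribution."""
    from .bouttype import _rank_sum_greater

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_neurons):
        pooled = rng.gamma(1.0, 0.3, 260)
        hits += _rank_sum_greater(pooled[:60], pooled[60:]) < 0.01
    return {"false_positive_rate": hits / n_neurons, "n": n_neurons}


def bouttype_group_accuracy(seed: int = 0, n_copies: int = 5) -> dict[str, float]:
    """Exact recovery of planted forward-component / steering archetypes."""
    from .pipeline import RunConfig, run_bouttype_pipeline

    rng = np.random.default_rng(seed)
    sched = synthgen.make_schedule(60, rng)
    trace, truth = synthgen.synth_session(sched, rng, noise_sigma_deg=0.5)
    kinds = ["forward_component", "left_steering", "right_steering", "null"] * n_copies
    arch = [{"kind": k} for k in kinds]
    fluo_traces = synthgen.synth_neurons(truth, arch, rng, duration_s=trace.time_s[-1])
    cfg = RunConfig(seed=seed)
    cfg.fluo.spike_solver = "ar"
    res = run_bouttype_pipeline(trace, fluo_traces, cfg)
    expected = ["forward_component", "left_steering", "right_steering", "other"] * n_copies
    got = list(res["labels"].group)
    acc = float(np.mean([g == e for g, e in zip(got, expected)]))
    return {"group_accuracy_pct": 100.0 * acc, "n": len(kinds)}


def roi_recovery(seed: int = 0) -> dict[str, float]:
    """Two planted 12-µm² disks recovered; a pure-noise movie yields none."""
    from .fluo import segment_rois_by_correlation

    rng = np.random.default_rng(seed)
    movie, planted = synthgen.synth_pixel_movie([((10, 10), 12.0), ((30, 30), 12.0)], rng)
    rois = segment_rois_by_correlation(movie)
    overlaps = [
        max(len(set(roi.pixels) & p) / len(p) for p in planted) for roi in rois
    ] or [0.0]
    noise_movie, _ = synthgen.synth_pixel_movie([], rng, shape=(30, 30), n_frames=400)
    n_noise = len(segment_rois_by_correlation(noise_movie))
    return {
        "n_rois": len(rois),
        "min_overlap_pct": 100.0 * min(overlaps),
        "noise_roi_count": n_noise,
    }


def stim_pipeline_determinism(seed: int = 0) -> dict[str, float]:
    """Two pipeline runs with identical config + seed are byte-identical."""
    import copy
    import tempfile
    from pathlib import Path

    from .kinematics import TailTrace
    from .pipeline import RunConfig, run_stim_pipeline, write_outputs

    rng = np.random.default_rng(seed)
    trials = _single_pulse_trials()
    t = np.arange(0, 120, 1 / 300.0)
    trace = TailTrace(t, np.zeros(t.size))
    truth = synthgen.GroundTruth(seed=seed, stim_trials=trials)
    arch = [
        {"kind": "stim_reliable", "threshold_ua": 3.0},
        {"kind": "stim_unreliable", "respond_at": [2.0, 4.0, 5.0]},
        {"kind": "non_recruited"},
    ]
    fluo_traces = synthgen.synth_neurons(truth, arch, rng, duration_s=120.0, noise_sigma_dff=0.01)
    identical = True
    with tempfile.TemporaryDirectory() as td:
        dirs = [Path(td) / "a", Path(td) / "b"]
        for d in dirs:
            res = run_stim_pipeline(trace, copy.deepcopy(fluo_traces), trials, RunConfig(seed=seed))
            write_outputs(res, d)
        for f1 in sorted(dirs[0].iterdir()):
            if f1.read_bytes() != (dirs[1] / f1.name).read_bytes():
                identical = False
    return {"byte_identical": float(identical)}
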