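"""Synthetic sessions with known ground truth.

Generates tail-angle traces built from scheduled bouts (forward, turns,
struggles, mixed forward/struggle chains and long stimulation-evoked forward
episodes), stimulation trains, and GCaMP-like calcium traces produced by
convolving archetype-driven spikes with an exponential kernel, adding
neuropil contamination and Gaussian noise.  Every output ships a
:class:`GroundTruth` record so each analysis stage has an independent
oracle.

Defaults emulate the study conditions: behavior at 300 Hz, imaging at 10 Hz,
forward tail-beat frequency centered near 17 Hz with amplitudes well below
the 25° classification bound, turn bends of 25–60°, struggles above 25° at
6–10 Hz, bout durations of a few hundred milliseconds, and indicator decays
of 1.5 s (regressors) / 1.8 s (deconvolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .fluo import FluoTrace, PixelMovie
from .kinematics import Bend, StimTrial, TailTrace

__all__ = [
    "TrueBout",
    "TrueEpisode",
    "GroundTruth",
    "synth_bout",
    "make_schedule",
    "synth_session",
    "synth_neurons",
    "synth_pixel_movie",
]

BEHAVIOR_RATE_HZ = 300.0
IMAGING_RATE_HZ = 10.0
DEFAULT_FORWARD_TBF_HZ = 17.0
CA_DECAY_S = 1.8


@dataclass
class TrueEpisode:
    label: str  # "forward" | "struggle"
    start_s: float
    end_s: float
    n_oscillations: int


@dataclass
class TrueBout:
    bout_type: str  # forward | left_turn | right_turn | struggle | mixed | evoked_forward
    label: str  # expected classify_bout label
    start_s: float
    duration_s: float
    tbf_hz: float
    max_tba_deg: float
    n_oscillations: int
    bend_times_s: np.ndarray
    bend_amps_deg: np.ndarray
    episodes: list[TrueEpisode] = field(default_factory=list)
    evoked: bool = False
    stim_id: int | None = None


@dataclass
class GroundTruth:
    seed: int
    bouts: list[TrueBout] = field(default_factory=list)
    stim_trials: list[StimTrial] = field(default_factory=list)
    neurons: list[dict[str, Any]] = field(default_factory=list)
    noise_sigma_deg: float = 0.0
    config: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# bout synthesis


def _half_cycle_segment(
    amps: np.ndarray,
    half_dur_s: np.ndarray,
    rate_hz: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a bend sequence as concatenated half-sine half-cycles.

    Half-cycle k spans ``half_dur_s[k]`` and peaks at ``amps[k]`` at its
    midpoint, which is the ground-truth bend time.  Returns (angle samples,
    bend times within the segment, bend amplitudes).
    """
    dt = 1.0 / rate_hz
    t_edges = np.concatenate([[0.0], np.cumsum(half_dur_s)])
    total = t_edges[-1]
    t = np.arange(0.0, total, dt)
    angle = np.zeros_like(t)
    for k, amp in enumerate(amps):
        sel = (t >= t_edges[k]) & (t < t_edges[k + 1])
        angle[sel] = amp * np.sin(np.pi * (t[sel] - t_edges[k]) / half_dur_s[k])
    bend_times = (t_edges[:-1] + t_edges[1:]) / 2.0
    return angle, bend_times, np.asarray(amps, dtype=float)


def synth_bout(
    bout_type: str,
    rng: np.random.Generator,
    tbf_hz: float | None = None,
    amp_deg: float | None = None,
    n_osc: int | None = None,
    turn_bend_deg: float | None = None,
    rate_hz: float = BEHAVIOR_RATE_HZ,
) -> tuple[np.ndarray, TrueBout]:
    """Synthesize one bout's tail-angle segment plus its truth record.

    forward: alternating bends, amplitude < 25° with a mild decay envelope,
    ≥ 3 oscillations, TBF in 15–30 Hz.  left/right turn: a signed initial
    bend of 25–60° followed by a forward component.  struggle: alternating
    bends above 25° at 6–10 Hz.  Raises on contradictory parameters.
    """
    if bout_type in ("forward", "evoked_forward"):
        f = tbf_hz if tbf_hz is not None else float(rng.uniform(15.0, 22.0))
        a = amp_deg if amp_deg is not None else float(rng.uniform(10.0, 21.0))
        n = n_osc if n_osc is not None else int(rng.integers(3, 8))
        if a >= 25.0:
            raise ValueError("forward bout amplitude must be below 25 degrees")
        if n < 3:
            raise ValueError("forward bout needs at least 3 oscillations")
        env = np.linspace(1.0, 0.65, 2 * n)
        amps = a * env * np.where(np.arange(2 * n) % 2 == 0, 1.0, -1.0)
        half = np.full(2 * n, 1.0 / (2 * f))
        angle, bt, ba = _half_cycle_segment(amps, half, rate_hz)
        label = "forward"
    elif bout_type in ("left_turn", "right_turn"):
        f = tbf_hz if tbf_hz is not None else float(rng.uniform(15.0, 22.0))
        a = amp_deg if amp_deg is not None else float(rng.uniform(10.0, 21.0))
        n = n_osc if n_osc is not None else int(rng.integers(3, 7))
        b = turn_bend_deg if turn_bend_deg is not None else float(rng.uniform(30.0, 55.0))
        if not 25.0 < b <= 60.0:
            raise ValueError("turn bend must be in (25, 60] degrees")
        sign = 1.0 if bout_type == "left_turn" else -1.0
        env = np.linspace(1.0, 0.65, 2 * n)
        fwd = a * env * np.where(np.arange(2 * n) % 2 == 0, -sign, sign)
        amps = np.concatenate([[sign * b], fwd])
        half = np.full(2 * n + 1, 1.0 / (2 * f))
        angle, bt, ba = _half_cycle_segment(amps, half, rate_hz)
        label = bout_type
    elif bout_type == "struggle":
        f = tbf_hz if tbf_hz is not None else float(rng.uniform(6.0, 10.0))
        a = amp_deg if amp_deg is not None else float(rng.uniform(32.0, 55.0))
        n_bends = 2 * (n_osc if n_osc is not None else int(rng.integers(1, 3)))
        if a <= 25.0:
            raise ValueError("struggle bends must exceed 25 degrees")
        if n_bends < 2:
            raise ValueError("struggle needs at least 2 bends")
        sign0 = float(rng.choice([1.0, -1.0]))
        # decaying envelope keeps the first bend strictly largest (no side tie)
        env = np.linspace(1.0, 0.85, n_bends)
        amps = a * env * sign0 * np.where(np.arange(n_bends) % 2 == 0, 1.0, -1.0)
        half = np.full(n_bends, 1.0 / (2 * f))
        angle, bt, ba = _half_cycle_segment(amps, half, rate_hz)
        label = "discarded" if a > 60.0 else "struggle"
    else:
        raise ValueError(f"unknown bout type {bout_type!r}")

    n_osc_true = len(ba) // 2
    episodes = _true_episodes(bout_type, bt, ba)
    truth = TrueBout(
        bout_type=bout_type,
        label=label if bout_type != "struggle" else _struggle_bout_label(ba),
        start_s=0.0,
        duration_s=float(angle.size / rate_hz),
        tbf_hz=f,
        max_tba_deg=float(np.max(np.abs(ba))),
        n_oscillations=n_osc_true,
        bend_times_s=bt,
        bend_amps_deg=ba,
        episodes=episodes,
    )
    return angle, truth


def _struggle_bout_label(amps: np.ndarray) -> str:
    mx = float(np.max(np.abs(amps)))
    if mx > 60.0:
        return "discarded"
    peak = amps[np.argmax(np.abs(amps))]
    return "left_turn" if peak > 0 else "right_turn"


def _true_episodes(bout_type: str, bt: np.ndarray, ba: np.ndarray) -> list[TrueEpisode]:
    """Episode ground truth implied by construction (bend-time boundaries)."""
    large = np.abs(ba) > 25.0
    if bout_type in ("forward", "evoked_forward"):
        return [TrueEpisode("forward", float(bt[0]), float(bt[-1]), len(ba) // 2)]
    if bout_type == "struggle":
        return [TrueEpisode("struggle", float(bt[0]), float(bt[-1]), len(ba) // 2)]
    if bout_type in ("left_turn", "right_turn"):
        # initial large bend -> 1-bend struggle episode; remainder forward
        return [
            TrueEpisode("struggle", float(bt[0]), float(bt[0]), 0),
            TrueEpisode("forward", float(bt[1]), float(bt[-1]), (len(ba) - 1) // 2),
        ]
    raise ValueError(bout_type)


# ---------------------------------------------------------------------------
# session synthesis


def make_schedule(
    n_bouts: int,
    rng: np.random.Generator,
    bout_types: tuple[str, ...] = ("forward", "left_turn", "right_turn", "struggle"),
    type_probs: tuple[float, ...] | None = None,
    gap_range_s: tuple[float, float] = (0.6, 1.8),
    start_s: float = 6.0,
) -> list[tuple[str, float]]:
    """Random non-overlapping schedule of (bout_type, start_s).

    The first ``start_s`` seconds are kept quiet so preprocessing always has
    an inactivity period for baseline and noise estimation.
    """
    t = start_s
    sched = []
    for _ in range(n_bouts):
        bt = str(rng.choice(bout_types, p=type_probs))
        sched.append((bt, t))
        t += 1.0 + float(rng.uniform(*gap_range_s))  # generous slot per bout
    return sched


def synth_session(
    schedule: list[tuple[str, float]],
    rng: np.random.Generator,
    stim_trains: list[StimTrial] | None = None,
    noise_sigma_deg: float = 0.0,
    rate_hz: float = BEHAVIOR_RATE_HZ,
    pad_s: float = 6.0,
    bout_params: dict[str, Any] | None = None,
) -> tuple[TailTrace, GroundTruth]:
    """Render a full tail-angle session from a bout schedule.

    ``schedule`` entries are ``(bout_type, start_s)``; "mixed" renders a
    forward segment chained with a struggle segment inside one bout, and
    "evoked_forward" a long forward episode (placed inside a train when the
    schedule start falls within one).  Bouts must not overlap.
    """
    stim_trains = stim_trains or []
    bout_params = bout_params or {}
    segments: list[tuple[float, np.ndarray, TrueBout]] = []
    last_end = -np.inf
    for bout_type, t0 in sorted(schedule, key=lambda s: s[1]):
        if bout_type == "mixed":
            angle, truth = _synth_mixed_bout(rng, rate_hz, **bout_params.get("mixed", {}))
        elif bout_type == "evoked_forward":
            params = dict(bout_params.get("evoked_forward", {}))
            params.setdefault("n_osc", int(rng.integers(60, 120)))  # seconds-long
            angle, truth = synth_bout("forward", rng, rate_hz=rate_hz, **params)
            truth.bout_type = "evoked_forward"
        else:
            angle, truth = synth_bout(
                bout_type, rng, rate_hz=rate_hz, **bout_params.get(bout_type, {})
            )
        if t0 < last_end:
            raise ValueError("overlapping schedule")
        last_end = t0 + truth.duration_s
        segments.append((t0, angle, truth))

    total_s = (last_end if segments else 0.0) + pad_s
    n = int(round(total_s * rate_hz))
    t = np.arange(n) / rate_hz
    angle_full = np.zeros(n)
    truth_bouts: list[TrueBout] = []
    for t0, angle, truth in segments:
        i0 = int(round(t0 * rate_hz))
        angle_full[i0 : i0 + angle.size] = angle
        shift = t[i0]
        truth.start_s = float(shift)
        truth.bend_times_s = truth.bend_times_s + shift
        for ep in truth.episodes:
            ep.start_s += shift
            ep.end_s += shift
        for tr in stim_trains:
            if tr.train_start_s <= truth.start_s < tr.train_end_s:
                truth.evoked = True
                truth.stim_id = tr.stim_id
        truth_bouts.append(truth)
    if noise_sigma_deg > 0:
        angle_full = angle_full + rng.normal(0.0, noise_sigma_deg, size=n)

    seed_val = int(rng.integers(0, 2**31 - 1))
    trace = TailTrace(time_s=t, angle_deg=angle_full, rate_hz=rate_hz)
    truth = GroundTruth(
        seed=seed_val,
        bouts=truth_bouts,
        stim_trials=stim_trains,
        noise_sigma_deg=noise_sigma_deg,
        config={"rate_hz": rate_hz, "n_bouts": len(truth_bouts)},
    )
    return trace, truth


def _synth_mixed_bout(
    rng: np.random.Generator,
    rate_hz: float,
    intra_gap_s: float = 0.05,
) -> tuple[np.ndarray, TrueBout]:
    """Forward segment chained with a struggle segment inside one bout."""
    a1, t1 = synth_bout("forward", rng, rate_hz=rate_hz)
    a2, t2 = synth_bout("struggle", rng, rate_hz=rate_hz)
    gap = np.zeros(int(round(intra_gap_s * rate_hz)))
    angle = np.concatenate([a1, gap, a2])
    off = (a1.size + gap.size) / rate_hz
    bt = np.concatenate([t1.bend_times_s, t2.bend_times_s + off])
    ba = np.concatenate([t1.bend_amps_deg, t2.bend_amps_deg])
    episodes = [
        TrueEpisode("forward", float(t1.bend_times_s[0]), float(t1.bend_times_s[-1]), t1.n_oscillations),
        TrueEpisode(
            "struggle",
            float(t2.bend_times_s[0] + off),
            float(t2.bend_times_s[-1] + off),
            t2.n_oscillations,
        ),
    ]
    truth = TrueBout(
        bout_type="mixed",
        label=_struggle_bout_label(ba),
        start_s=0.0,
        duration_s=float(angle.size / rate_hz),
        tbf_hz=t1.tbf_hz,
        max_tba_deg=float(np.max(np.abs(ba))),
        n_oscillations=len(ba) // 2,
        bend_times_s=bt,
        bend_amps_deg=ba,
        episodes=episodes,
    )
    return angle, truth


# ---------------------------------------------------------------------------
# neuron synthesis


def _ca_kernel_conv(spikes: np.ndarray, decay_s: float, rate_hz: float) -> np.ndarray:
    from scipy.signal import lfilter

    gamma = float(np.exp(-1.0 / (decay_s * rate_hz)))
    return lfilter([1.0], [1.0, -gamma], spikes)


def _frame_itbf(truth: GroundTruth, frame_times: np.ndarray) -> np.ndarray:
    """Frame-level iTBF from ground-truth bend times (generator-internal)."""
    dt = float(np.median(np.diff(frame_times)))
    out = np.zeros(frame_times.size)
    counts = np.zeros(frame_times.size)
    for b in truth.bouts:
        t = b.bend_times_s
        if t.size < 3:
            continue
        mids = (t[2:] + t[:-2]) / 2.0
        vals = 1.0 / (t[2:] - t[:-2])
        idx = np.floor((mids - frame_times[0]) / dt).astype(int)
        ok = (idx >= 0) & (idx < out.size)
        np.add.at(out, idx[ok], vals[ok])
        np.add.at(counts, idx[ok], 1.0)
    nz = counts > 0
    out[nz] /= counts[nz]
    return out


def synth_neurons(
    truth: GroundTruth,
    archetypes: list[dict[str, Any]],
    rng: np.random.Generator,
    duration_s: float,
    imaging_rate_hz: float = IMAGING_RATE_HZ,
    decay_s: float = CA_DECAY_S,
    noise_sigma_dff: float = 0.03,
    f0: float = 100.0,
    neuropil_scale: float = 20.0,
) -> list[FluoTrace]:
    """Generate calcium traces for a population of archetype neurons.

    Each archetype dict has ``kind`` plus parameters.  Kinds: ``null``
    (constant-rate Poisson events), ``itbf_coder`` (spike amplitude ∝ frame
    iTBF), ``itba_rise_coder``, ``oscillation_counter`` (one event per
    forward episode with amplitude ∝ ln(n_oscillations)), ``forward_component``,
    ``left_steering``, ``right_steering``, ``stim_reliable`` (with
    ``threshold_ua``), ``stim_unreliable`` (with ``respond_at`` intensity
    list), ``non_recruited``.  Calcium = spikes ∗ exp(−t/decay), F = F0·(1 +
    ΔF/F) + 0.7·neuropil + noise; the measured neuropil channel is stored so
    the standard correction with factor 0.7 recovers the clean trace.  The
    true couplings, spike vectors and noise σ are appended to
    ``truth.neurons``.
    """
    nf = int(round(duration_s * imaging_rate_hz))
    frame_times = np.arange(nf) / imaging_rate_hz
    dt = 1.0 / imaging_rate_hz
    itbf = _frame_itbf(truth, frame_times)
    traces: list[FluoTrace] = []
    for roi_id, arch in enumerate(archetypes):
        kind = arch["kind"]
        amp = float(arch.get("amp", 0.5))
        spikes = np.zeros(nf)
        if kind == "null":
            rate = float(arch.get("rate_hz", 0.2))
            spikes = rng.poisson(rate * dt, size=nf) * amp
        elif kind == "itbf_coder":
            gain = float(arch.get("gain", 0.03))
            spikes = gain * itbf
        elif kind == "itba_rise_coder":
            rise = np.zeros(nf)
            for b in truth.bouts:
                i = int(b.start_s / dt)
                if i < nf:
                    rise[i] = 1.0
            spikes = amp * rise
        elif kind == "oscillation_counter":
            gain = float(arch.get("gain", 0.3))
            for b in truth.bouts:
                for ep in b.episodes:
                    if ep.label == "forward" and ep.n_oscillations >= 1:
                        i = int(ep.start_s / dt)
                        if i < nf:
                            spikes[i] += gain * np.log(ep.n_oscillations)
        elif kind in ("forward_component", "left_steering", "right_steering"):
            want = {
                "forward_component": {"forward", "left_turn", "right_turn"},
                "left_steering": {"left_turn"},
                "right_steering": {"right_turn"},
            }[kind]
            for b in truth.bouts:
                if b.label in want:
                    i0 = int(b.start_s / dt)
                    i1 = max(i0 + 1, int((b.start_s + b.duration_s) / dt) + 1)
                    spikes[i0 : min(i1, nf)] += amp
        elif kind == "stim_reliable":
            thr = float(arch["threshold_ua"])
            for tr in truth.stim_trials:
                if tr.intensity_ua >= thr:
                    for pt in tr.pulse_times_s:
                        i = int(pt / dt) + 1
                        if i < nf:
                            spikes[i] += amp
        elif kind == "stim_unreliable":
            respond_at = set(arch.get("respond_at", []))
            for tr in truth.stim_trials:
                if tr.intensity_ua in respond_at:
                    for pt in tr.pulse_times_s:
                        i = int(pt / dt) + 1
                        if i < nf:
                            spikes[i] += amp
        elif kind == "non_recruited":
            pass
        else:
            raise ValueError(f"unknown archetype kind {kind!r}")

        dff_true = _ca_kernel_conv(spikes, decay_s, imaging_rate_hz)
        npil = neuropil_scale * (1.0 + 0.1 * np.sin(2 * np.pi * frame_times / 60.0))
        noise = rng.normal(0.0, noise_sigma_dff * f0, size=nf) if noise_sigma_dff > 0 else 0.0
        f_raw = f0 * (1.0 + dff_true) + 0.7 * npil + noise
        traces.append(
            FluoTrace(
                roi_id=roi_id,
                t_s=frame_times,
                f_raw=f_raw,
                f_neuropil=npil,
                rate_hz=imaging_rate_hz,
            )
        )
        truth.neurons.append(
            {
                "roi_id": roi_id,
                "archetype": dict(arch),
                "spikes": spikes,
                "dff_true": dff_true,
                "noise_sigma_dff": noise_sigma_dff,
                "f0": f0,
            }
        )
    return traces


# ---------------------------------------------------------------------------
# pixel movies


def synth_pixel_movie(
    roi_layout: list[tuple[tuple[int, int], float]],
    rng: np.random.Generator,
    shape: tuple[int, int] = (40, 40),
    n_frames: int = 400,
    rate_hz: float = IMAGING_RATE_HZ,
    pixel_size_um: float = 0.66,
    signal_amp: float = 3.0,
    noise_sigma: float = 1.0,
    event_rate_hz: float = 0.3,
) -> tuple[PixelMovie, list[set[tuple[int, int]]]]:
    """Pixel movie with planted disk ROIs sharing a latent calcium trace.

    ``roi_layout`` is a list of ((row, col) center, target_area_um2).  Each
    planted ROI's pixels show a common event-driven latent trace scaled by
    ``signal_amp`` plus i.i.d. pixel noise; background pixels are pure noise.
    Returns the movie and the planted pixel sets (ground truth).  Raises on
    overlapping layouts.
    """
    h, w = shape
    frames = rng.normal(0.0, noise_sigma, size=(n_frames, h, w))
    planted: list[set[tuple[int, int]]] = []
    used: set[tuple[int, int]] = set()
    for (cr, cc), area_um2 in roi_layout:
        n_px = int(round(area_um2 / pixel_size_um**2))
        rr, ccg = np.mgrid[0:h, 0:w]
        d2 = (rr - cr) ** 2 + (ccg - cc) ** 2
        order = np.argsort(d2.ravel(), kind="stable")
        pix = {divmod(int(i), w) for i in order[:n_px]}
        if pix & used:
            raise ValueError("overlapping layout")
        used |= pix
        events = rng.poisson(event_rate_hz / rate_hz, size=n_frames).astype(float)
        latent = _ca_kernel_conv(events, CA_DECAY_S, rate_hz)
        for r, c in pix:
            frames[:, r, c] += signal_amp * latent
        planted.append(pix)
    return PixelMovie(frames=frames, pixel_size_um=pixel_size_um, rate_hz=rate_hz), planted
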