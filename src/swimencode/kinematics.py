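"""Tail-kinematics segmentation and classification.

Turns a uniformly sampled tail-angle trace (head-embedded larval zebrafish,
behavior camera, default 300 Hz) into tail bends, swim bouts, cycle-level
kinematics (instantaneous tail-beat frequency and amplitude), forward/struggle
episodes, bout class labels and per-trial forward indices.

Sign convention: positive angle = leftward tail deflection, so a turn whose
maximum-magnitude bend is positive is a left turn.  All intervals are
half-open ``[start, end)`` in seconds; the time origin is the first sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, medfilt

__all__ = [
    "TailTrace",
    "Bend",
    "Bout",
    "Episode",
    "StimTrial",
    "detect_bends",
    "extract_bouts",
    "cycle_kinematics",
    "segment_episodes",
    "classify_bout",
    "forward_index",
    "site_median_forward_index",
    "tag_provenance",
]

#: Bout classification thresholds (degrees): below FORWARD_MAX_DEG is a
#: forward swim, between FORWARD_MAX_DEG and DISCARD_DEG a turn, above
#: DISCARD_DEG the bout is discarded as escape/struggle-like.
FORWARD_MAX_DEG = 25.0
DISCARD_DEG = 60.0

#: Struggle episodes split where successive supra-threshold bends are more
#: than this far apart.
STRUGGLE_SPLIT_GAP_S = 0.100

#: Minimum number of full oscillations for a forward episode.
MIN_FORWARD_OSC = 3


@dataclass
class TailTrace:
    """Uniformly sampled signed tail-angle series in degrees."""

    time_s: np.ndarray
    angle_deg: np.ndarray
    rate_hz: float = 300.0
    curvature: np.ndarray | None = None  # (20 segments, n) per-segment angles

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if self.time_s.size == 0:
            raise ValueError("empty input")
        if self.time_s.size != self.angle_deg.size:
            raise ValueError("time and angle length mismatch")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.angle_deg)):
            raise ValueError("angle must be finite everywhere")
        if self.time_s.size > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-9:
                raise ValueError("non-uniform sampling")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz


@dataclass(frozen=True)
class Bend:
    """One tail-bend: the signed extremum of a half-cycle."""

    t_s: float
    amp_deg: float


@dataclass
class Bout:
    """A discrete event during which the tail is continuously moving."""

    start_s: float
    end_s: float
    bends: list[Bend] = field(default_factory=list)
    label: str = "unclassified"
    provenance: str = "spontaneous"
    stim_id: int | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_oscillations(self) -> int:
        return len(self.bends) // 2

    @property
    def max_abs_tba_deg(self) -> float:
        if not self.bends:
            return 0.0
        return max(abs(b.amp_deg) for b in self.bends)

    @property
    def median_itbf_hz(self) -> float:
        itbf, _, _ = cycle_kinematics(self.bends)
        return float(np.median(itbf)) if itbf.size else float("nan")

    @property
    def median_itba_deg(self) -> float:
        _, itba, _ = cycle_kinematics(self.bends)
        return float(np.median(itba)) if itba.size else float("nan")


@dataclass
class Episode:
    """A sub-segment of a bout labeled forward swim or escape/struggle."""

    bout_id: int
    start_s: float
    end_s: float
    label: str  # "forward" | "struggle"
    bends: list[Bend] = field(default_factory=list)
    #: indices (within ``bends``) of rare supra-threshold bends absorbed into a
    #: forward episode under rule 2; empty for struggle episodes.
    absorbed: list[int] = field(default_factory=list)

    @property
    def n_oscillations(self) -> int:
        return len(self.bends) // 2

    @property
    def max_abs_tba_deg(self) -> float:
        return max(abs(b.amp_deg) for b in self.bends) if self.bends else 0.0

    @property
    def median_itbf_hz(self) -> float:
        itbf, _, _ = cycle_kinematics(self.bends)
        return float(np.median(itbf)) if itbf.size else float("nan")

    @property
    def median_itba_deg(self) -> float:
        _, itba, _ = cycle_kinematics(self.bends)
        return float(np.median(itba)) if itba.size else float("nan")


@dataclass
class StimTrial:
    """One electrical stimulation train (2-ms negative pulses)."""

    train_start_s: float
    train_end_s: float
    pulse_freq_hz: float
    intensity_ua: float
    pulse_width_ms: float = 2.0
    pulse_times_s: np.ndarray | None = None
    stim_id: int = 0

    def __post_init__(self) -> None:
        if self.pulse_times_s is None:
            n = int(np.floor((self.train_end_s - self.train_start_s) * self.pulse_freq_hz)) + 1
            self.pulse_times_s = self.train_start_s + np.arange(n) / self.pulse_freq_hz
        self.pulse_times_s = np.asarray(self.pulse_times_s, dtype=float)
        if np.any(self.pulse_times_s < self.train_start_s - 1e-9) or np.any(
            self.pulse_times_s > self.train_end_s + 1e-9
        ):
            raise ValueError("pulse times outside train window")
        if self.pulse_times_s.size > 1:
            spacing = np.diff(self.pulse_times_s)
            if np.ptp(spacing) > 1e-6 or abs(spacing[0] - 1.0 / self.pulse_freq_hz) > 1e-6:
                raise ValueError("pulse spacing inconsistent with pulse_freq_hz")


# ---------------------------------------------------------------------------
# bend detection


def detect_bends(trace: TailTrace, min_amp_deg: float = 5.0) -> list[Bend]:
    """Detect tail bends as alternating-sign local extrema of the angle trace.

    A 3-sample median filter suppresses single-sample outliers before extremum
    search; extrema below ``min_amp_deg`` in magnitude are discarded and, where
    two consecutive surviving extrema share a sign, only the larger one is
    kept (hysteresis against sub-threshold ripple).
    """
    if min_amp_deg < 0:
        raise ValueError("min_amp_deg must be >= 0")
    x = trace.angle_deg
    if x.size >= 3:
        x = medfilt(x, kernel_size=3)
    peaks, _ = find_peaks(x)
    troughs, _ = find_peaks(-x)
    idx = np.sort(np.concatenate([peaks, troughs]))
    bends: list[Bend] = []
    last_i = -1
    for i in idx:
        amp = float(x[i])
        if abs(amp) < min_amp_deg or amp == 0.0:
            continue
        if bends and np.sign(amp) == np.sign(bends[-1].amp_deg):
            # same-sign ripple within one half-cycle is merged; two genuine
            # same-sign bends (signal crossed zero or returned near baseline
            # in between, e.g. across a quiet gap) are both kept
            between = x[last_i : i + 1]
            returned = np.any(np.sign(between) == -np.sign(amp)) or np.any(
                np.abs(between) < 0.5 * min_amp_deg
            )
            if not returned:
                if abs(amp) > abs(bends[-1].amp_deg):
                    bends[-1] = Bend(float(trace.time_s[i]), amp)
                    last_i = i
                continue
        bends.append(Bend(float(trace.time_s[i]), amp))
        last_i = i
    return bends


# ---------------------------------------------------------------------------
# bout extraction


def extract_bouts(
    trace: TailTrace,
    motion_threshold_deg: float = 3.0,
    min_quiet_s: float = 0.100,
    min_duration_s: float = 0.050,
    min_amp_deg: float = 5.0,
) -> list[Bout]:
    """Extract bouts: maximal intervals of continuous tail motion.

    Intervals where the (median-filtered) absolute angle exceeds
    ``motion_threshold_deg`` are merged when separated by less than
    ``min_quiet_s`` of quiescence; intervals shorter than ``min_duration_s``
    are discarded as tracking noise.  Each bout carries its bends and is
    labeled by :func:`classify_bout`.
    """
    if motion_threshold_deg <= 0 or min_quiet_s <= 0:
        raise ValueError("thresholds must be positive")
    x = trace.angle_deg
    if x.size >= 3:
        x = medfilt(x, kernel_size=3)
    active = np.abs(x) > motion_threshold_deg
    if not np.any(active):
        return []
    # run-length extraction
    d = np.diff(active.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(active.size)
    # merge runs separated by less than min_quiet_s
    gap = int(round(min_quiet_s * trace.rate_hz))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    all_bends = detect_bends(trace, min_amp_deg=min_amp_deg)
    bend_times = np.array([b.t_s for b in all_bends])
    bouts: list[Bout] = []
    for s, e in merged:
        t0 = float(trace.time_s[s])
        t1 = float(trace.time_s[min(e, trace.time_s.size - 1)])
        if e >= trace.time_s.size:
            t1 = float(trace.time_s[-1]) + trace.dt
        if t1 - t0 < min_duration_s:
            continue
        if bend_times.size:
            lo, hi = np.searchsorted(bend_times, [t0, t1])
            bends = all_bends[lo:hi]
        else:
            bends = []
        bout = Bout(start_s=t0, end_s=t1, bends=list(bends))
        bout.label = classify_bout(bout)
        bouts.append(bout)
    return bouts


# ---------------------------------------------------------------------------
# cycle kinematics


def cycle_kinematics(bends: list[Bend]) -> tuple[np.ndarray, np.ndarray, int]:
    """Instantaneous tail-beat frequency/amplitude series and oscillation count.

    A full cycle is two consecutive opposite-sign bends.  The iTBF of cycle
    *i* is the inverse of the same-side bend spacing, ``1/(t_i - t_{i-2})``;
    the iTBA series is ``|amp|`` per bend.  ``n_oscillations`` is
    ``floor(n_bends / 2)``.
    """
    n = len(bends)
    if n < 2:
        return np.array([]), np.array([abs(b.amp_deg) for b in bends]), 0
    t = np.array([b.t_s for b in bends])
    itbf = 1.0 / (t[2:] - t[:-2]) if n >= 3 else np.array([])
    itba = np.array([abs(b.amp_deg) for b in bends])
    return itbf, itba, n // 2


# ---------------------------------------------------------------------------
# episode segmentation


def segment_episodes(
    bout: Bout,
    trace: TailTrace | None = None,
    bout_id: int = 0,
    large_thresh_deg: float = FORWARD_MAX_DEG,
    split_gap_s: float = STRUGGLE_SPLIT_GAP_S,
    min_forward_osc: int = MIN_FORWARD_OSC,
    flank_osc: int = 2,
    max_absorbed_per_osc: float = 1.0 / 6.0,
) -> list[Episode]:
    """Segment a bout into forward-swim and struggle episodes.

    Three rules (applied to the bout's bend sequence):

    1. runs of bends all below ``large_thresh_deg`` with at least
       ``min_forward_osc`` full oscillations become *forward* episodes;
    2. a rare isolated supra-threshold bend flanked by at least ``flank_osc``
       sub-threshold oscillations on each side is absorbed into the
       surrounding forward episode rather than splitting it (at most
       ``max_absorbed_per_osc`` absorbed bends per sub-threshold oscillation);
    3. consecutive supra-threshold bends form one *struggle* episode, split
       into several where successive supra-threshold bends are more than
       ``split_gap_s`` apart.

    Leftover sub-threshold runs too short for rule 1 are merged into the
    temporally nearest episode of the bout; a bout with no episode-forming
    bends yields an empty list.
    """
    bends = bout.bends
    n = len(bends)
    if n == 0:
        return []
    amps = np.array([b.amp_deg for b in bends])
    times = np.array([b.t_s for b in bends])
    large = np.abs(amps) > large_thresh_deg

    # rule 2: absorb isolated supra-threshold bends with enough flanking
    # sub-threshold oscillations on both sides
    absorbed = np.zeros(n, dtype=bool)
    need = 2 * flank_osc  # bends per side
    for i in np.flatnonzero(large):
        if 0 < i < n - 1 and not large[i - 1] and not large[i + 1]:
            left = 0
            j = i - 1
            while j >= 0 and not large[j]:
                left += 1
                j -= 1
            right = 0
            j = i + 1
            while j < n and not large[j]:
                right += 1
                j += 1
            if left >= need and right >= need:
                absorbed[i] = True
    effective_large = large & ~absorbed

    # rule 3: group the remaining supra-threshold bends into struggle episodes
    struggle_groups: list[list[int]] = []
    li = list(np.flatnonzero(effective_large))
    for i in li:
        if struggle_groups:
            prev = struggle_groups[-1][-1]
            n_small_between = int(np.sum(~large[prev + 1 : i]))
            if (times[i] - times[prev]) <= split_gap_s and n_small_between < 2 * min_forward_osc:
                struggle_groups[-1].append(i)
                continue
        struggle_groups.append([i])

    episodes: list[Episode] = []
    for g in struggle_groups:
        idx = list(range(g[0], g[-1] + 1))  # includes intervening small bends
        episodes.append(
            Episode(
                bout_id=bout_id,
                start_s=times[g[0]],
                end_s=times[g[-1]],
                label="struggle",
                bends=[bends[k] for k in idx],
            )
        )

    # rule 1: remaining maximal runs of unassigned bends
    assigned = np.zeros(n, dtype=bool)
    for g in struggle_groups:
        assigned[g[0] : g[-1] + 1] = True
    leftovers: list[list[int]] = []
    i = 0
    while i < n:
        if assigned[i]:
            i += 1
            continue
        j = i
        while j < n and not assigned[j]:
            j += 1
        run = list(range(i, j))
        n_osc = len(run) // 2
        n_abs = int(np.sum(absorbed[i:j]))
        if n_osc >= min_forward_osc and n_abs <= max_absorbed_per_osc * (len(run) - n_abs) / 2.0:
            episodes.append(
                Episode(
                    bout_id=bout_id,
                    start_s=times[i],
                    end_s=times[j - 1],
                    label="forward",
                    bends=[bends[k] for k in run],
                    absorbed=[k - i for k in run if absorbed[k]],
                )
            )
        else:
            leftovers.append(run)
        i = j
    episodes.sort(key=lambda e: e.start_s)

    # merge leftover short runs into the temporally nearest episode
    for run in leftovers:
        if not episodes:
            continue  # dropped from episode accounting
        t0, t1 = times[run[0]], times[run[-1]]
        best = min(
            episodes,
            key=lambda e: min(abs(e.start_s - t1), abs(t0 - e.end_s)),
        )
        merged_bends = sorted(best.bends + [bends[k] for k in run], key=lambda b: b.t_s)
        best.bends = merged_bends
        best.start_s = min(best.start_s, t0)
        best.end_s = max(best.end_s, t1)
        if best.label == "forward":
            base = [k for k, b in enumerate(merged_bends) if abs(b.amp_deg) > large_thresh_deg]
            best.absorbed = base
    episodes.sort(key=lambda e: e.start_s)

    # every forward episode must satisfy the rule-1 contract
    for ep in episodes:
        if ep.label == "forward":
            kept = [b for k, b in enumerate(ep.bends) if k not in set(ep.absorbed)]
            assert all(abs(b.amp_deg) <= large_thresh_deg for b in kept)
            assert ep.n_oscillations >= min_forward_osc
    return episodes


# ---------------------------------------------------------------------------
# bout classification


def classify_bout(bout: Bout) -> str:
    """Classify a bout from its maximum tail-bend amplitude.

    Below 25° → forward swim; 25–60° → turn, with side given by the sign of
    the maximum-magnitude bend (positive = left under the left-positive
    convention); above 60° → discarded (escape/struggle-like).
    """
    if not bout.bends:
        return "unclassified"
    mx = bout.max_abs_tba_deg
    if mx < FORWARD_MAX_DEG:
        return "forward"
    if mx > DISCARD_DEG:
        return "discarded"
    peak = max(bout.bends, key=lambda b: abs(b.amp_deg))
    return "left_turn" if peak.amp_deg > 0 else "right_turn"


# ---------------------------------------------------------------------------
# forward index


def forward_index(episodes: list[Episode]) -> float:
    """(n_forward − n_struggle) / n_total over one stimulation trial."""
    if not episodes:
        raise ValueError("no episodes in stimulation window")
    nf = sum(1 for e in episodes if e.label == "forward")
    ns = sum(1 for e in episodes if e.label == "struggle")
    return (nf - ns) / len(episodes)


def site_median_forward_index(
    trials: list[tuple[StimTrial, float]],
    pulse_freq_hz: float = 10.0,
    intensity_range_ua: tuple[float, float] = (1.0, 2.0),
) -> float:
    """Median forward index over a site's optimal-parameter trials.

    Only trials with trains at ``pulse_freq_hz`` (10 Hz) and intensity within
    ``intensity_range_ua`` (1–2 µA) qualify; returns NaN if none do.
    """
    if not trials:
        raise ValueError("no trials")
    lo, hi = intensity_range_ua
    vals = [
        fi
        for tr, fi in trials
        if abs(tr.pulse_freq_hz - pulse_freq_hz) < 1e-6 and lo <= tr.intensity_ua <= hi
    ]
    if not vals:
        return float("nan")
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# provenance tagging


def tag_provenance(
    bouts: list[Bout],
    trials: list[StimTrial],
    post_window_s: float = 60.0,
) -> list[Bout]:
    """Tag each bout evoked/spontaneous relative to stimulation trains.

    A bout is *evoked* if it starts inside a train window.  Bouts starting
    within ``post_window_s`` after a train end are marked ``excluded`` —
    neither evoked nor usable as spontaneous.
    """
    for b in bouts:
        b.provenance = "spontaneous"
        b.stim_id = None
        for tr in trials:
            if tr.train_start_s <= b.start_s < tr.train_end_s:
                b.provenance = "evoked"
                b.stim_id = tr.stim_id
                break
            if tr.train_end_s <= b.start_s < tr.train_end_s + post_window_s:
                b.provenance = "excluded"
    return bouts
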