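"""Event-locked recruitment statistics for V2a reticulospinal neurons.

Single-pulse response detection (baseline + 3×noise within 3 s), reliability
classes across graded stimulation intensities, rising slopes of evoked
transients, episode-locked recruitment (corrected max ΔF/F ≥ 5×noise), the
forward activity index, and agglomerative clustering to isolate the forward
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .fluo import FluoTrace
from .kinematics import Episode

__all__ = [
    "PulseResponse",
    "RecruitmentLabel",
    "EpisodeActivity",
    "detect_pulse_response",
    "classify_reliability",
    "rising_slope",
    "onset_peak_detect",
    "episode_recruitment",
    "corrected_episode_max",
    "forward_activity_index",
    "cluster_forward",
]


@dataclass
class PulseResponse:
    roi_id: int
    stim_id: int
    intensity_ua: float
    responded: bool
    peak_dff: float
    baseline_dff: float
    rising_slope: float | None = None


@dataclass
class RecruitmentLabel:
    roi_id: int
    label: str  # "reliable" | "unreliable" | "non_recruited"
    threshold_intensity_ua: float | None = None


@dataclass
class EpisodeActivity:
    roi_id: int
    episode_id: int
    corrected_max_dff: float
    recruited: bool


def _window_slice(t: np.ndarray, lo: float, hi: float) -> slice:
    i0, i1 = np.searchsorted(t, [lo, hi])
    return slice(int(i0), int(i1))


def detect_pulse_response(
    trace: FluoTrace,
    stim_time_s: float,
    stim_id: int = 0,
    intensity_ua: float = float("nan"),
    response_window_s: float = 3.0,
    baseline_window_s: float = 1.5,
    n_sigma: float = 3.0,
) -> PulseResponse:
    """Did the cell respond to a single pulse?

    Responded iff the maximal ΔF/F between stimulation start and 3 s after
    exceeds the baseline (mean ΔF/F over the 1.5 s before the stimulation)
    plus 3 times the cell's noise σ.
    """
    t = trace.t_s
    if stim_time_s - baseline_window_s < t[0] - 1e-9 or stim_time_s + response_window_s > t[-1] + 1e-9:
        raise ValueError("incomplete window")
    base = trace.dff[_window_slice(t, stim_time_s - baseline_window_s, stim_time_s)]
    resp = trace.dff[_window_slice(t, stim_time_s, stim_time_s + response_window_s)]
    if base.size == 0 or resp.size == 0:
        raise ValueError("incomplete window")
    baseline = float(np.mean(base))
    peak = float(np.max(resp))
    responded = peak > baseline + n_sigma * trace.noise_sigma
    return PulseResponse(
        roi_id=trace.roi_id,
        stim_id=stim_id,
        intensity_ua=intensity_ua,
        responded=bool(responded),
        peak_dff=peak,
        baseline_dff=baseline,
    )


def classify_reliability(
    responses_by_intensity: list[tuple[float, list[bool]]],
    roi_id: int = 0,
    allowed_failures: int = 0,
) -> RecruitmentLabel:
    """Classify a cell across graded pulse intensities.

    *non_recruited*: no response at any intensity.  *reliable*: from the
    lowest intensity with any response (the recruitment threshold I*) upward,
    every trial responded (up to ``allowed_failures`` tolerated failures).
    Anything else is *unreliable*.
    """
    intensities = [i for i, _ in responses_by_intensity]
    if any(b <= a for a, b in zip(intensities, intensities[1:])):
        raise ValueError("intensities must be strictly increasing")
    if not all(r for _, r in responses_by_intensity):
        raise ValueError("need at least one trial per intensity")
    any_resp = [any(r) for _, r in responses_by_intensity]
    if not any(any_resp):
        return RecruitmentLabel(roi_id=roi_id, label="non_recruited")
    first = any_resp.index(True)
    failures = sum(
        r.count(False) for _, r in responses_by_intensity[first:]
    )
    if failures <= allowed_failures:
        return RecruitmentLabel(
            roi_id=roi_id, label="reliable", threshold_intensity_ua=intensities[first]
        )
    return RecruitmentLabel(roi_id=roi_id, label="unreliable")


def rising_slope(trace: FluoTrace, t_onset_s: float, t_peak_s: float) -> float:
    """(ΔF/F(t_peak) − ΔF/F(t_onset)) / (t_peak − t_onset), on raw ΔF/F."""
    if t_peak_s <= t_onset_s:
        raise ValueError("t_peak must be after t_onset")
    t = trace.t_s
    if t_onset_s < t[0] - 1e-9 or t_peak_s > t[-1] + 1e-9:
        raise ValueError("time points outside trace")
    d_on = float(np.interp(t_onset_s, t, trace.dff))
    d_pk = float(np.interp(t_peak_s, t, trace.dff))
    return (d_pk - d_on) / (t_peak_s - t_onset_s)


def onset_peak_detect(
    trace: FluoTrace,
    stim_time_s: float,
    search_window_s: float = 3.0,
    n_sigma: float = 1.0,
    min_rise_frames: int = 2,
    baseline_window_s: float = 1.5,
) -> tuple[float, float]:
    """Automated onset/peak times of a stimulus-evoked transient.

    The transient is located at the first post-stimulation frame where ΔF/F
    exceeds baseline + 1×noise and stays above that threshold for at least
    ``min_rise_frames`` further frames (so single-frame noise excursions
    never qualify, while both gradual and frame-instant rises do); the onset
    is the preceding frame, where the trace last sat at baseline before
    rising.  Peak: argmax of ΔF/F within
    ``search_window_s`` after onset.  Raises if no qualifying onset exists.
    (Automated stand-in for manual annotation; outputs are meant for review.)
    """
    t = trace.t_s
    dff = trace.dff
    base = dff[_window_slice(t, stim_time_s - baseline_window_s, stim_time_s)]
    if base.size == 0:
        raise ValueError("incomplete window")
    thresh = float(np.mean(base)) + n_sigma * trace.noise_sigma
    sl = _window_slice(t, stim_time_s, stim_time_s + search_window_s)
    for i in range(sl.start, sl.stop):
        if dff[i] <= thresh:
            continue
        if i + min_rise_frames >= dff.size:
            break
        if all(dff[i + k + 1] > thresh for k in range(min_rise_frames)):
            # the rise begins at the last frame still at baseline, one frame
            # before the threshold crossing (keeps peak strictly after onset
            # even for frame-instant rises)
            on = max(i - 1, sl.start)
            t_onset = float(t[on])
            sl2 = _window_slice(t, t_onset, t_onset + search_window_s)
            j = sl2.start + int(np.argmax(dff[sl2]))
            if j <= on:
                j = on + 1
            return t_onset, float(t[j])
    raise ValueError("no transient")


def corrected_episode_max(
    dff: np.ndarray,
    t: np.ndarray,
    episode_start_s: float,
    episode_end_s: float,
    pre_s: float = 0.5,
    post_s: float = 2.0,
    baseline_s: float = 0.3,
) -> float:
    """Max ΔF/F in [start−0.5 s, end+2 s] minus the median ΔF/F of the 300 ms
    preceding the episode (correction for residual decay of earlier events)."""
    if episode_start_s - pre_s < t[0] - 1e-9 or episode_end_s + post_s > t[-1] + 1e-9:
        raise ValueError("incomplete window")
    win = dff[_window_slice(t, episode_start_s - pre_s, episode_end_s + post_s)]
    base = dff[_window_slice(t, episode_start_s - baseline_s, episode_start_s)]
    if win.size == 0 or base.size == 0:
        raise ValueError("incomplete window")
    return float(np.max(win) - np.median(base))


def episode_recruitment(
    trace: FluoTrace,
    episode: Episode,
    episode_id: int = 0,
    n_sigma: float = 5.0,
) -> EpisodeActivity:
    """Was the cell recruited during a swim episode?

    Recruited iff the baseline-corrected maximum ΔF/F around the episode
    reaches 5 times the cell's noise σ.
    """
    cmax = corrected_episode_max(trace.dff, trace.t_s, episode.start_s, episode.end_s)
    return EpisodeActivity(
        roi_id=trace.roi_id,
        episode_id=episode_id,
        corrected_max_dff=cmax,
        recruited=bool(cmax >= n_sigma * trace.noise_sigma),
    )


def forward_activity_index(
    trace: FluoTrace,
    forward_episodes: list[Episode],
    struggle_episodes: list[Episode],
    mode: str = "max",
) -> float:
    """(A_f − A_s) / (A_f + A_s): contrast of episode-locked response size.

    ``mode="max"`` (default): A_f and A_s are means over episodes of the
    per-episode baseline-corrected maximum ΔF/F, floored at zero so the index
    stays in [−1, 1].  ``mode="mean"``: means of the per-episode mean ΔF/F
    over the episode window (alternative reading of the definition).
    Returns NaN when both means are zero.
    """
    if not forward_episodes or not struggle_episodes:
        raise ValueError("need at least one episode of each class")

    def amp(ep: Episode) -> float:
        if mode == "max":
            return max(
                corrected_episode_max(trace.dff, trace.t_s, ep.start_s, ep.end_s), 0.0
            )
        if mode == "mean":
            win = trace.dff[_window_slice(trace.t_s, ep.start_s - 0.5, ep.end_s + 2.0)]
            return max(float(np.mean(win)), 0.0)
        raise ValueError(f"unknown mode {mode!r}")

    a_f = float(np.mean([amp(e) for e in forward_episodes]))
    a_s = float(np.mean([amp(e) for e in struggle_episodes]))
    if a_f + a_s == 0:
        return float("nan")
    return (a_f - a_s) / (a_f + a_s)


def cluster_forward(
    traces: list[FluoTrace],
    forward_episodes: list[Episode],
    struggle_episodes: list[Episode],
    n_clusters: int = 4,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Agglomerative clustering of ΔF/F traces and forward-cluster selection.

    Ward-linkage agglomerative clustering on z-scored ΔF/F (Euclidean); the
    forward cluster is the one whose members have the highest mean forward
    activity index.  Returns ``(cluster_labels, forward_cluster_id,
    per_roi_forward_activity_index)``.
    """
    if len(traces) < n_clusters:
        raise ValueError("need at least n_clusters ROIs")
    mat = np.stack([tr.dff for tr in traces])
    sd = mat.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("degenerate matrix: constant ΔF/F row(s)")
    z = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
    labels = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(z)
    fai = np.array(
        [forward_activity_index(tr, forward_episodes, struggle_episodes) for tr in traces]
    )
    means = [np.nanmean(fai[labels == k]) for k in range(n_clusters)]
    forward_id = int(np.nanargmax(means))
    if not means[forward_id] > 0:
        raise ValueError("no cluster with positive mean forward activity index")
    return labels, forward_id, fai
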