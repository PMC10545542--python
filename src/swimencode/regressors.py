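"""Behavior-derived predictor series at imaging rate.

Motor regressors are fictive calcium traces: per-frame tail-beat amplitude
(iTBA) and frequency (iTBF), their binary-rise indicators, swim vigor and
bout/stimulus on-off traces, each convolved with an exponential
calcium-indicator kernel (GCaMP6s decay, default 1.5 s) and, where built at
the behavior rate, downsampled to the imaging frame times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .kinematics import Bend, Bout, StimTrial, TailTrace, cycle_kinematics

__all__ = [
    "RegressorSet",
    "frame_kinematics",
    "binary_rise",
    "vigor",
    "convolve_kernel",
    "zscore",
    "build_regressor_set",
    "classify_motor_vigor",
]


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance series cannot be z-scored")
    return (x - x.mean()) / sd


@dataclass
class RegressorSet:
    """The four motor regressors plus vigor and on/off regressors.

    In the encoding model, x1 = iTBA, x2 = iTBA rise, x3 = iTBF,
    x4 = iTBF rise.  ``design_matrix()`` stacks them column-wise in that
    order (without intercept).
    """

    frame_times_s: np.ndarray
    x_itba: np.ndarray
    x_itba_rise: np.ndarray
    x_itbf: np.ndarray
    x_itbf_rise: np.ndarray
    x_vigor: np.ndarray | None = None
    x_bout_onoff: np.ndarray | None = None
    x_stim_onoff: np.ndarray | None = None
    kernel_tau_s: float = 1.5
    zscored: bool = True

    def design_matrix(self) -> np.ndarray:
        return np.column_stack([self.x_itba, self.x_itba_rise, self.x_itbf, self.x_itbf_rise])


def _frame_edges(frame_times: np.ndarray) -> np.ndarray:
    """Half-open frame intervals [t_i, t_{i+1}); last interval one median dt."""
    frame_times = np.asarray(frame_times, dtype=float)
    dt = float(np.median(np.diff(frame_times))) if frame_times.size > 1 else 1.0
    return np.append(frame_times, frame_times[-1] + dt)


def frame_kinematics(
    trace: TailTrace,
    bends: list[Bend],
    frame_times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-imaging-frame kinematics.

    iTBA per frame: maximal absolute tail angle over the behavior samples in
    the frame interval (0 if none).  iTBF per frame: mean iTBF of the cycles
    whose midpoint falls in the frame interval (0 if none).
    """
    edges = _frame_edges(frame_times)
    nf = len(frame_times)
    idx = np.clip(np.searchsorted(edges, trace.time_s, side="right") - 1, -1, nf)
    itba = np.zeros(nf)
    valid = (idx >= 0) & (idx < nf)
    np.maximum.at(itba, idx[valid], np.abs(trace.angle_deg[valid]))

    itbf = np.zeros(nf)
    cyc_f, _, _ = cycle_kinematics(bends)
    if cyc_f.size:
        t = np.array([b.t_s for b in bends])
        mid = (t[2:] + t[:-2]) / 2.0
        ci = np.clip(np.searchsorted(edges, mid, side="right") - 1, -1, nf)
        sums = np.zeros(nf)
        counts = np.zeros(nf)
        ok = (ci >= 0) & (ci < nf)
        np.add.at(sums, ci[ok], cyc_f[ok])
        np.add.at(counts, ci[ok], 1.0)
        nz = counts > 0
        itbf[nz] = sums[nz] / counts[nz]
    return itba, itbf


def binary_rise(series: np.ndarray, smooth_frames: int = 5) -> np.ndarray:
    """{0,1} indicator that a kinematic parameter is increasing.

    The series is smoothed with a ``smooth_frames``-frame running average
    (shrink-to-valid at the edges), differentiated, and thresholded at zero
    (Heaviside of the derivative); the first sample is 0.
    """
    series = np.asarray(series, dtype=float)
    if series.size <= smooth_frames:
        raise ValueError("series shorter than the smoothing window")
    kernel = np.ones(smooth_frames)
    sm = np.convolve(series, kernel, mode="same") / np.convolve(
        np.ones_like(series), kernel, mode="same"
    )
    out = np.zeros(series.size)
    out[1:] = (np.diff(sm) > 0).astype(float)
    return out


def vigor(trace: TailTrace, window_s: float = 0.050) -> np.ndarray:
    """Swim vigor: centered sliding s.d. of the tail angle (50-ms window)."""
    win = int(round(window_s * trace.rate_hz))
    if win < 2:
        raise ValueError("window must cover at least 2 samples")
    s = pd.Series(trace.angle_deg)
    v = s.rolling(win, center=True, min_periods=2).std(ddof=1)
    return v.fillna(0.0).to_numpy()


def convolve_kernel(
    series: np.ndarray,
    tau_s: float,
    rate_hz: float,
    frame_times: np.ndarray | None = None,
    source_times: np.ndarray | None = None,
    zscored: bool = False,
) -> np.ndarray:
    """Causal convolution with an exponential indicator kernel.

    ``k(t) = exp(-t / tau_s)`` sampled on the source grid (not normalized to
    unit sum); implemented as the exact first-order recursive filter.  If
    ``frame_times`` is given the convolved series is downsampled by taking
    the instantaneous value at each frame time.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    series = np.asarray(series, dtype=float)
    gamma = float(np.exp(-1.0 / (tau_s * rate_hz)))
    conv = lfilter([1.0], [1.0, -gamma], series)
    if frame_times is not None:
        if source_times is None:
            source_times = np.arange(series.size) / rate_hz
        conv = np.interp(frame_times, source_times, conv)
    if zscored:
        conv = zscore(conv)
    return conv


def _onoff(times: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    out = np.zeros(times.size)
    for a, b in intervals:
        out[(times >= a) & (times < b)] = 1.0
    return out


def build_regressor_set(
    trace: TailTrace,
    bends: list[Bend],
    frame_times: np.ndarray,
    tau_s: float = 1.5,
    bouts: list[Bout] | None = None,
    stim_trials: list[StimTrial] | None = None,
    zscored: bool = True,
    rise_smooth_frames: int = 5,
) -> RegressorSet:
    """Build the full regressor set for one session.

    The four motor regressors are built at the imaging rate (frame-level
    kinematics, binary rises, then kernel convolution at the frame rate).
    Vigor and bout/stimulus on-off regressors are built at the behavior rate,
    convolved there, and downsampled to the frame times.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    frame_rate = 1.0 / float(np.median(np.diff(frame_times)))
    itba, itbf = frame_kinematics(trace, bends, frame_times)
    itba_rise = binary_rise(itba, rise_smooth_frames)
    itbf_rise = binary_rise(itbf, rise_smooth_frames)

    def conv_frame(x: np.ndarray) -> np.ndarray:
        y = convolve_kernel(x, tau_s, frame_rate)
        return zscore(y) if zscored else y

    x_vigor = x_bout = x_stim = None
    vig = vigor(trace)
    if np.any(vig):
        x_vigor = convolve_kernel(
            vig, tau_s, trace.rate_hz, frame_times=frame_times, source_times=trace.time_s
        )
        x_vigor = zscore(x_vigor) if zscored else x_vigor
    if bouts:
        ob = _onoff(trace.time_s, [(b.start_s, b.end_s) for b in bouts])
        x_bout = convolve_kernel(
            ob, tau_s, trace.rate_hz, frame_times=frame_times, source_times=trace.time_s
        )
        x_bout = zscore(x_bout) if zscored else x_bout
    if stim_trials:
        os_ = _onoff(trace.time_s, [(s.train_start_s, s.train_end_s) for s in stim_trials])
        x_stim = convolve_kernel(
            os_, tau_s, trace.rate_hz, frame_times=frame_times, source_times=trace.time_s
        )
        x_stim = zscore(x_stim) if zscored else x_stim

    return RegressorSet(
        frame_times_s=frame_times,
        x_itba=conv_frame(itba),
        x_itba_rise=conv_frame(itba_rise),
        x_itbf=conv_frame(itbf),
        x_itbf_rise=conv_frame(itbf_rise),
        x_vigor=x_vigor,
        x_bout_onoff=x_bout,
        x_stim_onoff=x_stim,
        kernel_tau_s=tau_s,
        zscored=zscored,
    )


def classify_motor_vigor(
    r_motor: np.ndarray,
    r_stim: np.ndarray,
    r_vigor: np.ndarray,
    motor_percentile: float = 75.0,
    vigor_percentile: float = 75.0,
    vigor_percentile_pool: str = "all",
) -> pd.DataFrame:
    """Label ROIs as motor-correlated and vigor-correlated (per fish).

    Motor-correlated: motor correlation above the 75th percentile of motor
    correlations of all ROIs.  Vigor-correlated: motor correlation above the
    stimulus correlation AND vigor correlation within the top 25th percentile
    of vigor correlations (computed over all ROIs by default, or over the
    motor-over-stimulus candidate set with
    ``vigor_percentile_pool="candidates"``).
    """
    r_motor = np.asarray(r_motor, float)
    r_stim = np.asarray(r_stim, float)
    r_vigor = np.asarray(r_vigor, float)
    if r_motor.size < 4:
        raise ValueError("need at least 4 ROIs")
    motor_thr = np.percentile(r_motor, motor_percentile)
    motor_corr = r_motor > motor_thr
    candidates = r_motor > r_stim
    pool = r_vigor if vigor_percentile_pool == "all" else r_vigor[candidates]
    if pool.size == 0:
        vigor_corr = np.zeros(r_motor.size, dtype=bool)
    else:
        vigor_thr = np.percentile(pool, vigor_percentile)
        vigor_corr = candidates & (r_vigor >= vigor_thr)
    return pd.DataFrame(
        {
            "r_motor": r_motor,
            "r_stim": r_stim,
            "r_vigor": r_vigor,
            "motor_correlated": motor_corr,
            "vigor_correlated": vigor_corr,
        }
    )
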