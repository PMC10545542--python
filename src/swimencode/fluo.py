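"""Fluorescence preprocessing, spike-rate inference and ROI segmentation.

Per-ROI pipeline: neuropil subtraction (factor 0.7), ΔF/F against an
inactivity or low-percentile baseline, noise estimation on a 3-s inactivity
period, light smoothing, artifact masking with linear interpolation, and
nonnegative deconvolution against an exponential indicator kernel
(GCaMP decay, default 1.8 s).  Pixel movies are segmented into somata-sized
ROIs by correlation growing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import lsq_linear, nnls
from scipy.sparse.linalg import LinearOperator

__all__ = [
    "FluoTrace",
    "PixelMovie",
    "RoiMask",
    "neuropil_correct_and_dff",
    "estimate_noise",
    "smooth_trace",
    "mask_and_interpolate",
    "infer_spike_rate",
    "segment_rois_by_correlation",
]


@dataclass
class FluoTrace:
    """Per-ROI fluorescence record at imaging frame rate."""

    roi_id: int
    t_s: np.ndarray
    f_raw: np.ndarray
    f_neuropil: np.ndarray
    rate_hz: float
    dff: np.ndarray | None = None
    f0: float | None = None
    noise_sigma: float | None = None
    spike_rate: np.ndarray | None = None
    artifact_mask: np.ndarray | None = None  # True = bad frame

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.f_raw = np.asarray(self.f_raw, dtype=float)
        self.f_neuropil = np.asarray(self.f_neuropil, dtype=float)
        if not (self.t_s.size == self.f_raw.size == self.f_neuropil.size):
            raise ValueError("trace length mismatch")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.t_s.size, dtype=bool)


@dataclass
class PixelMovie:
    """A small 2D+t fluorescence movie for ROI segmentation."""

    frames: np.ndarray  # (T, H, W)
    pixel_size_um: float
    rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or min(self.frames.shape) == 0:
            raise ValueError("frames must be a nonempty (T, H, W) stack")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class RoiMask:
    roi_id: int
    pixels: list[tuple[int, int]]  # (row, col)
    area_um2: float
    trace: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# ΔF/F


def neuropil_correct_and_dff(
    f_raw: np.ndarray,
    f_neuropil: np.ndarray,
    neuropil_factor: float = 0.7,
    baseline_mode: str = "inactivity_median",
    inactivity_interval: tuple[int, int] | None = None,
    percentile: float = 10.0,
) -> tuple[np.ndarray, float]:
    """Neuropil-corrected ΔF/F.

    Corrected fluorescence is ``F = f_raw - neuropil_factor * f_neuropil``.
    The baseline F0 is either the median of F over an inactivity interval
    (frame indices, half-open; single-plane recordings) or the median of the
    lowest ``percentile`` of F values (volumetric recordings).  Returns
    ``(dff, f0)`` with ``dff = (F - F0) / F0``.
    """
    f_raw = np.asarray(f_raw, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_raw.shape != f_neuropil.shape:
        raise ValueError("trace length mismatch")
    if not 0.0 <= neuropil_factor < 1.0:
        raise ValueError("neuropil_factor must be in [0, 1)")
    f = f_raw - neuropil_factor * f_neuropil
    if baseline_mode == "inactivity_median":
        if inactivity_interval is None:
            raise ValueError("inactivity_interval required for inactivity_median")
        lo, hi = inactivity_interval
        if lo < 0 or hi > f.size or hi <= lo:
            raise ValueError("inactivity interval outside trace")
        f0 = float(np.median(f[lo:hi]))
    elif baseline_mode == "low_percentile":
        cut = np.percentile(f, percentile)
        f0 = float(np.median(f[f <= cut]))
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    if f0 <= 0:
        raise ValueError("degenerate baseline")
    return (f - f0) / f0, f0


def estimate_noise(
    dff: np.ndarray,
    inactivity_interval: tuple[int, int],
    rate_hz: float,
    min_length_s: float = 1.0,
) -> float:
    """Noise σ: sample s.d. of ΔF/F over an inactivity interval (frames)."""
    dff = np.asarray(dff, dtype=float)
    lo, hi = inactivity_interval
    if lo < 0 or hi > dff.size or hi <= lo:
        raise ValueError("interval outside trace")
    if (hi - lo) / rate_hz < min_length_s:
        raise ValueError("inactivity interval too short")
    return float(np.std(dff[lo:hi], ddof=1))


def smooth_trace(
    dff: np.ndarray,
    mode: str = "running_average_3",
    cutoff_hz: float | None = None,
    rate_hz: float | None = None,
) -> np.ndarray:
    """Smooth ΔF/F: 3-frame centered running mean, or zero-phase low-pass.

    The running average shrinks to the available neighbors at the edges
    (2-frame mean), so a constant series is left unchanged.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.size < 3:
        raise ValueError("need at least 3 frames")
    if mode == "running_average_3":
        kernel = np.ones(3)
        num = np.convolve(dff, kernel, mode="same")
        den = np.convolve(np.ones_like(dff), kernel, mode="same")
        return num / den
    if mode == "low_pass":
        if cutoff_hz is None or rate_hz is None:
            raise ValueError("low_pass mode needs cutoff_hz and rate_hz")
        b, a = signal.butter(1, cutoff_hz / (rate_hz / 2.0))
        return signal.filtfilt(b, a, dff)
    raise ValueError(f"unknown mode {mode!r}")


def mask_and_interpolate(dff: np.ndarray, bad_frames: np.ndarray) -> np.ndarray:
    """Replace artifact frames by linear interpolation between good neighbors.

    Unmasked frames are returned bit-identical; leading/trailing bad frames
    take the nearest good value.
    """
    dff = np.asarray(dff, dtype=float)
    bad = np.zeros(dff.size, dtype=bool)
    bad[np.asarray(bad_frames, dtype=int)] = True
    good = np.flatnonzero(~bad)
    if good.size == 0:
        raise ValueError("all frames masked")
    out = dff.copy()
    if good.size < dff.size:
        out[bad] = np.interp(np.flatnonzero(bad), good, dff[good])
    return out


# ---------------------------------------------------------------------------
# spike inference


def _exp_kernel_operator(n: int, gamma: float) -> LinearOperator:
    """Causal convolution with k[j] = gamma**j as a linear operator."""

    def matvec(r: np.ndarray) -> np.ndarray:
        return signal.lfilter([1.0], [1.0, -gamma], r)

    def rmatvec(y: np.ndarray) -> np.ndarray:
        return signal.lfilter([1.0], [1.0, -gamma], y[::-1])[::-1]

    return LinearOperator((n, n), matvec=matvec, rmatvec=rmatvec, dtype=float)


def infer_spike_rate(
    dff: np.ndarray,
    decay_s: float = 1.8,
    rate_hz: float = 10.0,
    sparsity: float = 0.0,
    solver: str = "nnls",
) -> np.ndarray:
    """Nonnegative spike-rate inference by exponential-kernel deconvolution.

    Finds the nonnegative series r minimizing ``||k * r - dff||^2`` where
    ``k(t) = exp(-t / decay_s)`` sampled on the imaging grid (optionally with
    an L2 sparsity penalty of weight ``sparsity``).  ``solver="nnls"`` uses a
    bound-constrained least-squares solve through the convolution operator;
    ``solver="ar"`` uses the exact one-step autoregressive inversion
    ``r[t] = dff[t] - gamma * dff[t-1]`` clipped at zero — fast, and identical
    on noise-free nonnegative-generating input.
    """
    dff = np.asarray(dff, dtype=float)
    if decay_s <= 0:
        raise ValueError("decay_s must be positive")
    n = dff.size
    gamma = float(np.exp(-1.0 / (decay_s * rate_hz)))
    if not np.any(dff):
        return np.zeros(n)
    if solver == "ar":
        r = dff.copy()
        r[1:] -= gamma * dff[:-1]
        return np.clip(r, 0.0, None)
    if solver != "nnls":
        raise ValueError(f"unknown solver {solver!r}")
    if n <= 600:
        # small systems: dense active-set NNLS
        k = gamma ** np.arange(n)
        kmat = np.tril(np.array([[k[i - j] if i >= j else 0.0 for j in range(n)] for i in range(n)]))
        if sparsity > 0:
            kmat = np.vstack([kmat, np.sqrt(sparsity) * np.eye(n)])
            target = np.concatenate([dff, np.zeros(n)])
        else:
            target = dff
        r, _ = nnls(kmat, target)
        return r
    op = _exp_kernel_operator(n, gamma)
    if sparsity > 0:
        base = op

        def matvec(r: np.ndarray) -> np.ndarray:
            return np.concatenate([base.matvec(r), np.sqrt(sparsity) * r])

        def rmatvec(y: np.ndarray) -> np.ndarray:
            return base.rmatvec(y[:n]) + np.sqrt(sparsity) * y[n:]

        op = LinearOperator((2 * n, n), matvec=matvec, rmatvec=rmatvec, dtype=float)
        target = np.concatenate([dff, np.zeros(n)])
    else:
        target = dff
    res = lsq_linear(op, target, bounds=(0.0, np.inf), method="trf", lsq_solver="lsmr", tol=1e-10)
    return np.clip(res.x, 0.0, None)


# ---------------------------------------------------------------------------
# ROI segmentation by correlation growing


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = np.inf  # constant pixels correlate with nothing
    return (x - mu) / sd


def neighbor_correlation_map(movie: PixelMovie) -> np.ndarray:
    """Per-pixel correlation with the average trace of its 8 adjacent pixels."""
    t, h, w = movie.frames.shape
    x = movie.frames
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nb_sum = np.empty_like(x)
    for i in range(t):  # small movies; per-frame 2D convolution
        nb_sum[i] = signal.convolve2d(x[i], kernel, mode="same")
    counts = signal.convolve2d(np.ones((h, w)), kernel, mode="same")
    nb_mean = nb_sum / counts
    zx = _zscore_rows(x.reshape(t, -1).T)
    zn = _zscore_rows(nb_mean.reshape(t, -1).T)
    corr = (zx * zn).mean(axis=1)
    return corr.reshape(h, w)


def segment_rois_by_correlation(
    movie: PixelMovie,
    seed_threshold: float = 0.3,
    far_threshold: float = 0.35,
    far_distance_um: float = 3.0,
    area_range_um2: tuple[float, float] = (9.0, 28.0),
) -> list[RoiMask]:
    """Segment somata-sized ROIs by iterative correlation growing.

    Seeds at the highest remaining value of the 8-neighbor correlation map
    above ``seed_threshold``; grows by adding neighboring pixels whose
    correlation with the running mean trace of the current region exceeds a
    threshold rising linearly from ``seed_threshold`` (adjacent to the seed)
    to ``far_threshold`` at ``far_distance_um`` from the seed.  Regions whose
    final area falls outside ``area_range_um2`` are rejected (not shrunk).
    ROI traces are the sum of member-pixel traces; masks are disjoint.
    """
    t, h, w = movie.frames.shape
    if h < 3 or w < 3 or t < 50:
        raise ValueError("movie too small: need >= 3x3 pixels and >= 50 frames")
    px_area = movie.pixel_size_um**2
    corr = neighbor_correlation_map(movie).copy()
    traces = movie.frames.reshape(t, -1).T  # (H*W, T)
    ztr = _zscore_rows(traces)
    available = np.ones(h * w, dtype=bool)
    max_pixels = int(np.ceil(area_range_um2[1] / px_area))

    def threshold_at(d_um: float) -> float:
        frac = min(max(d_um, 0.0) / far_distance_um, 1.0)
        return seed_threshold + (far_threshold - seed_threshold) * frac

    rois: list[RoiMask] = []
    roi_id = 0
    flat_corr = corr.ravel()
    while True:
        cand = np.where(available, flat_corr, -np.inf)
        seed = int(np.argmax(cand))
        if cand[seed] <= seed_threshold:
            break
        sr, sc = divmod(seed, w)
        members = [seed]
        region_sum = ztr[seed].copy()
        grew = True
        # grow until nothing passes; may overshoot the area cap by one pixel,
        # in which case the area gate below rejects the region outright
        while grew and len(members) <= max_pixels:
            grew = False
            frontier: set[int] = set()
            for m in members:
                r, c = divmod(m, w)
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w:
                            p = rr * w + cc
                            if available[p] and p not in members:
                                frontier.add(p)
            if not frontier:
                break
            region_mean = region_sum / len(members)
            rm = region_mean - region_mean.mean()
            rm_sd = rm.std()
            if rm_sd == 0:
                break
            best_p, best_c = -1, -np.inf
            for p in sorted(frontier):  # row-major tie-break
                cval = float((ztr[p] * rm).mean() / rm_sd)
                if cval > best_c:
                    best_p, best_c = p, cval
            rr, cc = divmod(best_p, w)
            d_um = float(np.hypot(rr - sr, cc - sc)) * movie.pixel_size_um
            if best_c > threshold_at(d_um):
                members.append(best_p)
                region_sum += ztr[best_p]
                grew = True
        available[members] = False  # consumed whether accepted or rejected
        area = len(members) * px_area
        if area_range_um2[0] <= area <= area_range_um2[1]:
            pix = [divmod(m, w) for m in members]
            trace = traces[members].sum(axis=0)
            rois.append(RoiMask(roi_id=roi_id, pixels=pix, area_um2=area, trace=trace))
            roi_id += 1
    return rois
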