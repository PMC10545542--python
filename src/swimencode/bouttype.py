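"""Bout-type neural activity mapping.

From inferred spike rates and classified bouts, decide for each neuron
whether it is active during forward swims, left turns and right turns
(one-sided rank-sum against rest activity, P < 0.01, window from 200 ms
before bout start to bout end), then assign functional groups:
forward-component neurons are active in all three bout types; steering
neurons are active for one turn side but not during forward swims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinematics import Bout, TailTrace
from .regressors import _frame_edges

__all__ = [
    "FunctionalLabel",
    "rest_spike_sample",
    "detect_active",
    "assign_groups",
    "session_passes_inclusion",
]

BOUT_TYPES = ("forward", "left_turn", "right_turn")


@dataclass
class FunctionalLabel:
    roi_id: int
    active_forward: bool | None
    active_left: bool | None
    active_right: bool | None
    p_forward: float
    p_left: float
    p_right: float
    group: str  # forward_component | left_steering | right_steering | other


def rest_spike_sample(
    spike_rate: np.ndarray,
    frame_times: np.ndarray,
    trace: TailTrace,
    bouts: list[Bout],
    rest_epsilon_deg: float = 0.5,
    min_rest_s: float = 5.0,
) -> np.ndarray:
    """Spike rates at frames where the fish is at rest.

    A frame counts as rest when the mean absolute (median-filtered) tail
    angle over its interval stays below ``rest_epsilon_deg`` and the interval
    overlaps no bout.  The median filter and the per-frame mean make the
    "angle is zero" criterion robust to tracking noise.
    """
    from scipy.signal import medfilt

    spike_rate = np.asarray(spike_rate, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    edges = _frame_edges(frame_times)
    nf = frame_times.size
    idx = np.clip(np.searchsorted(edges, trace.time_s, side="right") - 1, -1, nf)
    angle = trace.angle_deg
    if angle.size >= 3:
        angle = medfilt(angle, kernel_size=3)
    sums = np.zeros(nf)
    counts = np.zeros(nf)
    ok = (idx >= 0) & (idx < nf)
    np.add.at(sums, idx[ok], np.abs(angle[ok]))
    np.add.at(counts, idx[ok], 1.0)
    moving = np.zeros(nf, dtype=bool)
    covered = counts > 0
    moving[covered] = (sums[covered] / counts[covered]) >= rest_epsilon_deg
    moving[~covered] = True  # frames beyond the behavior record are unusable
    for b in bouts:
        moving[(edges[:-1] < b.end_s) & (edges[1:] > b.start_s)] = True
    rest = spike_rate[~moving]
    dt = float(np.median(np.diff(frame_times))) if nf > 1 else 1.0
    if rest.size * dt < min_rest_s:
        raise ValueError("insufficient rest in session")
    return rest


def _rank_sum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided rank-sum p (x stochastically greater than y).

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with tie correction.
    """
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue)


def detect_active(
    spike_rate: np.ndarray,
    frame_times: np.ndarray,
    bouts: list[Bout],
    rest_sample: np.ndarray,
    alpha: float = 0.01,
    pre_bout_s: float = 0.2,
) -> tuple[bool | None, float]:
    """Is the neuron active during this bout type?

    Pools spike rates over [start − 200 ms, end] of every bout of the type
    and tests them against the rest sample with a one-sided Wilcoxon
    rank-sum test at P = ``alpha``.  Fewer than 3 bouts of the type returns
    ``(None, nan)`` — an undefined-marker, not an error.
    """
    if len(bouts) < 3:
        return None, float("nan")
    if rest_sample.size == 0:
        raise ValueError("empty rest sample")
    spike_rate = np.asarray(spike_rate, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    sel = np.zeros(frame_times.size, dtype=bool)
    for b in bouts:
        sel |= (frame_times >= b.start_s - pre_bout_s) & (frame_times <= b.end_s)
    sample = spike_rate[sel]
    if sample.size == 0:
        return None, float("nan")
    p = _rank_sum_greater(sample, rest_sample)
    return bool(p < alpha), p


def assign_groups(
    flags: dict[str, tuple[bool | None, float]],
    roi_id: int = 0,
) -> FunctionalLabel:
    """Assign a functional group from per-bout-type activity flags.

    forward_component ⇔ active in forward, left and right turns;
    left_steering ⇔ active_left and not active_forward; right_steering
    likewise; anything else (including undefined-markers) is *other*.
    Precedence: forward_component first, so groups are mutually exclusive.
    """
    f, pf = flags.get("forward", (None, float("nan")))
    l, pl = flags.get("left_turn", (None, float("nan")))
    r, pr = flags.get("right_turn", (None, float("nan")))
    if f and l and r:
        group = "forward_component"
    elif l and not f:
        group = "left_steering"
    elif r and not f:
        group = "right_steering"
    else:
        group = "other"
    return FunctionalLabel(
        roi_id=roi_id,
        active_forward=f,
        active_left=l,
        active_right=r,
        p_forward=pf,
        p_left=pl,
        p_right=pr,
        group=group,
    )


def session_passes_inclusion(
    bouts: list[Bout],
    min_bouts: int = 50,
) -> bool:
    """Session inclusion rule: at least ``min_bouts`` swim bouts and at least
    one bout of each category (forward, left turn, right turn)."""
    labels = [b.label for b in bouts]
    return len(bouts) >= min_bouts and all(labels.count(t) >= 1 for t in BOUT_TYPES)
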