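"""Reading and writing the pipeline's tabular formats.

Tail traces and fluorescence tables travel as CSV (NPZ for long sessions);
bouts, episodes and statistics tables as CSV; run summaries and ground truth
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fluo import FluoTrace
from .kinematics import Bout, Episode, StimTrial, TailTrace

__all__ = [
    "read_tail_trace",
    "write_tail_trace",
    "read_fluo_traces",
    "write_fluo_traces",
    "read_stim_trials",
    "write_stim_trials",
    "bouts_to_frame",
    "episodes_to_frame",
    "write_json",
]


def write_tail_trace(trace: TailTrace, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, time_s=trace.time_s, angle_deg=trace.angle_deg, rate_hz=trace.rate_hz)
        return
    df = pd.DataFrame({"time_s": trace.time_s, "angle_deg": trace.angle_deg})
    if trace.curvature is not None:
        for k in range(trace.curvature.shape[0]):
            df[f"seg_{k:02d}"] = trace.curvature[k]
    df.to_csv(path, index=False)


def read_tail_trace(path: str | Path, rate_hz: float | None = None) -> TailTrace:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return TailTrace(z["time_s"], z["angle_deg"], float(z["rate_hz"]))
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    seg_cols = [c for c in df.columns if c.startswith("seg_")]
    curvature = df[seg_cols].to_numpy().T if seg_cols else None
    return TailTrace(t, df["angle_deg"].to_numpy(), rate_hz, curvature=curvature)


def write_fluo_traces(traces: list[FluoTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "roi_id": tr.roi_id,
                    "frame": np.arange(tr.t_s.size),
                    "t_s": tr.t_s,
                    "f_raw": tr.f_raw,
                    "f_neuropil": tr.f_neuropil,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_fluo_traces(path: str | Path) -> list[FluoTrace]:
    df = pd.read_csv(path)
    traces = []
    for roi_id, g in df.groupby("roi_id", sort=True):
        g = g.sort_values("frame")
        t = g["t_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
        traces.append(
            FluoTrace(
                roi_id=int(roi_id),
                t_s=t,
                f_raw=g["f_raw"].to_numpy(),
                f_neuropil=g["f_neuropil"].to_numpy(),
                rate_hz=rate,
            )
        )
    return traces


def write_stim_trials(trials: list[StimTrial], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "stim_id": tr.stim_id,
                "train_start_s": tr.train_start_s,
                "train_end_s": tr.train_end_s,
                "pulse_freq_hz": tr.pulse_freq_hz,
                "intensity_ua": tr.intensity_ua,
                "pulse_width_ms": tr.pulse_width_ms,
            }
            for tr in trials
        ]
    ).to_csv(path, index=False)


def read_stim_trials(path: str | Path) -> list[StimTrial]:
    df = pd.read_csv(path)
    return [
        StimTrial(
            train_start_s=r.train_start_s,
            train_end_s=r.train_end_s,
            pulse_freq_hz=r.pulse_freq_hz,
            intensity_ua=r.intensity_ua,
            pulse_width_ms=r.pulse_width_ms,
            stim_id=int(r.stim_id),
        )
        for r in df.itertuples()
    ]


_BOUT_COLS = [
    "bout_id", "start_s", "end_s", "duration_s", "n_oscillations",
    "max_abs_tba_deg", "median_itbf_hz", "median_itba_deg", "label",
    "provenance", "stim_id",
]
_EP_COLS = [
    "bout_id", "episode_id", "start_s", "end_s", "label", "n_oscillations",
    "max_abs_tba_deg", "median_itbf_hz", "median_itba_deg",
]


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    if not bouts:
        return pd.DataFrame(columns=_BOUT_COLS)
    return pd.DataFrame(
        [
            {
                "bout_id": i,
                "start_s": b.start_s,
                "end_s": b.end_s,
                "duration_s": b.duration_s,
                "n_oscillations": b.n_oscillations,
                "max_abs_tba_deg": b.max_abs_tba_deg,
                "median_itbf_hz": b.median_itbf_hz,
                "median_itba_deg": b.median_itba_deg,
                "label": b.label,
                "provenance": b.provenance,
                "stim_id": b.stim_id,
            }
            for i, b in enumerate(bouts)
        ]
    )


def episodes_to_frame(episodes: list[Episode]) -> pd.DataFrame:
    if not episodes:
        return pd.DataFrame(columns=_EP_COLS)
    return pd.DataFrame(
        [
            {
                "bout_id": e.bout_id,
                "episode_id": i,
                "start_s": e.start_s,
                "end_s": e.end_s,
                "label": e.label,
                "n_oscillations": e.n_oscillations,
                "max_abs_tba_deg": e.max_abs_tba_deg,
                "median_itbf_hz": e.median_itbf_hz,
                "median_itba_deg": e.median_itba_deg,
            }
            for i, e in enumerate(episodes)
        ]
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
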