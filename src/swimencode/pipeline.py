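"""End-to-end orchestration of the three analyses.

``run_stim_pipeline`` (stimulation-recruitment: episodes, forward indices,
pulse responses, reliability, rising slopes), ``run_encoding_pipeline``
(motor-regressor encoding models, forward cluster, forward activity
indices), and ``run_bouttype_pipeline`` (bout-type activity mapping).  A
:class:`RunConfig` carries every tunable with its default; runs are
deterministic given config + seed and write a manifest with the config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import bouttype as bt
from . import fluo, io, kinematics, recruitment, regression, regressors
from .fluo import FluoTrace
from .kinematics import Bout, StimTrial, TailTrace

__all__ = [
    "RunConfig",
    "run_stim_pipeline",
    "run_encoding_pipeline",
    "run_bouttype_pipeline",
    "write_outputs",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KinematicsConfig(_Section):
    min_amp_deg: float = 5.0
    motion_threshold_deg: float = 3.0
    min_quiet_s: float = 0.100
    min_duration_s: float = 0.050
    large_thresh_deg: float = 25.0
    split_gap_s: float = 0.100
    min_forward_osc: int = 3
    post_stim_exclude_s: float = 60.0
    site_pulse_freq_hz: float = 10.0
    site_intensity_min_ua: float = 1.0
    site_intensity_max_ua: float = 2.0


class FluoConfig(_Section):
    neuropil_factor: float = 0.7
    baseline_mode: str = "inactivity_median"
    baseline_percentile: float = 10.0
    inactivity_s: float = 3.0
    smooth_mode: str = "running_average_3"
    decay_s: float = 1.8
    spike_solver: str = "nnls"


class RecruitmentConfig(_Section):
    response_window_s: float = 3.0
    baseline_window_s: float = 1.5
    response_n_sigma: float = 3.0
    episode_n_sigma: float = 5.0
    n_clusters: int = 4
    fai_mode: str = "max"


class RegressionConfig(_Section):
    kernel_tau_s: float = 1.5
    n_perm: int = 999
    alpha_level: float = 0.05


class BoutTypeConfig(_Section):
    alpha: float = 0.01
    pre_bout_s: float = 0.2
    rest_epsilon_deg: float = 0.5
    min_bouts: int = 50


class RunConfig(_Section):
    seed: int = 0
    alignment_offset_s: float = 0.0
    max_clock_drift_frames: float = 1.0
    kinematics: KinematicsConfig = KinematicsConfig()
    fluo: FluoConfig = FluoConfig()
    recruitment: RecruitmentConfig = RecruitmentConfig()
    regression: RegressionConfig = RegressionConfig()
    bouttype: BoutTypeConfig = BoutTypeConfig()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _check_alignment(trace: TailTrace, fluo_traces: list[FluoTrace], config: RunConfig) -> None:
    if not fluo_traces:
        return
    t = fluo_traces[0].t_s
    frame_dt = 1.0 / fluo_traces[0].rate_hz
    drift = abs(t[0] - (trace.time_s[0] + config.alignment_offset_s))
    if drift > config.max_clock_drift_frames * frame_dt:
        raise ValueError("misaligned clocks between behavior and imaging")


def _find_inactivity_interval(
    trace: TailTrace, bouts: list[Bout], fl: FluoTrace, min_s: float
) -> tuple[int, int]:
    """Longest bout-free interval (in imaging frames), at least ``min_s`` long.

    Falls back to the start of the recording if the session has no quiet
    stretch (callers then use the low-percentile baseline instead).
    """
    t = fl.t_s
    busy = np.zeros(t.size, dtype=bool)
    for b in bouts:
        busy |= (t >= b.start_s - 0.5) & (t <= b.end_s + 2.0)
    best, cur, best_len = 0, None, 0
    i = 0
    while i <= t.size:
        if i < t.size and not busy[i]:
            if cur is None:
                cur = i
        else:
            if cur is not None and i - cur > best_len:
                best, best_len = cur, i - cur
            cur = None
        i += 1
    need = int(np.ceil(min_s * fl.rate_hz))
    if best_len < need:
        return 0, min(need, t.size)
    return best, best + best_len


def preprocess_fluo(
    trace: TailTrace,
    fluo_traces: list[FluoTrace],
    bouts: list[Bout],
    config: RunConfig,
) -> list[FluoTrace]:
    """ΔF/F, noise σ and smoothing for every ROI (in place)."""
    cfg = config.fluo
    for fl in fluo_traces:
        interval = _find_inactivity_interval(trace, bouts, fl, cfg.inactivity_s)
        fl.dff, fl.f0 = fluo.neuropil_correct_and_dff(
            fl.f_raw,
            fl.f_neuropil,
            neuropil_factor=cfg.neuropil_factor,
            baseline_mode=cfg.baseline_mode,
            inactivity_interval=interval,
            percentile=cfg.baseline_percentile,
        )
        fl.noise_sigma = fluo.estimate_noise(fl.dff, interval, fl.rate_hz)
        if np.any(fl.artifact_mask):
            fl.dff = fluo.mask_and_interpolate(fl.dff, np.flatnonzero(fl.artifact_mask))
    return fluo_traces


def segment_behavior(
    trace: TailTrace, stim_trials: list[StimTrial], config: RunConfig
) -> tuple[list[Bout], pd.DataFrame, pd.DataFrame]:
    kc = config.kinematics
    bouts = kinematics.extract_bouts(
        trace,
        motion_threshold_deg=kc.motion_threshold_deg,
        min_quiet_s=kc.min_quiet_s,
        min_duration_s=kc.min_duration_s,
        min_amp_deg=kc.min_amp_deg,
    )
    kinematics.tag_provenance(bouts, stim_trials, post_window_s=kc.post_stim_exclude_s)
    episodes = []
    for i, b in enumerate(bouts):
        episodes.extend(
            kinematics.segment_episodes(
                b,
                trace,
                bout_id=i,
                large_thresh_deg=kc.large_thresh_deg,
                split_gap_s=kc.split_gap_s,
                min_forward_osc=kc.min_forward_osc,
            )
        )
    return bouts, io.bouts_to_frame(bouts), io.episodes_to_frame(episodes)


def run_stim_pipeline(
    trace: TailTrace,
    fluo_traces: list[FluoTrace],
    stim_trials: list[StimTrial],
    config: RunConfig,
) -> dict[str, pd.DataFrame | dict]:
    """Stimulation-recruitment analysis: behavior + pulse responses."""
    _check_alignment(trace, fluo_traces, config)
    bouts, bout_df, ep_df = segment_behavior(trace, stim_trials, config)
    kc, rc = config.kinematics, config.recruitment

    fi_rows = []
    for tr in stim_trials:
        in_train = ep_df[(ep_df.start_s >= tr.train_start_s) & (ep_df.start_s < tr.train_end_s)]
        if len(in_train):
            nf = int((in_train.label == "forward").sum())
            ns = int((in_train.label == "struggle").sum())
            fi_rows.append(
                {
                    "stim_id": tr.stim_id,
                    "pulse_freq_hz": tr.pulse_freq_hz,
                    "intensity_ua": tr.intensity_ua,
                    "forward_index": (nf - ns) / len(in_train),
                }
            )
    fi_df = pd.DataFrame(fi_rows)
    site_median = float("nan")
    if len(fi_df):
        qual = fi_df[
            (np.abs(fi_df.pulse_freq_hz - kc.site_pulse_freq_hz) < 1e-6)
            & (fi_df.intensity_ua >= kc.site_intensity_min_ua)
            & (fi_df.intensity_ua <= kc.site_intensity_max_ua)
        ]
        if len(qual):
            site_median = float(qual.forward_index.median())

    preprocess_fluo(trace, fluo_traces, bouts, config)
    resp_rows, rel_rows = [], []
    by_intensity: dict[int, list[tuple[float, list[bool]]]] = {}
    for fl in fluo_traces:
        per_int: dict[float, list[bool]] = {}
        for tr in stim_trials:
            pr = recruitment.detect_pulse_response(
                fl,
                tr.train_start_s,
                stim_id=tr.stim_id,
                intensity_ua=tr.intensity_ua,
                response_window_s=rc.response_window_s,
                baseline_window_s=rc.baseline_window_s,
                n_sigma=rc.response_n_sigma,
            )
            slope = np.nan
            if pr.responded:
                try:
                    t_on, t_pk = recruitment.onset_peak_detect(fl, tr.train_start_s)
                    slope = recruitment.rising_slope(fl, t_on, t_pk)
                except ValueError:
                    pass
            resp_rows.append(
                {
                    "roi_id": fl.roi_id,
                    "stim_id": tr.stim_id,
                    "intensity_ua": tr.intensity_ua,
                    "responded": pr.responded,
                    "peak_dff": pr.peak_dff,
                    "baseline_dff": pr.baseline_dff,
                    "rising_slope": slope,
                }
            )
            per_int.setdefault(tr.intensity_ua, []).append(pr.responded)
        by_intensity[fl.roi_id] = sorted(per_int.items())
        if by_intensity[fl.roi_id]:
            lab = recruitment.classify_reliability(by_intensity[fl.roi_id], roi_id=fl.roi_id)
            rel_rows.append(
                {
                    "roi_id": fl.roi_id,
                    "label": lab.label,
                    "threshold_intensity_ua": lab.threshold_intensity_ua,
                }
            )

    return {
        "bouts": bout_df,
        "episodes": ep_df,
        "forward_indices": fi_df,
        "site_median_forward_index": {"value": site_median},
        "pulse_responses": pd.DataFrame(resp_rows),
        "reliability": pd.DataFrame(rel_rows),
        "manifest": _manifest(config),
    }


def run_encoding_pipeline(
    trace: TailTrace,
    fluo_traces: list[FluoTrace],
    config: RunConfig,
    stim_trials: list[StimTrial] | None = None,
) -> dict[str, pd.DataFrame | dict]:
    """Encoding-model analysis: four-regressor OLS + permutation tests,
    forward cluster and per-ROI forward activity indices."""
    _check_alignment(trace, fluo_traces, config)
    bouts, bout_df, ep_df = segment_behavior(trace, stim_trials or [], config)
    preprocess_fluo(trace, fluo_traces, bouts, config)
    rc, gc = config.recruitment, config.regression

    bends = kinematics.detect_bends(trace, min_amp_deg=config.kinematics.min_amp_deg)
    frame_times = fluo_traces[0].t_s
    rs = regressors.build_regressor_set(
        trace, bends, frame_times, tau_s=gc.kernel_tau_s, bouts=bouts
    )
    rows = []
    for i, fl in enumerate(fluo_traces):
        fit = regression.fit_encoding_model(fl.dff, rs, mask=fl.artifact_mask, roi_id=fl.roi_id)
        fit = regression.permutation_significance(
            fl.dff,
            rs,
            fit,
            n_perm=gc.n_perm,
            seed=config.seed + i,
            tau_s=gc.kernel_tau_s,
            rate_hz=fl.rate_hz,
            alpha_level=gc.alpha_level,
            mask=fl.artifact_mask,
        )
        row = {"roi_id": fl.roi_id, "r2": fit.r2, "seed": fit.seed}
        for k, name in enumerate(fit.coef_names):
            row[f"alpha_{name}"] = float(fit.alphas[k])
        for k, name in enumerate(fit.coef_names[1:]):
            row[f"p_{name}"] = float(fit.p_perm[k])
            row[f"sig_{name}"] = bool(fit.significant[k])
        rows.append(row)
    reg_df = pd.DataFrame(rows)

    fwd_eps = [e for e in _episodes_from_frame(ep_df) if e.label == "forward"]
    str_eps = [e for e in _episodes_from_frame(ep_df) if e.label == "struggle"]
    cluster_df = pd.DataFrame()
    if fwd_eps and str_eps and len(fluo_traces) >= rc.n_clusters:
        try:
            labels, fwd_id, fai = recruitment.cluster_forward(
                fluo_traces, fwd_eps, str_eps, n_clusters=rc.n_clusters
            )
            cluster_df = pd.DataFrame(
                {
                    "roi_id": [fl.roi_id for fl in fluo_traces],
                    "cluster": labels,
                    "is_forward_cluster": labels == fwd_id,
                    "forward_activity_index": fai,
                }
            )
        except ValueError:
            pass
    return {
        "bouts": bout_df,
        "episodes": ep_df,
        "regression": reg_df,
        "clusters": cluster_df,
        "manifest": _manifest(config),
    }


def run_bouttype_pipeline(
    trace: TailTrace,
    fluo_traces: list[FluoTrace],
    config: RunConfig,
) -> dict[str, pd.DataFrame | dict]:
    """Bout-type mapping: per-neuron activity flags and functional groups."""
    _check_alignment(trace, fluo_traces, config)
    bouts, bout_df, ep_df = segment_behavior(trace, [], config)
    bc = config.bouttype
    included = bt.session_passes_inclusion(bouts, min_bouts=bc.min_bouts)
    if not included:
        return {
            "bouts": bout_df,
            "labels": pd.DataFrame(),
            "proportions": {"included": False, "reason": "fewer than required bouts per class"},
            "manifest": _manifest(config),
        }
    preprocess_fluo(trace, fluo_traces, bouts, config)
    by_type = {t: [b for b in bouts if b.label == t] for t in bt.BOUT_TYPES}
    rows = []
    for fl in fluo_traces:
        fl.spike_rate = fluo.infer_spike_rate(
            fl.dff, decay_s=config.fluo.decay_s, rate_hz=fl.rate_hz, solver=config.fluo.spike_solver
        )
        rest = bt.rest_spike_sample(
            fl.spike_rate, fl.t_s, trace, bouts, rest_epsilon_deg=bc.rest_epsilon_deg
        )
        flags = {
            t: bt.detect_active(
                fl.spike_rate, fl.t_s, by_type[t], rest, alpha=bc.alpha, pre_bout_s=bc.pre_bout_s
            )
            for t in bt.BOUT_TYPES
        }
        lab = bt.assign_groups(flags, roi_id=fl.roi_id)
        rows.append(
            {
                "roi_id": fl.roi_id,
                "active_forward": lab.active_forward,
                "active_left": lab.active_left,
                "active_right": lab.active_right,
                "p_forward": lab.p_forward,
                "p_left": lab.p_left,
                "p_right": lab.p_right,
                "group": lab.group,
            }
        )
    label_df = pd.DataFrame(rows)
    n = len(label_df)
    proportions = {
        "included": True,
        **{
            g: float((label_df.group == g).mean()) if n else 0.0
            for g in ("forward_component", "left_steering", "right_steering", "other")
        },
    }
    return {
        "bouts": bout_df,
        "labels": label_df,
        "proportions": proportions,
        "manifest": _manifest(config),
    }


def _episodes_from_frame(ep_df: pd.DataFrame):
    from .kinematics import Episode

    return [
        Episode(bout_id=int(r.bout_id), start_s=r.start_s, end_s=r.end_s, label=r.label)
        for r in ep_df.itertuples()
    ]


def _manifest(config: RunConfig) -> dict:
    import swimencode

    return {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": swimencode.__version__,
    }


def write_outputs(results: dict, outdir: str | Path) -> None:
    """Write a pipeline result dict to CSV/JSON files, deterministically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
        else:
            io.write_json(obj, outdir / f"{name}.json")
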