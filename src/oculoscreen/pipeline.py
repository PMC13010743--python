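"""End-to-end extraction: raw cohort gaze -> trial feature table + QC table.

Thin orchestration over :mod:`preprocess`, :mod:`events` and
:mod:`features`; all scientific parameters live in the config dataclasses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import (
    ALL_FEATURES,
    FeatureConfig,
    task1_features,
    task2_features,
    task3_features,
)
from .preprocess import (
    PreprocessConfig,
    ScreenGeometry,
    preprocess_trial,
    px_to_deg,
    resolve_amblyopic_side,
)
from .simulate import Cohort, make_pursuit_trajectory


def _target_arrays(
    t: np.ndarray, sched: dict, sampling_rate: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Aligned target position/velocity for a pursuit trial segment.

    Before motion onset the target is the stationary fixation point at the
    trajectory start; afterwards it follows the analytic sinusoidal path.
    """
    onset = sched["onset_s"] + sched["motion_onset_offset_s"]
    duration = sched["offset_s"] - onset
    traj = make_pursuit_trajectory(
        duration, sampling_rate, tuple(sched["frequencies"]), tuple(sched["phases"])
    )
    pos = np.empty((len(t), 2))
    vel = np.zeros((len(t), 2))
    pre = t < onset - 1e-9
    pos[pre] = traj.pos[0]
    idx = np.clip(np.round((t[~pre] - onset) * sampling_rate).astype(int), 0, len(traj.pos) - 1)
    pos[~pre] = traj.pos[idx]
    vel[~pre] = traj.vel[idx]
    return pos, vel, onset


def extract_features(
    cohort: Cohort,
    stream_kind: str = "cyclopean",
    preprocess_config: PreprocessConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full preprocessing + feature chain over a cohort.

    Returns ``(features, qc)``: one feature row per (subject, task, trial)
    with NaN for features the trial could not provide (excluded trials have
    all-NaN features), and a QC table with per-trial invalid fractions and
    retention flags.
    """
    pcfg = preprocess_config or PreprocessConfig()
    fcfg = feature_config or FeatureConfig()
    geometry = cohort.spec.screen
    fs = cohort.spec.sampling_rate
    feat_rows: list[dict] = []
    qc_rows: list[dict] = []

    gaze = cohort.gaze
    for (sid, task_id), task_df in gaze.groupby(["subject_id", "task_id"], sort=True):
        side = resolve_amblyopic_side(cohort.clinical.loc[sid])
        group = task_df["group"].iloc[0]
        sched_by_trial = {s["trial_id"]: s for s in cohort.schedules[(sid, task_id)]}
        for trial_id, tdf in task_df.groupby("trial_id", sort=True):
            t = tdf["t_s"].to_numpy()
            l_deg = px_to_deg(tdf[["lx_px", "ly_px"]].to_numpy(), geometry)
            r_deg = px_to_deg(tdf[["rx_px", "ry_px"]].to_numpy(), geometry)
            sched = sched_by_trial[trial_id]
            seg = preprocess_trial(
                sid,
                task_id,
                trial_id,
                t,
                l_deg,
                r_deg,
                tdf["l_valid"].to_numpy(bool),
                tdf["r_valid"].to_numpy(bool),
                geometry,
                pcfg,
                stream_kind,
                side,
                meta=sched,
            )
            qc_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "task_id": task_id,
                    "trial_id": trial_id,
                    "invalid_fraction": seg.invalid_fraction,
                    "retained": seg.retained,
                }
            )
            row: dict = {
                "subject_id": sid,
                "group": group,
                "task_id": task_id,
                "trial_id": trial_id,
                "orientation_deg": sched.get("orientation_deg", np.nan),
                "contrast": sched.get("contrast", np.nan),
            }
            if not seg.retained:
                row.update({name: np.nan for name in ALL_FEATURES})
                feat_rows.append(row)
                continue
            if task_id == 1:
                row.update(task1_features(seg, geometry, fcfg))
            elif task_id == 2:
                row.update(task2_features(seg, geometry, sched["orientation_deg"], t[0], fcfg))
            else:
                target_pos, target_vel, onset = _target_arrays(t, sched, fs)
                row.update(task3_features(seg, target_pos, target_vel, onset, fcfg))
            feat_rows.append(row)
    features = pd.DataFrame(feat_rows)
    qc = pd.DataFrame(qc_rows)
    return features, qc


def extract_event_tables(
    cohort: Cohort,
    stream_kind: str = "cyclopean",
    preprocess_config: PreprocessConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Columnar event tables for every retained trial.

    Returns (fixations, events): fixations with
    ``trial_id, t_start, t_end, cx, cy, rms, cell`` and saccade-like events
    with ``trial_id, onset, offset, amplitude, class`` (both keyed by
    subject and task as well).
    """
    from .events import idt_fixations, saccade_like_events
    from .features import grid_cell

    pcfg = preprocess_config or PreprocessConfig()
    fcfg = feature_config or FeatureConfig()
    geometry = cohort.spec.screen
    fix_rows: list[dict] = []
    ev_rows: list[dict] = []
    for (sid, task_id), task_df in cohort.gaze.groupby(["subject_id", "task_id"], sort=True):
        side = resolve_amblyopic_side(cohort.clinical.loc[sid])
        for trial_id, tdf in task_df.groupby("trial_id", sort=True):
            seg = preprocess_trial(
                sid,
                task_id,
                trial_id,
                tdf["t_s"].to_numpy(),
                px_to_deg(tdf[["lx_px", "ly_px"]].to_numpy(), geometry),
                px_to_deg(tdf[["rx_px", "ry_px"]].to_numpy(), geometry),
                tdf["l_valid"].to_numpy(bool),
                tdf["r_valid"].to_numpy(bool),
                geometry,
                pcfg,
                stream_kind,
                side,
            )
            if not seg.retained:
                continue
            for f in idt_fixations(seg, fcfg.idt_dispersion_deg, fcfg.idt_min_duration_ms):
                col, row = grid_cell(f.centroid, geometry, fcfg.grid_cols, fcfg.grid_rows)
                fix_rows.append(
                    {
                        "subject_id": sid,
                        "task_id": task_id,
                        "trial_id": trial_id,
                        "t_start": f.t_start,
                        "t_end": f.t_end,
                        "cx": f.centroid[0],
                        "cy": f.centroid[1],
                        "rms": f.rms_dispersion,
                        "cell": f"{col},{row}",
                    }
                )
            for e in saccade_like_events(
                seg,
                fcfg.event_speed_threshold,
                fcfg.small_band,
                fcfg.catch_up_min_amplitude,
                fcfg.event_speed_signal,
            ):
                ev_rows.append(
                    {
                        "subject_id": sid,
                        "task_id": task_id,
                        "trial_id": trial_id,
                        "onset": e.onset_idx,
                        "offset": e.offset_idx,
                        "amplitude": e.amplitude,
                        "class": e.klass,
                    }
                )
    return pd.DataFrame(fix_rows), pd.DataFrame(ev_rows)
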