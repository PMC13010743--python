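"""Trial-level oculomotor feature extraction and subject-level aggregation.

Task 1 (free visual search): fixation statistics, refixations, inter-fixation
saccade amplitude, regressions against the predominant horizontal scanning
direction, and scan-path transition entropy on a uniform display grid.

Task 2 (central grating viewing): fixation latency into a circular ROI,
net drift projected on the stimulus orientation axis, convex-hull dispersion
of in-ROI samples, and the small-corrective-event rate.

Task 3 (2-D sinusoidal pursuit): tracking error, velocity pursuit gain,
catch-up saccade count and pursuit onset latency against the analytically
known target trajectory.

All trial vectors share one fixed-length schema; features that a trial
cannot provide are NaN and are median-imputed inside model training folds,
never here.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .events import (
    FixationEvent,
    catch_up_saccades,
    idt_fixations,
    pursuit_onset_latency,
    saccade_like_events,
)
from .preprocess import ScreenGeometry, TrialSegment

TASK1_FEATURES = [
    "fix_duration_mean_ms",
    "fix_duration_sd_ms",
    "fix_rms_dispersion_deg",
    "refixation_count",
    "saccade_amplitude_mean_deg",
    "regression_count",
    "scanpath_entropy_bits",
]
TASK2_FEATURES = [
    "fixation_latency_ms",
    "directional_drift_deg",
    "hull_dispersion_deg2",
    "small_corrective_rate_per_min",
]
TASK3_FEATURES = [
    "tracking_error_deg",
    "pursuit_gain",
    "catch_up_count",
    "pursuit_onset_latency_ms",
]
ALL_FEATURES = TASK1_FEATURES + TASK2_FEATURES + TASK3_FEATURES
TASK_FEATURES = {1: TASK1_FEATURES, 2: TASK2_FEATURES, 3: TASK3_FEATURES}
META_COLUMNS = ["subject_id", "group", "task_id", "trial_id", "orientation_deg", "contrast"]


@dataclass(frozen=True)
class FeatureConfig:
    grid_cols: int = 8
    grid_rows: int = 6
    idt_dispersion_deg: float = 1.0
    idt_min_duration_ms: float = 100.0
    refixation_radius_deg: float = 1.0
    roi_radius_deg: float = 2.0
    event_speed_threshold: float = 60.0
    small_band: tuple[float, float] = (0.3, 1.0)
    catch_up_min_amplitude: float = 1.5
    gain_gate_deg_s: float = 2.0
    onset_speed_gate: float = 5.0
    onset_run_length: int = 3
    event_speed_signal: str = "raw_forward"


def grid_cell(
    point: tuple[float, float], geometry: ScreenGeometry, cols: int = 8, rows: int = 6
) -> tuple[int, int]:
    """Map a degree-space point to its (col, row) on the uniform display grid."""
    hw, hh = geometry.half_width_deg, geometry.half_height_deg
    col = int(np.clip((point[0] + hw) / (2 * hw) * cols, 0, cols - 1e-9))
    row = int(np.clip((point[1] + hh) / (2 * hh) * rows, 0, rows - 1e-9))
    return col, row


def transition_entropy(cells: list[tuple[int, int]]) -> float:
    """Plug-in Shannon entropy (bits) of the (from, to) transition pairs.

    The empirical distribution over observed transition pairs is used
    directly (maximum-likelihood estimate, no bias correction).
    """
    if len(cells) < 2:
        return float("nan")
    counter = Counter(zip(cells[:-1], cells[1:]))
    counts = np.array(list(counter.values()), float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _nan_row(task_id: int) -> dict[str, float]:
    return {name: float("nan") for name in ALL_FEATURES}


def task1_features(
    segment: TrialSegment,
    geometry: ScreenGeometry,
    config: FeatureConfig = FeatureConfig(),
    fixations: list[FixationEvent] | None = None,
) -> dict[str, float]:
    """Free-viewing scan features from the fixation sequence.

    Saccade amplitude is the Euclidean distance between successive fixation
    centroids; a regression is an inter-fixation step whose horizontal
    component opposes the predominant (sign of summed) horizontal direction;
    a refixation is a fixation whose centroid returns within the refixation
    radius of any non-adjacent earlier centroid. Transition-based features
    are NaN with fewer than two fixations.
    """
    out = _nan_row(1)
    if fixations is None:
        fixations = idt_fixations(segment, config.idt_dispersion_deg, config.idt_min_duration_ms)
    if not fixations:
        return out
    durations = np.array([f.duration_ms for f in fixations])
    out["fix_duration_mean_ms"] = float(durations.mean())
    out["fix_duration_sd_ms"] = float(durations.std(ddof=1)) if len(durations) > 1 else float("nan")
    out["fix_rms_dispersion_deg"] = float(np.mean([f.rms_dispersion for f in fixations]))
    centroids = np.array([f.centroid for f in fixations])
    refix = 0
    for k in range(len(centroids)):
        earlier = centroids[: max(k - 1, 0)]  # exclude the immediately preceding fixation
        if len(earlier) and np.any(
            np.linalg.norm(earlier - centroids[k], axis=1) <= config.refixation_radius_deg
        ):
            refix += 1
    out["refixation_count"] = float(refix)
    if len(fixations) < 2:
        out["regression_count"] = 0.0
        return out
    steps = np.diff(centroids, axis=0)
    out["saccade_amplitude_mean_deg"] = float(np.linalg.norm(steps, axis=1).mean())
    predominant = np.sign(steps[:, 0].sum())
    if predominant == 0:
        regressions = 0
    else:
        regressions = int(np.sum(np.sign(steps[:, 0]) == -predominant))
    out["regression_count"] = float(regressions)
    cells = [grid_cell(f.centroid, geometry, config.grid_cols, config.grid_rows) for f in fixations]
    out["scanpath_entropy_bits"] = transition_entropy(cells)
    return out


def task2_features(
    segment: TrialSegment,
    geometry: ScreenGeometry,
    orientation_deg: float,
    stimulus_onset_s: float,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Grating-viewing stability features within a circular ROI at screen center."""
    out = _nan_row(2)
    fixations = idt_fixations(segment, config.idt_dispersion_deg, config.idt_min_duration_ms)
    # latency: onset to the first fixation whose centroid lies inside the ROI
    for f in fixations:
        if math.hypot(*f.centroid) <= config.roi_radius_deg and f.t_start >= stimulus_onset_s:
            out["fixation_latency_ms"] = (f.t_start - stimulus_onset_s) * 1000.0
            break
    pos = segment.smoothed
    finite = np.isfinite(pos).all(axis=1)
    if finite.sum() >= 2:
        first = pos[finite][0]
        last = pos[finite][-1]
        u = np.array([math.cos(math.radians(orientation_deg)), math.sin(math.radians(orientation_deg))])
        out["directional_drift_deg"] = float(abs(np.dot(last - first, u)))
    in_roi = finite & (np.linalg.norm(np.nan_to_num(pos), axis=1) <= config.roi_radius_deg)
    roi_pts = pos[in_roi]
    if len(roi_pts) >= 1:
        out["hull_dispersion_deg2"] = _hull_area(roi_pts)
    events = saccade_like_events(
        segment,
        config.event_speed_threshold,
        config.small_band,
        config.catch_up_min_amplitude,
        config.event_speed_signal,
    )
    n_small = sum(1 for e in events if e.klass == "small_corrective")
    duration_min = (segment.t[-1] - segment.t[0]) / 60.0 if len(segment.t) > 1 else float("nan")
    out["small_corrective_rate_per_min"] = n_small / duration_min if duration_min else float("nan")
    return out


def _hull_area(points: np.ndarray) -> float:
    """Convex hull area; degenerate point sets (collinear, <3 points) give 0."""
    if len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0


def task3_features(
    segment: TrialSegment,
    target_pos: np.ndarray,
    target_vel: np.ndarray,
    motion_onset_s: float,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Pursuit-fidelity features against the analytic target trajectory.

    Tracking error: mean |gaze - target| over valid samples. Pursuit gain:
    median gaze-speed / target-speed ratio over samples where the target is
    faster than the gain gate. Catch-up count and onset latency come from the
    event layer.
    """
    out = _nan_row(3)
    if target_pos.shape != segment.pos.shape:
        raise ValueError("target trajectory must be aligned frame by frame with gaze")
    pos = segment.smoothed
    finite = np.isfinite(pos).all(axis=1)
    motion = segment.t >= motion_onset_s
    sel = finite & motion
    if sel.sum() > 0:
        out["tracking_error_deg"] = float(
            np.linalg.norm(pos[sel] - target_pos[sel], axis=1).mean()
        )
    target_speed = np.linalg.norm(target_vel, axis=1)
    gate = sel & (target_speed > config.gain_gate_deg_s) & np.isfinite(segment.speed)
    if gate.sum() > 0:
        out["pursuit_gain"] = float(np.median(segment.speed[gate] / target_speed[gate]))
    events = saccade_like_events(
        segment,
        config.event_speed_threshold,
        config.small_band,
        config.catch_up_min_amplitude,
        config.event_speed_signal,
    )
    out["catch_up_count"] = float(
        catch_up_saccades(events, segment.pos, target_pos, config.catch_up_min_amplitude)
    )
    out["pursuit_onset_latency_ms"] = pursuit_onset_latency(
        segment, target_vel, motion_onset_s, config.onset_speed_gate, config.onset_run_length
    )
    return out


def aggregate_subject(features: pd.DataFrame) -> pd.DataFrame:
    """Subject-level aggregates: per-feature median over retained trials.

    Task 2 features are first medianed within each stimulus orientation and
    then averaged across orientations, so that unbalanced orientation
    retention cannot bias the summary. Returns one row per (subject, group)
    with all feature columns (NaN when a subject has no retained trial with
    that feature).
    """
    rows = []
    for (sid, grp), sub in features.groupby(["subject_id", "group"], sort=True):
        rec: dict[str, object] = {"subject_id": sid, "group": grp}
        for task_id, cols in TASK_FEATURES.items():
            tsub = sub[sub["task_id"] == task_id]
            if len(tsub) == 0:
                for c in cols:
                    rec[c] = np.nan
                continue
            if task_id == 2 and tsub["orientation_deg"].notna().any():
                per_ori = tsub.groupby("orientation_deg")[cols].median()
                agg = per_ori.mean()
            else:
                agg = tsub[cols].median()
            for c in cols:
                rec[c] = agg[c]
        rows.append(rec)
    return pd.DataFrame(rows)


def orientation_curves(features: pd.DataFrame) -> pd.DataFrame:
    """Orientation-resolved group summaries of the Task 2 features."""
    t2 = features[features["task_id"] == 2]
    per_subject = t2.groupby(["group", "subject_id", "orientation_deg"])[TASK2_FEATURES].median()
    return per_subject.groupby(["group", "orientation_deg"]).agg(["mean", "std"])
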