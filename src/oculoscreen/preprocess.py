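"""Gaze preprocessing: raw binocular pixel streams to cleaned trial segments.

The chain is: pixel -> degree conversion about the screen center, binocular
stream construction (cyclopean by default), validity flagging (device flags,
off-display samples, kinematically implausible jumps, blink-edge margin),
linear bridging of short gaps, trial-level quality control, and
Savitzky-Golay smoothing with central-difference velocity.

All positions are handled in degrees of visual angle with the origin at the
screen center, x rightward and y upward. Pixel input follows the raster
convention (origin top-left, y down).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

STREAM_KINDS = ("cyclopean", "amblyopic_eye", "fellow_eye", "both_valid_only")


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry used for the angular conversion.

    Defaults describe a 24-inch 16:9 panel at 1920x1080 viewed from 60 cm.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_cm: float = 53.1
    height_cm: float = 29.9
    distance_cm: float = 60.0

    def __post_init__(self):
        if self.distance_cm <= 0:
            raise ValueError("viewing distance must be positive")
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("physical screen size must be positive")

    @property
    def half_width_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.width_cm / 2.0, self.distance_cm)))

    @property
    def half_height_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.height_cm / 2.0, self.distance_cm)))


@dataclass(frozen=True)
class PreprocessConfig:
    velocity_limit_deg_s: float = 1000.0
    margin_frames: int = 1
    max_gap_ms: float = 200.0
    qc_threshold: float = 0.30
    sg_window: int = 5
    sg_polyorder: int = 2
    # velocity signal used by the 60 deg/s event gate downstream:
    # "raw_forward" (pre-smoothing forward difference) or "smoothed_central"
    event_speed_signal: str = "raw_forward"
    # velocity estimator: "savgol" or "lowpass" (moving-average) before the
    # central difference; both are part of the robustness grid
    smoother: str = "savgol"


@dataclass
class TrialSegment:
    """One cleaned, smoothed monocular-or-cyclopean gaze trace for one trial."""

    subject_id: str
    task_id: int
    trial_id: int
    t: np.ndarray
    pos: np.ndarray  # (n, 2) deg, NaN where missing (post interpolation)
    valid: np.ndarray  # per-sample validity after flagging (pre interpolation)
    smoothed: np.ndarray  # (n, 2) deg
    vel: np.ndarray  # (n, 2) deg/s, NaN at run edges / missing samples
    speed: np.ndarray  # Euclidean norm of vel
    raw_speed: np.ndarray  # forward-difference speed of pos (pre-smoothing)
    invalid_fraction: float
    retained: bool
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) + float(np.median(np.diff(self.t))) if len(self.t) > 1 else 0.0


def px_to_deg(pos_px: np.ndarray, geometry: ScreenGeometry) -> np.ndarray:
    """Convert raster pixel coordinates to signed degrees about screen center.

    Per-axis arctangent of the physical offset over the viewing distance;
    the screen center maps to (0, 0) and y points upward.
    """
    pos_px = np.asarray(pos_px, float)
    pitch_x = geometry.width_cm / geometry.width_px
    pitch_y = geometry.height_cm / geometry.height_px
    x_cm = (pos_px[..., 0] - geometry.width_px / 2.0) * pitch_x
    y_cm = (geometry.height_px / 2.0 - pos_px[..., 1]) * pitch_y
    out = np.empty_like(pos_px)
    out[..., 0] = np.degrees(np.arctan2(x_cm, geometry.distance_cm))
    out[..., 1] = np.degrees(np.arctan2(y_cm, geometry.distance_cm))
    return out


def deg_to_px(pos_deg: np.ndarray, geometry: ScreenGeometry) -> np.ndarray:
    """Inverse of :func:`px_to_deg` (used by the simulator's pixel emission)."""
    pos_deg = np.asarray(pos_deg, float)
    pitch_x = geometry.width_cm / geometry.width_px
    pitch_y = geometry.height_cm / geometry.height_px
    x_cm = np.tan(np.radians(pos_deg[..., 0])) * geometry.distance_cm
    y_cm = np.tan(np.radians(pos_deg[..., 1])) * geometry.distance_cm
    out = np.empty_like(pos_deg)
    out[..., 0] = x_cm / pitch_x + geometry.width_px / 2.0
    out[..., 1] = geometry.height_px / 2.0 - y_cm / pitch_y
    return out


def build_stream(
    l_pos: np.ndarray,
    r_pos: np.ndarray,
    l_valid: np.ndarray,
    r_valid: np.ndarray,
    stream_kind: str = "cyclopean",
    amblyopic_side: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Combine the two eye streams into a single analysis stream.

    cyclopean: sample-wise mean when both eyes are valid, the single valid
    eye otherwise, missing when neither is valid. amblyopic_eye/fellow_eye
    select one eye (for controls the caller resolves "amblyopic" to the
    worse-acuity eye). both_valid_only keeps only timestamps with two valid
    eyes.

    Returns (positions (n,2) with NaN where invalid, validity mask).
    """
    if stream_kind not in STREAM_KINDS:
        raise ValueError(f"unknown stream_kind {stream_kind!r}; expected one of {STREAM_KINDS}")
    l_pos = np.asarray(l_pos, float)
    r_pos = np.asarray(r_pos, float)
    l_valid = np.asarray(l_valid, bool)
    r_valid = np.asarray(r_valid, bool)

    if stream_kind in ("amblyopic_eye", "fellow_eye"):
        if amblyopic_side not in ("L", "R"):
            raise ValueError("amblyopic_side ('L'/'R') required for eye-specific streams")
        use_left = (amblyopic_side == "L") == (stream_kind == "amblyopic_eye")
        pos = l_pos.copy() if use_left else r_pos.copy()
        valid = l_valid.copy() if use_left else r_valid.copy()
    elif stream_kind == "both_valid_only":
        valid = l_valid & r_valid
        pos = (l_pos + r_pos) / 2.0
    else:  # cyclopean
        valid = l_valid | r_valid
        pos = np.full_like(l_pos, np.nan)
        both = l_valid & r_valid
        pos[both] = (l_pos[both] + r_pos[both]) / 2.0
        only_l = l_valid & ~r_valid
        pos[only_l] = l_pos[only_l]
        only_r = r_valid & ~l_valid
        pos[only_r] = r_pos[only_r]
    pos = pos.copy()
    pos[~valid] = np.nan
    return pos, valid


def forward_speed(t: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Forward-difference speed; entry i is the speed over [i, i+1], NaN last."""
    n = len(t)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    dt = np.diff(t)
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    out[:-1] = step / dt
    return out


def flag_invalid(
    t: np.ndarray,
    pos: np.ndarray,
    valid: np.ndarray,
    geometry: ScreenGeometry,
    config: PreprocessConfig = PreprocessConfig(),
) -> np.ndarray:
    """Validity mask after the kinematic-plausibility and display screens.

    Marks device-invalid samples, samples off the display region, both
    endpoints of any inter-sample step whose raw forward-difference speed
    exceeds the limit, and every sample within ``margin_frames`` of an
    invalid sample (blink-edge margin). The speed screen runs on the raw,
    unsmoothed, uninterpolated stream so glitches cannot leak into bridged
    gaps.
    """
    valid = np.asarray(valid, bool).copy()
    pos = np.asarray(pos, float)
    off = (
        (np.abs(pos[:, 0]) > geometry.half_width_deg)
        | (np.abs(pos[:, 1]) > geometry.half_height_deg)
        | ~np.isfinite(pos).all(axis=1)
    )
    valid &= ~off
    spd = forward_speed(t, np.where(valid[:, None], pos, np.nan))
    fast = np.zeros(len(t), bool)
    hit = np.where(spd > config.velocity_limit_deg_s)[0]
    fast[hit] = True
    fast[np.minimum(hit + 1, len(t) - 1)] = True
    valid &= ~fast
    if config.margin_frames > 0 and (~valid).any():
        invalid = ~valid
        m = config.margin_frames
        dilated = invalid.copy()
        for k in range(1, m + 1):
            dilated[:-k] |= invalid[k:]
            dilated[k:] |= invalid[:-k]
        valid = ~dilated
    return valid


def interpolate_gaps(
    t: np.ndarray, pos: np.ndarray, valid: np.ndarray, max_gap_samples: int = 6
) -> np.ndarray:
    """Linearly bridge interior invalid runs of at most ``max_gap_samples``.

    Longer gaps and gaps touching the segment edges remain missing.
    Originally valid samples are never altered.
    """
    pos = np.asarray(pos, float).copy()
    pos[~valid] = np.nan
    n = len(t)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        gap = j - i
        if i > 0 and j < n and gap <= max_gap_samples:
            for ax in (0, 1):
                pos[i:j, ax] = np.interp(t[i:j], [t[i - 1], t[j]], [pos[i - 1, ax], pos[j, ax]])
        i = j
    return pos


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def smooth_and_differentiate(
    t: np.ndarray,
    pos: np.ndarray,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Savitzky-Golay smoothing and central-difference velocity per valid run.

    Smoothing is applied independently to each contiguous finite run; runs
    shorter than the window pass through unsmoothed so their samples stay
    available for dispersion features. Velocity v_i = (x_{i+1} - x_{i-1}) /
    (2 dt) on the smoothed positions, NaN at run edges.
    """
    if config.sg_polyorder >= config.sg_window:
        raise ValueError("polynomial order must be smaller than the window length")
    pos = np.asarray(pos, float)
    smoothed = pos.copy()
    vel = np.full_like(pos, np.nan)
    finite = np.isfinite(pos).all(axis=1)
    for i, j in _contiguous_runs(finite):
        run = pos[i:j]
        if j - i >= config.sg_window:
            if config.smoother == "lowpass":
                kern = np.ones(config.sg_window) / config.sg_window
                sm = np.column_stack(
                    [np.convolve(run[:, ax], kern, mode="same") for ax in (0, 1)]
                )
                # moving-average edges are biased; keep raw values there
                h = config.sg_window // 2
                sm[:h] = run[:h]
                sm[len(run) - h:] = run[len(run) - h:]
            else:
                sm = savgol_filter(run, config.sg_window, config.sg_polyorder, axis=0, mode="interp")
            smoothed[i:j] = sm
        if j - i >= 3:
            dt = np.diff(t[i:j])
            mid = smoothed[i + 2 : j] - smoothed[i : j - 2]
            denom = (dt[:-1] + dt[1:])[:, None]
            vel[i + 1 : j - 1] = mid / denom
    speed = np.linalg.norm(vel, axis=1)
    return smoothed, vel, speed


def qc_trial(valid: np.ndarray, threshold: float = 0.30) -> tuple[bool, float]:
    """Retained flag and invalid fraction; strictly more than ``threshold`` excludes."""
    valid = np.asarray(valid, bool)
    if valid.size == 0:
        return False, 1.0
    invalid_fraction = float((~valid).mean())
    return invalid_fraction <= threshold, invalid_fraction


def preprocess_trial(
    subject_id: str,
    task_id: int,
    trial_id: int,
    t: np.ndarray,
    l_pos_deg: np.ndarray,
    r_pos_deg: np.ndarray,
    l_valid: np.ndarray,
    r_valid: np.ndarray,
    geometry: ScreenGeometry,
    config: PreprocessConfig = PreprocessConfig(),
    stream_kind: str = "cyclopean",
    amblyopic_side: str | None = None,
    meta: dict | None = None,
) -> TrialSegment:
    """Full per-trial chain: stream -> flag -> interpolate -> QC -> smooth."""
    pos, valid = build_stream(l_pos_deg, r_pos_deg, l_valid, r_valid, stream_kind, amblyopic_side)
    valid = flag_invalid(t, pos, valid, geometry, config)
    max_gap = int(round(config.max_gap_ms / 1000.0 * 30.0)) if len(t) < 2 else int(
        round(config.max_gap_ms / 1000.0 / float(np.median(np.diff(t))))
    )
    pos = interpolate_gaps(t, pos, valid, max_gap_samples=max_gap)
    retained, invalid_fraction = qc_trial(valid, config.qc_threshold)
    raw_speed = forward_speed(t, pos)
    smoothed, vel, speed = smooth_and_differentiate(t, pos, config)
    return TrialSegment(
        subject_id=subject_id,
        task_id=task_id,
        trial_id=trial_id,
        t=t,
        pos=pos,
        valid=valid,
        smoothed=smoothed,
        vel=vel,
        speed=speed,
        raw_speed=raw_speed,
        invalid_fraction=invalid_fraction,
        retained=retained,
        meta=meta or {},
    )


def resolve_amblyopic_side(clinical_row: pd.Series) -> str:
    """Amblyopic (or worse-acuity) eye for a subject; ties resolve to left.

    Amblyopia subjects carry an explicit side label; for controls the
    eye-specific gaze streams are anchored to the worse-acuity eye so that
    stream-sensitivity analyses are defined for every subject.
    """
    side = clinical_row.get("amblyopic_side")
    if isinstance(side, str) and side in ("L", "R"):
        return side
    return "R" if clinical_row["bcva_right"] > clinical_row["bcva_left"] else "L"
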