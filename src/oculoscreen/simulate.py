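"""Synthetic binocular gaze cohorts for the three-task screening battery.

The generator produces labeled subjects (visually normal controls vs.
unilateral amblyopia) with 30 Hz binocular screen-coordinate gaze for three
tasks -- free visual search over an icon array, central grating viewing, and
2-D sinusoidal pursuit -- plus clinical covariates, trial schedules, and
injected artifacts (blinks, tracking loss, off-screen excursions, velocity
glitches).

Latent oculomotor parameters are drawn per subject from group-level
distributions whose defaults are set to the published subject-level summary
statistics the cohort emulates (e.g. pursuit gain 0.946 +/- 0.046 in
controls vs. 0.799 +/- 0.074 in amblyopia). The construction is
target-first: each subject's latent value IS the intended pipeline-extracted
feature value, and task kinematics are built so the extraction chain
recovers it (small affine calibration constants absorb residual biases of
smoothing, sampling and artifact handling).

Scan-path entropy is realized exactly: for each trial the planner picks a
partition of the transition count whose plug-in entropy is closest to the
subject's target, then realizes it as dwell "blocks" (self-transitions
within one grid cell, separated by >1 deg hops) joined by distinct
between-cell moves. Fixational instability during grating viewing is an
Ornstein-Uhlenbeck process; pursuit is velocity-scaled tracking with
sub-detection corrective jumps plus scripted lapse/catch-up cycles that the
event detector counts.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import ScreenGeometry, deg_to_px

__all__ = [
    "CohortSpec",
    "TrialPlan",
    "ArtifactRates",
    "GroupLatents",
    "SubjectProfile",
    "TargetTrajectory",
    "Cohort",
    "make_pursuit_trajectory",
    "draw_profile",
    "simulate_subject_gaze",
    "simulate_cohort",
    "DEFAULT_CONTROL",
    "DEFAULT_AMBLYOPIA",
]

TASK2_ORIENTATIONS = tuple(range(0, 180, 15))  # 0, 15, ..., 165 deg
TASK2_CONTRASTS = (0.2, 0.4, 0.8)


@dataclass(frozen=True)
class TrialPlan:
    """Formal trial counts and timing for the three tasks."""

    task1_trials: int = 8
    task1_max_duration_s: float = 60.0
    task2_reps: int = 2
    task2_stim_s: float = 2.0
    task2_blank_s: float = 1.0
    task3_trials: int = 6
    task3_motion_s: float = 20.0
    task3_prefix_s: float = 3.0

    @property
    def task2_trials(self) -> int:
        return len(TASK2_ORIENTATIONS) * len(TASK2_CONTRASTS) * self.task2_reps


@dataclass(frozen=True)
class ArtifactRates:
    """Rates of injected recording artifacts (all disabled when zero)."""

    blink_rate_hz: float = 0.22  # blink onsets per second
    blink_duration_median_ms: float = 140.0
    blink_duration_sigma: float = 0.45  # log-normal sigma -> some gaps exceed 200 ms
    tracking_loss_prob: float = 0.002  # per-eye per-sample device invalid
    glitch_prob: float = 0.0012  # binocular single-sample teleport (> 1000 deg/s)
    offscreen_prob: float = 0.0008  # start of a short off-display excursion

    def none(self) -> "ArtifactRates":
        return ArtifactRates(0.0, self.blink_duration_median_ms, self.blink_duration_sigma, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroupLatents:
    """Group-level distributions (mean, SD) of latent oculomotor parameters.

    The feature-valued entries are targets on the scale of the extracted
    subject-level feature; the remaining entries are generative knobs.
    """

    # Task 1
    scan_entropy_bits: tuple[float, float] = (2.126, 0.282)
    regressions_per_trial: tuple[float, float] = (1.914, 1.401)
    saccade_amplitude_deg: tuple[float, float] = (3.303, 0.776)
    fix_duration_ms: tuple[float, float] = (290.0, 35.0)
    fixations_per_trial: tuple[float, float] = (16.0, 2.0)
    # Task 2
    fixation_latency_ms: tuple[float, float] = (226.5, 20.2)
    directional_drift_deg: tuple[float, float] = (0.384, 0.061)
    hull_dispersion_deg2: tuple[float, float] = (2.737, 0.312)
    corrective_events_per_trial: tuple[float, float] = (0.18, 0.08)
    # Task 3
    pursuit_gain: tuple[float, float] = (0.946, 0.046)
    tracking_error_deg: tuple[float, float] = (0.605, 0.130)
    catch_up_per_trial: tuple[float, float] = (5.22, 2.07)
    onset_latency_ms: tuple[float, float] = (185.0, 30.0)
    # measurement / binocular model
    eye_noise_deg: float = 0.10
    amblyopic_eye_noise_multiplier: float = 1.0
    amblyopic_eye_wander_deg: float = 0.06
    fellow_eye_wander_deg: float = 0.06
    # clinical covariates
    bcva_worse: tuple[float, float] = (0.03, 0.05)
    bcva_better: tuple[float, float] = (0.02, 0.05)
    se_worse: tuple[float, float] = (-0.25, 0.75)
    se_better: tuple[float, float] = (-0.15, 0.70)
    stereo_log_median: float = math.log(60.0)
    stereo_log_sigma: float = 0.514


DEFAULT_CONTROL = GroupLatents()
DEFAULT_AMBLYOPIA = GroupLatents(
    scan_entropy_bits=(2.824, 0.354),
    regressions_per_trial=(3.857, 2.144),
    saccade_amplitude_deg=(4.098, 1.249),
    fix_duration_ms=(320.0, 45.0),
    fixations_per_trial=(17.0, 2.0),
    fixation_latency_ms=(272.9, 23.5),
    directional_drift_deg=(0.646, 0.104),
    hull_dispersion_deg2=(3.923, 0.641),
    corrective_events_per_trial=(0.45, 0.15),
    pursuit_gain=(0.799, 0.074),
    tracking_error_deg=(1.069, 0.210),
    catch_up_per_trial=(11.26, 4.05),
    onset_latency_ms=(240.0, 40.0),
    eye_noise_deg=0.10,
    amblyopic_eye_noise_multiplier=1.5,
    amblyopic_eye_wander_deg=0.35,
    fellow_eye_wander_deg=0.07,
    bcva_worse=(0.34, 0.09),
    bcva_better=(0.05, 0.05),
    se_worse=(2.00, 2.25),
    se_better=(0.50, 1.50),
    stereo_log_median=math.log(400.0),
    stereo_log_sigma=1.028,
)


@dataclass(frozen=True)
class Calibration:
    """Affine maps from latent targets to injected magnitudes.

    These absorb the deterministic biases of the extraction chain
    (Savitzky-Golay shrinkage, frame quantization, hull geometry of a
    correlated point cloud) so that large-n extracted group means land on
    the configured targets. Tuned once on noise-controlled simulations.
    """

    # slow-meander variance solving  hull = a * (sigma_slow^2 + c)^b
    hull_pow_a: float = 3.174
    hull_pow_b: float = 0.333
    hull_pow_c: float = -0.022
    sigma_fast_deg: float = 0.30  # fast fixational jitter (fixed)
    # injected drift solves E|N(D, s^2)| = target; s is the residual scatter
    # of the (re-centered) trial endpoints, nearly group-independent
    drift_noise_sd_deg: float = 0.42
    latency_offset_ms: float = -4.2  # constant part of the latency correction
    latency_sigma_coef: float = 49.4  # ms per deg^2 of cloud variance
    # injected gain = gain_scale * target + gain_offset (corrects the upward
    # bias that correction hops and smoothing add to the median speed ratio)
    gain_scale: float = 1.2048
    gain_offset: float = -0.2106
    error_theta_scale: float = 1.72  # theta = scale * (target - error_floor)
    error_floor_deg: float = 0.07  # noise/wander floor of mean |gaze - target|
    # injected lapse count = catch_up_scale * target + catch_up_offset
    # (compensates lapse merging/truncation losses at high counts)
    catch_up_scale: float = 1.30
    catch_up_offset: float = -0.47
    entropy_offset_bits: float = 0.0
    onset_offset_ms: float = 25.0


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: int = 35
    sampling_rate: float = 30.0
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    trial_plan: TrialPlan = field(default_factory=TrialPlan)
    artifacts: ArtifactRates = field(default_factory=ArtifactRates)
    control: GroupLatents = field(default_factory=lambda: DEFAULT_CONTROL)
    amblyopia: GroupLatents = field(default_factory=lambda: DEFAULT_AMBLYOPIA)
    calibration: Calibration = field(default_factory=Calibration)
    pursuit_frequencies: tuple[float, float] = (0.08, 0.16)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class SubjectProfile:
    subject_id: str
    group: str  # "control" | "amblyopia"
    latents: dict[str, float]
    amblyopic_side: str  # for controls: the designated worse-acuity eye
    bcva_left: float
    bcva_right: float
    se_left: float
    se_right: float
    stereoacuity_arcsec: float
    age_years: float
    sex: str
    etiology: str | None


@dataclass
class TargetTrajectory:
    """2-D sinusoidal pursuit target with analytic velocity."""

    t: np.ndarray
    pos: np.ndarray  # (n, 2) deg
    vel: np.ndarray  # (n, 2) deg/s
    frequencies: tuple[float, float]
    phases: tuple[float, float]
    amplitudes: tuple[float, float] = (15.0, 7.5)


@dataclass
class Cohort:
    spec: CohortSpec
    gaze: pd.DataFrame  # one row per sample, gaze CSV dialect
    schedules: dict[tuple[str, int], list[dict]]  # (subject_id, task_id) -> trials
    clinical: pd.DataFrame  # one row per subject
    labels: pd.Series  # subject_id -> 0/1
    injected: pd.DataFrame  # per-trial injected-invalid bookkeeping
    profiles: dict[str, "SubjectProfile"] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.labels.index)


def make_pursuit_trajectory(
    duration_s: float,
    sampling_rate: float,
    frequencies: tuple[float, float] = (0.08, 0.16),
    phases: tuple[float, float] = (0.0, 0.0),
    amplitudes: tuple[float, float] = (15.0, 7.5),
) -> TargetTrajectory:
    """Sinusoidal 2-D target path with analytic velocities.

    x(t) = Ax sin(2 pi fx t + phx), y(t) = Ay sin(2 pi fy t + phy); the
    default +/-15 x +/-7.5 deg excursion and frequency pair give a peak
    tangential speed of about 10 deg/s.
    """
    if duration_s <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if min(frequencies) <= 0:
        raise ValueError("frequencies must be positive")
    ax, ay = amplitudes
    fx, fy = frequencies
    phx, phy = phases
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    pos = np.column_stack(
        [ax * np.sin(2 * np.pi * fx * t + phx), ay * np.sin(2 * np.pi * fy * t + phy)]
    )
    vel = np.column_stack(
        [
            ax * 2 * np.pi * fx * np.cos(2 * np.pi * fx * t + phx),
            ay * 2 * np.pi * fy * np.cos(2 * np.pi * fy * t + phy),
        ]
    )
    return TargetTrajectory(t=t, pos=pos, vel=vel, frequencies=frequencies, phases=phases, amplitudes=amplitudes)


# ---------------------------------------------------------------------------
# Task 1: scan-path planner (exact transition-entropy realization)
# ---------------------------------------------------------------------------

_PARTITION_CATALOG: dict[int, tuple[np.ndarray, list[tuple[tuple[int, ...], int]]]] = {}


def _partitions(n: int, k: int, maximum: int) -> list[tuple[int, ...]]:
    """All partitions of n into exactly k parts, each <= maximum, descending."""
    if k == 1:
        return [(n,)] if 1 <= n <= maximum else []
    out = []
    for first in range(min(n - k + 1, maximum), 0, -1):
        for rest in _partitions(n - first, k - 1, first):
            out.append((first,) + rest)
    return out


def _plugin_entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _partition_catalog(T: int):
    """Achievable (entropy, plan) pairs for T transitions.

    A plan is k dwell blocks with self-transition counts (c_1..c_k) joined
    by k-1 distinct unit moves: the transition multiset is
    {c_1..c_k, 1 x (k-1)} summing to T.
    """
    if T in _PARTITION_CATALOG:
        return _PARTITION_CATALOG[T]
    entries: list[tuple[float, tuple[tuple[int, ...], int]]] = []
    for k in range(1, (T + 1) // 2 + 1):
        total = T - (k - 1)
        if total < k:
            break
        for parts in _partitions(total, k, total):
            counts = np.array(list(parts) + [1] * (k - 1), float)
            entries.append((_plugin_entropy(counts), (parts, k - 1)))
    entries.sort(key=lambda e: e[0])
    ent = np.array([e[0] for e in entries])
    plans = [e[1] for e in entries]
    _PARTITION_CATALOG[T] = (ent, plans)
    return ent, plans


def plan_scanpath(T: int, target_entropy_bits: float) -> tuple[tuple[int, ...], int]:
    """Block plan whose realized transition entropy is closest to the target."""
    ent, plans = _partition_catalog(T)
    idx = int(np.argmin(np.abs(ent - target_entropy_bits)))
    return plans[idx]


def _grid_centers(screen: ScreenGeometry, cols: int = 8, rows: int = 6) -> np.ndarray:
    hw, hh = screen.half_width_deg, screen.half_height_deg
    xs = (np.arange(cols) + 0.5) / cols * 2 * hw - hw
    ys = (np.arange(rows) + 0.5) / rows * 2 * hh - hh
    return np.array([[x, y] for y in ys for x in xs])


def _simulate_task1_trial(
    profile: SubjectProfile, spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent cyclopean trace for one search trial: (t_rel, pos)."""
    lat = profile.latents
    cal = spec.calibration
    fs = spec.sampling_rate
    n_fix = int(np.clip(round(rng.normal(lat["fixations_per_trial"], 1.2)), 10, 24))
    T = n_fix - 1
    blocks, n_moves = plan_scanpath(T, lat["scan_entropy_bits"] + cal.entropy_offset_bits)
    k = len(blocks)

    # regressions: leftward steps, allocated to moves first, then dwell hops
    r_target = int(np.clip(round(rng.normal(lat["regressions_per_trial"], 0.8)), 0, T - 1))
    move_left = min(r_target, max((n_moves) // 3, 0))
    hop_left = min(r_target - move_left, int(sum(blocks)))

    # between-block move length solving the mean-amplitude target
    hop_len = 1.4
    n_hops = int(sum(blocks))
    if n_moves > 0:
        move_len = (lat["saccade_amplitude_deg"] * T - hop_len * n_hops) / n_moves
        move_len = float(np.clip(move_len, 5.0, 40.0))
    else:
        move_len = 0.0

    centers = _grid_centers(spec.screen)
    hw, hh = spec.screen.half_width_deg, spec.screen.half_height_deg
    # block cells: start left of center, walk mostly rightward at ~move_len
    used: list[int] = []
    start = np.array([-hw * 0.55 + rng.uniform(-2, 2), rng.uniform(-hh * 0.4, hh * 0.4)])
    cur_idx = int(np.argmin(np.linalg.norm(centers - start, axis=1)))
    used.append(cur_idx)
    move_signs = np.array([1] * (n_moves - move_left) + [-1] * move_left)
    rng.shuffle(move_signs)
    for s in move_signs:
        cur = centers[used[-1]]
        cand = [i for i in range(len(centers)) if i not in used]
        target_pt = cur + np.array([s * move_len, 0.0])
        target_pt[0] = np.clip(target_pt[0], -hw + 2, hw - 2)
        dists = np.linalg.norm(centers[cand] - cur, axis=1)
        side_ok = np.sign(centers[cand][:, 0] - cur[0]) == s
        score = np.abs(dists - move_len) + np.abs(centers[cand][:, 1] - cur[1]) * 0.3
        score = np.where(side_ok, score, score + 100.0)
        used.append(cand[int(np.argmin(score))])
    block_cells = centers[used]

    # realize fixation sequence: dwell blocks joined by moves. Every hop
    # carries a deliberate horizontal sign (rightward by default) so that
    # measurement noise cannot flip the regression reading of a step.
    fix_pos: list[np.ndarray] = []
    left_remaining = hop_left
    hops_remaining = n_hops
    for b, c in enumerate(blocks):
        center = block_cells[b]
        p = center + np.array([-1.1 + rng.uniform(-0.15, 0.15), rng.uniform(-0.3, 0.3)])
        fix_pos.append(p.copy())
        for _ in range(c):
            x_off = p[0] - center[0]
            if left_remaining > 0 and (x_off >= -0.45 or hops_remaining <= left_remaining):
                dx = -0.9
                left_remaining -= 1
            elif x_off + 0.35 > 1.3:  # dwell-box edge: forced left bounce
                dx = -0.9
                left_remaining = max(left_remaining - 1, 0)
            else:
                dx = 0.35
            hops_remaining -= 1
            dy = math.sqrt(max(hop_len**2 - dx**2, 0.25))
            p = p + np.array([dx, dy if p[1] < center[1] else -dy])
            p[0] = center[0] + np.clip(p[0] - center[0], -1.35, 1.35)
            fix_pos.append(p.copy())
    fix_pos_arr = np.array(fix_pos)

    durations = np.clip(rng.normal(lat["fix_duration_ms"], 60.0, size=n_fix), 150.0, 700.0)
    dur_frames = np.maximum(np.round(durations / 1000.0 * fs).astype(int), 4)

    samples: list[np.ndarray] = []
    for i in range(n_fix):
        jitter = rng.normal(0.0, 0.02, size=(dur_frames[i], 2))
        samples.append(fix_pos_arr[i] + jitter)
        if i < n_fix - 1:
            step = np.linalg.norm(fix_pos_arr[i + 1] - fix_pos_arr[i])
            if step > 3.0:  # between-cell move: 2 transit samples
                for frac in (1 / 3, 2 / 3):
                    samples.append((fix_pos_arr[i] + frac * (fix_pos_arr[i + 1] - fix_pos_arr[i]))[None, :])
    pos = np.vstack(samples)
    n = len(pos)
    t_rel = np.arange(n) / fs
    max_n = int(spec.trial_plan.task1_max_duration_s * fs)
    return t_rel[:max_n], pos[:max_n]


# ---------------------------------------------------------------------------
# Task 2: grating viewing (O-U drift + oriented slow drift + entry saccade)
# ---------------------------------------------------------------------------

ORIENTATION_MULTIPLIER = {
    ori: 1.0 + 0.4 * math.exp(-((min(abs(ori - 45), abs(ori - 135)) / 25.0) ** 2))
    for ori in TASK2_ORIENTATIONS
}
_MULT_MEAN = float(np.mean(list(ORIENTATION_MULTIPLIER.values())))


def _folded_mean(d: float, s: float) -> float:
    """E|X| for X ~ N(d, s^2)."""
    if s <= 1e-9:
        return abs(d)
    return d * math.erf(d / (s * math.sqrt(2))) + s * math.sqrt(2 / math.pi) * math.exp(
        -(d**2) / (2 * s**2)
    )


def _invert_folded_mean(target: float, s: float) -> float:
    """Drift magnitude whose folded-normal mean under noise s equals target."""
    if target <= _folded_mean(0.0, s):
        return 0.0
    lo, hi = 0.0, target
    for _ in range(40):
        mid = (lo + hi) / 2
        if _folded_mean(mid, s) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _simulate_task2_trial(
    profile: SubjectProfile,
    spec: CohortSpec,
    orientation_deg: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    lat = profile.latents
    cal = spec.calibration
    fs = spec.sampling_rate
    n = int(round(spec.trial_plan.task2_stim_s * fs))
    t = np.arange(n) / fs

    group = spec.amblyopia if profile.group == "amblyopia" else spec.control
    wander_var_cyc = (group.amblyopic_eye_wander_deg**2 + group.fellow_eye_wander_deg**2) / 4.0
    # two-timescale fixational instability: fast jitter + slow meander whose
    # variance is solved from the subject's hull-dispersion target
    if "t2_sigma_slow" in lat:  # direct override (calibration/tests)
        sigma_slow = lat["t2_sigma_slow"]
    else:
        hull_target = max(lat["hull_dispersion_deg2"], 0.3)
        sigma_slow2 = (hull_target / cal.hull_pow_a) ** (1.0 / cal.hull_pow_b) - cal.hull_pow_c
        sigma_slow = math.sqrt(max(sigma_slow2 - wander_var_cyc, 0.01))
    cloud_var = cal.sigma_fast_deg**2 + sigma_slow**2 + wander_var_cyc

    latency_corr = cal.latency_offset_ms + cal.latency_sigma_coef * cloud_var
    latency_s = max(rng.normal(lat["fixation_latency_ms"] - latency_corr, 18.0), 40.0) / 1000.0

    drift_base = _invert_folded_mean(lat["directional_drift_deg"], cal.drift_noise_sd_deg)
    drift_total = drift_base * ORIENTATION_MULTIPLIER[orientation_deg] / _MULT_MEAN
    u = np.array([math.cos(math.radians(orientation_deg)), math.sin(math.radians(orientation_deg))])
    drift_sign = rng.choice([-1.0, 1.0])

    # pre-entry: parked just outside the ROI, roughly perpendicular to the
    # stimulus orientation axis so the entry step projects ~0 onto it
    ang = math.radians(orientation_deg + 90.0) + rng.uniform(-0.06, 0.06)
    ang += rng.choice([0.0, math.pi])
    start = 2.35 * np.array([math.cos(ang), math.sin(ang)])
    anchor = 0.35 * np.array([math.cos(ang), math.sin(ang)])  # entry lands near center

    pos = np.empty((n, 2))
    n_entry = min(int(round(latency_s * fs)), n - 2)
    pos[:n_entry] = start + rng.normal(0, 0.05, size=(n_entry, 2))
    dt = 1.0 / fs
    theta_fast, theta_slow = 3.0, 1.0
    xf = np.zeros(2)
    xs = np.zeros(2)
    step_fast = cal.sigma_fast_deg * math.sqrt(2 * theta_fast * dt)
    step_slow = sigma_slow * math.sqrt(2 * theta_slow * dt)
    span = max(n - n_entry, 1)
    for i in range(n_entry, n):
        xf = xf * (1 - theta_fast * dt) + rng.normal(0, step_fast, 2)
        xs = xs * (1 - theta_slow * dt) + rng.normal(0, step_slow, 2)
        frac = (i - n_entry) / span
        # final samples re-foveate the (drifted) stimulus: the slow meander
        # collapses, so the net trial displacement reflects the oriented drift
        meander = xs if i < n - 3 else 0.12 * xs
        pos[i] = anchor + xf + meander + drift_sign * drift_total * frac * u
    # small corrective saccade-like events: 2-leg overshoot/return (>60 deg/s legs)
    if rng.random() < lat["corrective_events_per_trial"]:
        i = rng.integers(n_entry + 3, n - 3)
        out_dir = rng.normal(size=2)
        out_dir /= np.linalg.norm(out_dir)
        net = rng.uniform(0.45, 0.85)
        pos[i + 1] = pos[i] + out_dir * (net + 2.3)
        pos[i + 2 :] += out_dir * net
    return t, pos


# ---------------------------------------------------------------------------
# Task 3: sinusoidal pursuit
# ---------------------------------------------------------------------------


def _simulate_task3_trial(
    profile: SubjectProfile,
    spec: CohortSpec,
    traj: TargetTrajectory,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent trace for prefix + motion; returns (t_rel, pos)."""
    lat = profile.latents
    cal = spec.calibration
    fs = spec.sampling_rate
    dt = 1.0 / fs
    n_pre = int(round(spec.trial_plan.task3_prefix_s * fs))
    n_mot = len(traj.t)
    n = n_pre + n_mot
    pos = np.empty((n, 2))
    fix_point = traj.pos[0]
    pos[:n_pre] = fix_point + rng.normal(0, 0.05, size=(n_pre, 2))

    group = spec.amblyopia if profile.group == "amblyopia" else spec.control
    # the upward bias of the median speed ratio is noise-driven (E|v+n|>|v|),
    # so the affine correction is scaled by the configured noise relative to
    # the level it was calibrated at; noise-free simulation injects the
    # target gain unchanged
    noise_factor = min((group.eye_noise_deg / 0.10) ** 2, 2.0)
    delta = (cal.gain_scale - 1.0) * lat["pursuit_gain"] + cal.gain_offset
    gain = float(np.clip(lat["pursuit_gain"] + delta * noise_factor, 0.05, 1.45))
    theta = max(cal.error_theta_scale * (lat["tracking_error_deg"] - cal.error_floor_deg), 0.35)
    onset_lat_frames = int(round(max(lat["onset_latency_ms"] + cal.onset_offset_ms, 0.0) / 1000.0 * fs))
    n_catch = max(
        int(round(rng.normal(cal.catch_up_scale * lat["catch_up_per_trial"] + cal.catch_up_offset, 1.0))), 0
    )
    lapse_starts = np.sort(rng.uniform(1.0, spec.trial_plan.task3_motion_s - 1.5, size=n_catch))
    lapse_idx = set((lapse_starts * fs).astype(int).tolist())

    g = fix_point.copy()
    in_lapse = False
    for i in range(n_mot):
        tgt = traj.pos[i]
        if i < onset_lat_frames:
            pos[n_pre + i] = g + rng.normal(0, 0.03, 2)
            continue
        if i in lapse_idx:
            in_lapse = True
        err = tgt - g
        if in_lapse:
            # pursuit pauses; once error is large, a catch-up saccade (>1.5
            # deg, one frame, >60 deg/s) recovers most of it
            if np.linalg.norm(err) >= 2.6:
                g = g + 0.85 * err
                in_lapse = False
        else:
            g = g + gain * (traj.pos[i] - traj.pos[i - 1]) if i > 0 else g
            err = tgt - g
            if np.linalg.norm(err) > theta:
                # sub-detection corrective hop (< 2 deg per frame, < 60 deg/s)
                g = g + min(0.8, 1.9 / max(np.linalg.norm(err), 1e-9)) * err
        pos[n_pre + i] = g + rng.normal(0, 0.03, 2)
    t_rel = np.arange(n) / fs
    return t_rel, pos


# ---------------------------------------------------------------------------
# binocular emission + artifacts
# ---------------------------------------------------------------------------


def _ou_series(n: int, sigma: float, tau_s: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary 2-D Ornstein-Uhlenbeck wander with SD sigma, timescale tau."""
    if sigma <= 0:
        return np.zeros((n, 2))
    theta = 1.0 / tau_s
    dt = 1.0 / fs
    out = np.empty((n, 2))
    out[0] = rng.normal(0, sigma, 2)
    step_sd = sigma * math.sqrt(2 * theta * dt)
    for i in range(1, n):
        out[i] = out[i - 1] * (1 - theta * dt) + rng.normal(0, step_sd, 2)
    return out


def _emit_eyes(
    latent: np.ndarray,
    profile: SubjectProfile,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Left/right pixel streams + validity + injected-invalid bookkeeping."""
    group = spec.amblyopia if profile.group == "amblyopia" else spec.control
    n = len(latent)
    fs = spec.sampling_rate
    sigma = group.eye_noise_deg
    amb_sigma = sigma * group.amblyopic_eye_noise_multiplier
    wander_amb = _ou_series(n, group.amblyopic_eye_wander_deg, 1.2, fs, rng)
    wander_fel = _ou_series(n, group.fellow_eye_wander_deg, 1.2, fs, rng)
    amb_eye = latent + wander_amb + rng.normal(0, amb_sigma, size=(n, 2))
    fel_eye = latent + wander_fel + rng.normal(0, sigma, size=(n, 2))
    if profile.amblyopic_side == "L":
        l_pos, r_pos = amb_eye, fel_eye
    else:
        l_pos, r_pos = fel_eye, amb_eye
    l_valid = np.ones(n, bool)
    r_valid = np.ones(n, bool)

    art = spec.artifacts
    injected = np.zeros(n, bool)  # samples invalid under the cyclopean definition
    # blinks: both eyes lost
    if art.blink_rate_hz > 0:
        n_blinks = rng.poisson(art.blink_rate_hz * n / fs)
        for _ in range(n_blinks):
            dur_ms = art.blink_duration_median_ms * math.exp(rng.normal(0, art.blink_duration_sigma))
            start = rng.integers(0, n)
            stop = min(start + max(int(round(dur_ms / 1000 * fs)), 1), n)
            l_valid[start:stop] = False
            r_valid[start:stop] = False
            injected[start:stop] = True
    # per-eye tracking loss (cyclopean survives unless both eyes drop)
    if art.tracking_loss_prob > 0:
        l_loss = rng.random(n) < art.tracking_loss_prob
        r_loss = rng.random(n) < art.tracking_loss_prob
        l_valid &= ~l_loss
        r_valid &= ~r_loss
        injected |= l_loss & r_loss
    # binocular glitches: one-sample teleport, speed > 1000 deg/s
    if art.glitch_prob > 0:
        for i in np.where(rng.random(n) < art.glitch_prob)[0]:
            if 0 < i < n - 1:
                jump = rng.uniform(35, 44) * np.array([rng.choice([-1, 1]), rng.uniform(-0.3, 0.3)])
                l_pos[i] += jump
                r_pos[i] += jump
                injected[i] = True
    # off-display excursions
    if art.offscreen_prob > 0:
        hw = spec.screen.half_width_deg
        for i in np.where(rng.random(n) < art.offscreen_prob)[0]:
            stop = min(i + rng.integers(3, 9), n)
            off = np.array([np.sign(l_pos[i, 0] + 1e-9) * (hw + rng.uniform(1, 4)), l_pos[i, 1]])
            l_pos[i:stop] = off
            r_pos[i:stop] = off
            injected[i:stop] = True

    l_px = deg_to_px(l_pos, spec.screen)
    r_px = deg_to_px(r_pos, spec.screen)
    # dilate by the blink-edge margin used in preprocessing
    dil = injected.copy()
    dil[:-1] |= injected[1:]
    dil[1:] |= injected[:-1]
    return {
        "l_px": l_px,
        "r_px": r_px,
        "l_valid": l_valid,
        "r_valid": r_valid,
        "injected_fraction": float(injected.mean()),
        "injected_dilated_fraction": float(dil.mean()),
    }


# ---------------------------------------------------------------------------
# profiles, subjects, cohort
# ---------------------------------------------------------------------------


def _draw(rng: np.random.Generator, ms: tuple[float, float]) -> float:
    return float(rng.normal(ms[0], ms[1]))


def draw_profile(group: str, index: int, spec: CohortSpec, rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject's latent parameters and clinical covariates."""
    g = spec.amblyopia if group == "amblyopia" else spec.control
    lat = {
        "scan_entropy_bits": float(np.clip(_draw(rng, g.scan_entropy_bits), 0.8, 4.2)),
        "regressions_per_trial": max(_draw(rng, g.regressions_per_trial), 0.0),
        "saccade_amplitude_deg": float(np.clip(_draw(rng, g.saccade_amplitude_deg), 2.0, 8.0)),
        "fix_duration_ms": float(np.clip(_draw(rng, g.fix_duration_ms), 200.0, 450.0)),
        "fixations_per_trial": float(np.clip(_draw(rng, g.fixations_per_trial), 11.0, 22.0)),
        "fixation_latency_ms": float(np.clip(_draw(rng, g.fixation_latency_ms), 80.0, 450.0)),
        "directional_drift_deg": float(np.clip(_draw(rng, g.directional_drift_deg), 0.05, 1.6)),
        "hull_dispersion_deg2": float(np.clip(_draw(rng, g.hull_dispersion_deg2), 0.8, 8.0)),
        "corrective_events_per_trial": float(np.clip(_draw(rng, g.corrective_events_per_trial), 0.0, 0.95)),
        "pursuit_gain": float(np.clip(_draw(rng, g.pursuit_gain), 0.3, 1.4)),
        "tracking_error_deg": float(np.clip(_draw(rng, g.tracking_error_deg), 0.25, 2.2)),
        "catch_up_per_trial": float(np.clip(_draw(rng, g.catch_up_per_trial), 0.0, 25.0)),
        "onset_latency_ms": float(np.clip(_draw(rng, g.onset_latency_ms), 80.0, 450.0)),
    }
    if group == "amblyopia":
        bcva_worse = float(np.clip(_draw(rng, g.bcva_worse), 0.2, 0.5))
        bcva_better = float(np.clip(_draw(rng, g.bcva_better), -0.1, min(bcva_worse - 0.2, 0.1)))
        etiology = str(rng.choice(["anisometropic", "strabismic", "mixed"], p=[18 / 35, 10 / 35, 7 / 35]))
    else:
        bcva_worse = float(np.clip(_draw(rng, g.bcva_worse), -0.1, 0.1))
        bcva_better = float(np.clip(_draw(rng, g.bcva_better), bcva_worse - 0.1, bcva_worse))
        etiology = None
    side = str(rng.choice(["L", "R"]))
    bcva_left, bcva_right = (bcva_worse, bcva_better) if side == "L" else (bcva_better, bcva_worse)
    se_worse = _draw(rng, g.se_worse)
    se_better = _draw(rng, g.se_better)
    se_left, se_right = (se_worse, se_better) if side == "L" else (se_better, se_worse)
    prefix = "amb" if group == "amblyopia" else "ctl"
    return SubjectProfile(
        subject_id=f"{prefix}{index:03d}",
        group=group,
        latents=lat,
        amblyopic_side=side,
        bcva_left=bcva_left,
        bcva_right=bcva_right,
        se_left=se_left,
        se_right=se_right,
        stereoacuity_arcsec=float(
            np.clip(math.exp(rng.normal(g.stereo_log_median, g.stereo_log_sigma)), 20.0, 3000.0)
        ),
        age_years=float(np.clip(rng.normal(8.9, 1.65), 6.0, 12.0)),
        sex=str(rng.choice(["M", "F"])),
        etiology=etiology,
    )


def simulate_subject_gaze(
    profile: SubjectProfile, spec: CohortSpec, task_id: int, seed: int
) -> tuple[pd.DataFrame, list[dict], list[dict]]:
    """Binocular sample stream + schedule + artifact bookkeeping for one task.

    Deterministic in (profile, spec, task_id, seed). Timestamps are a global
    session clock; trials are contiguous blocks separated by inter-trial
    intervals that carry no samples.
    """
    if task_id not in (1, 2, 3):
        raise ValueError(f"unknown task_id {task_id}")
    sid_hash = zlib.crc32(profile.subject_id.encode()) & 0xFFFF
    rng = np.random.default_rng([seed & 0x7FFFFFFF, task_id, sid_hash])
    plan = spec.trial_plan
    fs = spec.sampling_rate
    rows: list[pd.DataFrame] = []
    schedule: list[dict] = []
    injected: list[dict] = []
    clock = float(task_id * 1000.0)  # disjoint per-task time ranges

    if task_id == 1:
        trial_specs = [{"trial_id": i} for i in range(plan.task1_trials)]
    elif task_id == 2:
        combos = [
            {"orientation_deg": o, "contrast": c}
            for _ in range(plan.task2_reps)
            for o in TASK2_ORIENTATIONS
            for c in TASK2_CONTRASTS
        ]
        order = rng.permutation(len(combos))
        trial_specs = [dict(combos[j], trial_id=i) for i, j in enumerate(order)]
    else:
        trial_specs = [{"trial_id": i} for i in range(plan.task3_trials)]

    for ts in trial_specs:
        trial_rng = np.random.default_rng(
            [spec.seed & 0x7FFFFFFF, seed & 0x7FFFFFFF, task_id, ts["trial_id"], sid_hash]
        )
        meta: dict = {}
        if task_id == 1:
            t_rel, latent = _simulate_task1_trial(profile, spec, trial_rng)
        elif task_id == 2:
            t_rel, latent = _simulate_task2_trial(profile, spec, ts["orientation_deg"], trial_rng)
            meta = {"orientation_deg": ts["orientation_deg"], "contrast": ts["contrast"]}
        else:
            phases = tuple(trial_rng.uniform(0, 2 * np.pi, 2))
            traj = make_pursuit_trajectory(plan.task3_motion_s, fs, spec.pursuit_frequencies, phases)
            t_rel, latent = _simulate_task3_trial(profile, spec, traj, trial_rng)
            meta = {
                "frequencies": list(spec.pursuit_frequencies),
                "phases": [float(p) for p in phases],
                "motion_onset_offset_s": plan.task3_prefix_s,
            }
        eyes = _emit_eyes(latent, profile, spec, trial_rng)
        t_abs = clock + t_rel
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": profile.subject_id,
                    "group": profile.group,
                    "task_id": task_id,
                    "trial_id": ts["trial_id"],
                    "t_s": t_abs,
                    "lx_px": eyes["l_px"][:, 0],
                    "ly_px": eyes["l_px"][:, 1],
                    "l_valid": eyes["l_valid"],
                    "rx_px": eyes["r_px"][:, 0],
                    "ry_px": eyes["r_px"][:, 1],
                    "r_valid": eyes["r_valid"],
                }
            )
        )
        schedule.append(
            {
                "trial_id": ts["trial_id"],
                "onset_s": float(t_abs[0]),
                "offset_s": float(t_abs[-1] + 1.0 / fs),
                "practice": False,
                **meta,
            }
        )
        injected.append(
            {
                "subject_id": profile.subject_id,
                "task_id": task_id,
                "trial_id": ts["trial_id"],
                "injected_fraction": eyes["injected_fraction"],
                "injected_dilated_fraction": eyes["injected_dilated_fraction"],
            }
        )
        clock = float(t_abs[-1]) + 1.0 + 1.0 / fs  # inter-trial interval
    return pd.concat(rows, ignore_index=True), schedule, injected


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Full labeled cohort: gaze for all tasks, schedules, clinical table."""
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0xC0C0])
    gaze_parts: list[pd.DataFrame] = []
    schedules: dict[tuple[str, int], list[dict]] = {}
    clin_rows: list[dict] = []
    labels: dict[str, int] = {}
    injected_parts: list[dict] = []
    profiles: dict[str, SubjectProfile] = {}
    for group, label in [("control", 0), ("amblyopia", 1)]:
        for i in range(spec.n_per_group):
            profile = draw_profile(group, i, spec, rng)
            subject_seed = int(rng.integers(0, 2**31 - 1))
            for task_id in (1, 2, 3):
                df, sched, inj = simulate_subject_gaze(profile, spec, task_id, subject_seed)
                gaze_parts.append(df)
                schedules[(profile.subject_id, task_id)] = sched
                injected_parts.extend(inj)
            labels[profile.subject_id] = label
            profiles[profile.subject_id] = profile
            clin_rows.append(
                {
                    "subject_id": profile.subject_id,
                    "group": group,
                    "age_years": profile.age_years,
                    "sex": profile.sex,
                    "bcva_left": profile.bcva_left,
                    "bcva_right": profile.bcva_right,
                    "bcva_worse": max(profile.bcva_left, profile.bcva_right),
                    "bcva_better": min(profile.bcva_left, profile.bcva_right),
                    "iod_logmar": abs(profile.bcva_left - profile.bcva_right),
                    "se_left": profile.se_left,
                    "se_right": profile.se_right,
                    "stereoacuity_arcsec": profile.stereoacuity_arcsec,
                    "etiology": profile.etiology,
                    "amblyopic_side": profile.amblyopic_side,
                }
            )
    return Cohort(
        spec=spec,
        gaze=pd.concat(gaze_parts, ignore_index=True),
        schedules=schedules,
        clinical=pd.DataFrame(clin_rows).set_index("subject_id", drop=False),
        labels=pd.Series(labels, name="label"),
        injected=pd.DataFrame(injected_parts),
        profiles=profiles,
    )


def noise_free_spec(spec: CohortSpec) -> CohortSpec:
    """Copy of ``spec`` with artifacts disabled and measurement noise zeroed."""
    quiet_ctrl = replace(
        spec.control, eye_noise_deg=0.0, amblyopic_eye_wander_deg=0.0, fellow_eye_wander_deg=0.0
    )
    quiet_amb = replace(
        spec.amblyopia, eye_noise_deg=0.0, amblyopic_eye_wander_deg=0.0, fellow_eye_wander_deg=0.0
    )
    return replace(spec, artifacts=spec.artifacts.none(), control=quiet_ctrl, amblyopia=quiet_amb)
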