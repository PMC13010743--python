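"""Oculomotor event detection on cleaned trial segments.

Fixations via a greedy dispersion-threshold (I-DT) scan, saccade-like events
via speed-gate thresholding with amplitude taken between the flanking
sub-threshold samples, catch-up saccades as large error-reducing events
during pursuit, and pursuit onset latency as sustained co-directional motion
after target onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TrialSegment


@dataclass
class FixationEvent:
    start_idx: int
    end_idx: int  # inclusive
    t_start: float
    t_end: float
    duration_ms: float
    centroid: tuple[float, float]
    rms_dispersion: float
    cell: tuple[int, int] | None = None  # (col, row) on the display grid

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass
class SaccadeLikeEvent:
    onset_idx: int  # first supra-threshold interval start
    offset_idx: int  # sample after the last supra-threshold interval
    amplitude: float
    peak_speed: float
    klass: str  # small_corrective / catch_up_candidate / other


def _dispersion(pos: np.ndarray) -> float:
    """I-DT dispersion: (max x - min x) + (max y - min y) over the window."""
    return float(np.ptp(pos[:, 0]) + np.ptp(pos[:, 1]))


def idt_fixations(
    segment: TrialSegment,
    dispersion_threshold: float = 1.0,
    min_duration_ms: float = 100.0,
) -> list[FixationEvent]:
    """Greedy left-to-right I-DT fixation segmentation on smoothed positions.

    A window is grown rightward while its dispersion (x-range plus y-range)
    stays at or below the threshold; windows covering at least the minimum
    duration become fixations with the window's centroid and RMS distance to
    the centroid. Missing samples break windows.
    """
    pos = segment.smoothed
    t = segment.t
    finite = np.isfinite(pos).all(axis=1)
    if len(t) < 2:
        return []
    dt = float(np.median(np.diff(t)))
    min_samples = max(int(np.ceil(min_duration_ms / 1000.0 / dt)), 2)
    fixations: list[FixationEvent] = []
    n = len(t)
    i = 0
    while i <= n - min_samples:
        if not finite[i : i + min_samples].all():
            i += 1
            continue
        window = pos[i : i + min_samples]
        if _dispersion(window) > dispersion_threshold:
            i += 1
            continue
        j = i + min_samples
        while j < n and finite[j] and _dispersion(pos[i : j + 1]) <= dispersion_threshold:
            j += 1
        members = pos[i:j]
        centroid = members.mean(axis=0)
        rms = float(np.sqrt(np.mean(np.sum((members - centroid) ** 2, axis=1))))
        fixations.append(
            FixationEvent(
                start_idx=i,
                end_idx=j - 1,
                t_start=float(t[i]),
                t_end=float(t[j - 1]),
                duration_ms=float((t[j - 1] - t[i]) * 1000.0) + dt * 1000.0,
                centroid=(float(centroid[0]), float(centroid[1])),
                rms_dispersion=rms,
            )
        )
        i = j
    return fixations


def event_speed(segment: TrialSegment, signal: str = "raw_forward") -> np.ndarray:
    """Speed trace used by the saccade-like event gate.

    ``raw_forward``: forward differences on the cleaned, pre-smoothing
    positions (entry i spans the interval [i, i+1]). ``smoothed_central``:
    the central-difference speed of the smoothed positions.
    """
    if signal == "raw_forward":
        return segment.raw_speed
    if signal == "smoothed_central":
        return segment.speed
    raise ValueError(f"unknown event speed signal {signal!r}")


def saccade_like_events(
    segment: TrialSegment,
    speed_threshold: float = 60.0,
    small_band: tuple[float, float] = (0.3, 1.0),
    catch_up_min: float = 1.5,
    signal: str = "raw_forward",
) -> list[SaccadeLikeEvent]:
    """One event per maximal supra-threshold run of the gate speed.

    With the forward-difference signal, a supra-threshold entry at i means
    the step from sample i to i+1 was fast; the flanking sub-threshold
    samples of a run [i..k] are i and k+1, and the amplitude is the position
    change between them. Events abutting the segment edges (no flanking
    sample on one side) are discarded. Classes: small_corrective for
    amplitudes inside ``small_band`` (inclusive), catch_up_candidate above
    ``catch_up_min``, other in between / below.
    """
    spd = event_speed(segment, signal)
    pos = segment.pos if signal == "raw_forward" else segment.smoothed
    supra = spd > speed_threshold
    supra &= np.isfinite(spd)
    events: list[SaccadeLikeEvent] = []
    n = len(spd)
    i = 0
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j < n and supra[j]:
            j += 1
        # supra run covers entries [i, j); flanking sub-threshold samples:
        #  raw_forward  -- entry k spans samples k..k+1, so samples i and j
        #  smoothed_central -- entry k sits at sample k, so samples i-1 and j
        if signal == "raw_forward":
            pre, post = i, j
            edge = i == 0 or j >= n - 1  # no sub-threshold interval on one side
        else:
            pre, post = i - 1, j
            edge = pre < 0 or post > n - 1
        if edge or post >= len(pos):
            i = j
            continue
        if not (np.isfinite(pos[pre]).all() and np.isfinite(pos[post]).all()):
            i = j
            continue
        amp = float(np.linalg.norm(pos[post] - pos[pre]))
        lo, hi = small_band
        if lo <= amp <= hi:
            klass = "small_corrective"
        elif amp > catch_up_min:
            klass = "catch_up_candidate"
        else:
            klass = "other"
        events.append(
            SaccadeLikeEvent(
                onset_idx=pre,
                offset_idx=post,
                amplitude=amp,
                peak_speed=float(np.nanmax(spd[i:j])),
                klass=klass,
            )
        )
        i = j
    return events


def catch_up_saccades(
    events: list[SaccadeLikeEvent],
    gaze: np.ndarray,
    target: np.ndarray,
    min_amplitude: float = 1.5,
) -> int:
    """Count events with amplitude above the gate that reduce position error.

    Error is |gaze - target| at the nearest valid sample before onset versus
    after offset; the count requires a strict decrease.
    """
    gaze = np.asarray(gaze, float)
    target = np.asarray(target, float)
    if gaze.shape != target.shape:
        raise ValueError("gaze and target must be aligned frame by frame")
    err = np.linalg.norm(gaze - target, axis=1)
    count = 0
    for ev in events:
        if ev.amplitude <= min_amplitude:
            continue
        pre = ev.onset_idx
        while pre >= 0 and not np.isfinite(err[pre]):
            pre -= 1
        post = ev.offset_idx
        while post < len(err) and not np.isfinite(err[post]):
            post += 1
        if pre < 0 or post >= len(err):
            continue
        if err[post] < err[pre]:
            count += 1
    return count


def pursuit_onset_latency(
    segment: TrialSegment,
    target_vel: np.ndarray,
    motion_onset_s: float,
    speed_gate: float = 5.0,
    run_length: int = 3,
) -> float:
    """Latency (ms) from motion onset to sustained co-directional pursuit.

    First post-onset time at which gaze speed exceeds the gate and the
    gaze-velocity / target-velocity dot product stays positive for at least
    ``run_length`` consecutive samples; NaN if never reached.
    """
    t = segment.t
    vel = segment.vel
    ok = (
        (t >= motion_onset_s)
        & (segment.speed > speed_gate)
        & (np.einsum("ij,ij->i", np.nan_to_num(vel), np.asarray(target_vel, float)) > 0)
        & np.isfinite(vel).all(axis=1)
    )
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= run_length:
            start = i - run_length + 1
            return float((t[start] - motion_onset_s) * 1000.0)
    return float("nan")
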