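import numpy as np
import pandas as pd
import pytest

from oculoscreen import CohortSpec, TrialPlan, extract_features, simulate_cohort
from oculoscreen.preprocess import PreprocessConfig, ScreenGeometry, TrialSegment, smooth_and_differentiate


def make_segment(
    pos: np.ndarray,
    fs: float = 30.0,
    valid: np.ndarray | None = None,
    smooth: bool = True,
    subject_id: str = "s1",
    task_id: int = 1,
    trial_id: int = 0,
) -> TrialSegment:
    """Build a TrialSegment directly from a degree-space position array."""
    pos = np.asarray(pos, float)
    n = len(pos)
    t = np.arange(n) / fs
    if valid is None:
        valid = np.isfinite(pos).all(axis=1)
    if smooth:
        smoothed, vel, speed = smooth_and_differentiate(t, pos, PreprocessConfig())
    else:
        smoothed = pos.copy()
        vel = np.gradient(pos, axis=0) * fs
        speed = np.linalg.norm(vel, axis=1)
    dt = 1.0 / fs
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    raw_speed = np.full(n, np.nan)
    raw_speed[:-1] = step / dt
    invalid_fraction = float(1.0 - np.asarray(valid, bool).mean())
    return TrialSegment(
        subject_id=subject_id,
        task_id=task_id,
        trial_id=trial_id,
        t=t,
        pos=pos,
        valid=np.asarray(valid, bool),
        smoothed=smoothed,
        vel=vel,
        speed=speed,
        raw_speed=raw_speed,
        invalid_fraction=invalid_fraction,
        retained=invalid_fraction <= 0.30,
    )


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def tiny_plan() -> TrialPlan:
    """Reduced trial plan for fast structural tests."""
    return TrialPlan(task1_trials=3, task2_reps=1, task3_trials=2)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_plan):
    """Small cohort (4/group) with the default group structure."""
    return simulate_cohort(CohortSpec(n_per_group=4, trial_plan=tiny_plan, seed=5))


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    feats, qc = extract_features(tiny_cohort)
    return feats, qc


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized cohort: 35 subjects per group, fixed seed."""
    return simulate_cohort(CohortSpec(n_per_group=35, seed=11))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    feats, qc = extract_features(default_cohort)
    return feats, qc
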