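"""File interchange: gaze CSV dialect, schedule JSON, clinical CSV, reports.

The gaze dialect is one row per sample:
``subject_id, group, task_id, trial_id, t_s, lx_px, ly_px, l_valid, rx_px,
ry_px, r_valid``. Schedules are JSON keyed ``"<subject>/<task>"`` with
per-trial onset/offset and task parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import EvaluationReport
from .simulate import Cohort, CohortSpec

GAZE_COLUMNS = [
    "subject_id", "group", "task_id", "trial_id", "t_s",
    "lx_px", "ly_px", "l_valid", "rx_px", "ry_px", "r_valid",
]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.gaze[GAZE_COLUMNS].to_csv(out / "gaze.csv", index=False, float_format="%.4f")
    sched = {f"{sid}/{task}": trials for (sid, task), trials in cohort.schedules.items()}
    (out / "schedules.json").write_text(json.dumps(sched, indent=1))
    cohort.clinical.to_csv(out / "clinical.csv", index=False, float_format="%.4f")
    cohort.labels.rename("label").to_csv(out / "labels.csv")
    cohort.injected.to_csv(out / "injected_artifacts.csv", index=False, float_format="%.5f")
    return out


def read_cohort(in_dir: str | Path, spec: CohortSpec | None = None) -> Cohort:
    src = Path(in_dir)
    gaze = pd.read_csv(src / "gaze.csv")
    sched_raw = json.loads((src / "schedules.json").read_text())
    schedules = {}
    for key, trials in sched_raw.items():
        sid, task = key.rsplit("/", 1)
        schedules[(sid, int(task))] = trials
    clinical = pd.read_csv(src / "clinical.csv").set_index("subject_id", drop=False)
    labels = pd.read_csv(src / "labels.csv", index_col=0)["label"]
    injected_path = src / "injected_artifacts.csv"
    injected = pd.read_csv(injected_path) if injected_path.exists() else pd.DataFrame()
    return Cohort(
        spec=spec or CohortSpec(),
        gaze=gaze,
        schedules=schedules,
        clinical=clinical,
        labels=labels,
        injected=injected,
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


BUNDLE_SCHEMA_VERSION = 1


def save_bundle(estimator, path: str | Path) -> Path:
    """Serialize a fitted screener (scaler, imputer, forest, calibration map,
    threshold) with a schema version tag."""
    import joblib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump({"schema_version": BUNDLE_SCHEMA_VERSION, "estimator": estimator}, path)
    return path


def load_bundle(path: str | Path):
    import joblib

    payload = joblib.load(path)
    if payload.get("schema_version") != BUNDLE_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported bundle schema {payload.get('schema_version')!r}; "
            f"expected {BUNDLE_SCHEMA_VERSION}"
        )
    return payload["estimator"]


def write_report(report: EvaluationReport, out_dir: str | Path, name: str = "evaluation") -> Path:
    """Evaluation report as JSON (metrics, confusion) + CSV (subject scores)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "metrics": _jsonable(report.metrics),
        "confusion": _jsonable(report.confusion),
        "thresholds": _jsonable(report.thresholds),
    }
    (out / f"{name}.json").write_text(json.dumps(payload, indent=1))
    report.subject_scores.to_csv(out / f"{name}_subjects.csv")
    return out
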