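"""Evaluation experiments around the primary nested-LOSO screening model.

Each mode reruns the identical subject-wise protocol with one substitution:
alternative trial-level classifiers (baselines), task-subset feature sets
(ablation), eye-specific gaze streams (stream sensitivity), growing
training sets (learning curve), clinical covariates with or without gaze
features, and a grid of preprocessing variants (robustness).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .features import ALL_FEATURES, FeatureConfig, TASK_FEATURES, aggregate_subject
from .model import EvaluationReport, TrialForestScreener, nested_loso
from .pipeline import extract_features
from .preprocess import PreprocessConfig
from .simulate import Cohort

TASK_SUBSETS = {
    "task1": (1,),
    "task2": (2,),
    "task3": (3,),
    "task1+task2": (1, 2),
    "task2+task3": (2, 3),
    "task1+task3": (1, 3),
    "all": (1, 2, 3),
}
STREAMS = ("cyclopean", "amblyopic_eye", "fellow_eye", "both_valid_only")
CLINICAL_FEATURES = [
    "bcva_worse",
    "bcva_better",
    "iod_logmar",
    "log_stereo",
    "se_left",
    "se_right",
    "aniso_se",
]

EXPERIMENT_MODES = (
    "primary",
    "baselines",
    "task_ablation",
    "gaze_stream",
    "learning_curve",
    "clinical_only",
    "clinical_plus_gaze",
    "preprocessing_grid",
)


def feature_matrix(
    features: pd.DataFrame, labels: pd.Series, tasks: tuple[int, ...] = (1, 2, 3)
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Trial-row design matrix (X, y, subjects, names) for the given tasks.

    Rows are (subject, task, trial); features of other tasks are NaN by
    construction and handled by fold-internal median imputation.
    """
    cols = [c for t in tasks for c in TASK_FEATURES[t]]
    sub = features[features["task_id"].isin(tasks)]
    X = sub[cols].to_numpy(float)
    subjects = sub["subject_id"].to_numpy()
    y = labels.loc[subjects].to_numpy()
    return X, y, subjects, cols


def clinical_matrix(clinical: pd.DataFrame, labels: pd.Series):
    """Subject-level clinical design matrix (one row per subject)."""
    df = clinical.copy()
    df["log_stereo"] = np.log10(df["stereoacuity_arcsec"])
    df["aniso_se"] = (df["se_right"] - df["se_left"]).abs()
    X = df[CLINICAL_FEATURES].to_numpy(float)
    subjects = df["subject_id"].to_numpy()
    y = labels.loc[subjects].to_numpy()
    return X, y, subjects, list(CLINICAL_FEATURES)


def _default_screener(seed: int, **kw) -> TrialForestScreener:
    return TrialForestScreener(random_state=seed, **kw)


BASELINES = {
    "logistic_l2": lambda: LogisticRegression(C=1.0, max_iter=2000),  # default L2 penalty
    "linear_svm": lambda: LinearSVC(C=1.0, dual="auto", max_iter=5000),
    "gradient_boosting": lambda: GradientBoostingClassifier(n_estimators=150, max_depth=2),
}


def run_experiment(
    cohort: Cohort,
    mode: str = "primary",
    seed: int = 0,
    features: pd.DataFrame | None = None,
    n_estimators: int = 300,
    learning_fractions: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0),
):
    """Run one evaluation mode; returns an EvaluationReport or a dict of them.

    ``features`` may carry a precomputed cyclopean feature table to avoid
    re-extraction; stream and preprocessing modes always re-extract.
    """
    if mode not in EXPERIMENT_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {EXPERIMENT_MODES}")
    labels = cohort.labels
    if features is None and mode not in ("gaze_stream", "preprocessing_grid", "clinical_only"):
        features, _ = extract_features(cohort)

    if mode == "primary":
        X, y, subjects, _ = feature_matrix(features, labels)
        return nested_loso(X, y, subjects, _default_screener(seed, n_estimators=n_estimators), seed=seed)

    if mode == "baselines":
        X, y, subjects, _ = feature_matrix(features, labels)
        out: dict[str, EvaluationReport] = {}
        for name, make in BASELINES.items():
            est = TrialForestScreener(estimator=make(), random_state=seed)
            out[name] = nested_loso(X, y, subjects, est, seed=seed)
        return out

    if mode == "task_ablation":
        out = {}
        for name, tasks in TASK_SUBSETS.items():
            X, y, subjects, _ = feature_matrix(features, labels, tasks)
            out[name] = nested_loso(
                X, y, subjects, _default_screener(seed, n_estimators=n_estimators), seed=seed
            )
        return out

    if mode == "gaze_stream":
        out = {}
        for stream in STREAMS:
            feats, _ = extract_features(cohort, stream_kind=stream)
            X, y, subjects, _ = feature_matrix(feats, labels)
            out[stream] = nested_loso(
                X, y, subjects, _default_screener(seed, n_estimators=n_estimators), seed=seed
            )
        return out

    if mode == "learning_curve":
        X, y, subjects, _ = feature_matrix(features, labels)
        rng = np.random.default_rng(seed)
        uniq = pd.unique(subjects)
        lab = labels.loc[uniq].to_numpy()
        order = np.concatenate([rng.permutation(np.where(lab == c)[0]) for c in (0, 1)])
        rows = []
        for frac in learning_fractions:
            keep: list = []
            for c in (0, 1):
                ids = [uniq[i] for i in order if lab[i] == c]
                keep.extend(ids[: max(int(round(frac * len(ids))), 2)])
            mask = np.isin(subjects, keep)
            rep = nested_loso(
                X[mask], y[mask], subjects[mask],
                _default_screener(seed, n_estimators=n_estimators), seed=seed,
            )
            rows.append({"fraction": frac, "n_subjects": len(keep), "auc": rep.auc,
                         "accuracy": rep.metrics["accuracy"]})
        return pd.DataFrame(rows)

    if mode == "clinical_only":
        X, y, subjects, _ = clinical_matrix(cohort.clinical, labels)
        est = TrialForestScreener(estimator=LogisticRegression(C=1.0, max_iter=2000),
                                  random_state=seed)
        return nested_loso(X, y, subjects, est, seed=seed)

    if mode == "clinical_plus_gaze":
        Xc, yc, sc, names_c = clinical_matrix(cohort.clinical, labels)
        agg = aggregate_subject(features).set_index("subject_id")
        gaze = agg.loc[sc, ALL_FEATURES].to_numpy(float)
        X = np.hstack([Xc, gaze])
        return nested_loso(
            X, yc, sc, _default_screener(seed, n_estimators=n_estimators), seed=seed
        )

    # preprocessing_grid: robustness of the nested evaluation to the
    # fixation-segmentation and smoothing choices
    grid = [
        {"name": "idt_0.75deg", "fcfg": FeatureConfig(idt_dispersion_deg=0.75)},
        {"name": "idt_1.25deg", "fcfg": FeatureConfig(idt_dispersion_deg=1.25)},
        {"name": "min_dur_80ms", "fcfg": FeatureConfig(idt_min_duration_ms=80.0)},
        {"name": "min_dur_120ms", "fcfg": FeatureConfig(idt_min_duration_ms=120.0)},
        {"name": "lowpass_velocity", "pcfg": PreprocessConfig(smoother="lowpass")},
        {"name": "qc_25pct", "pcfg": PreprocessConfig(qc_threshold=0.25)},
        {"name": "qc_35pct", "pcfg": PreprocessConfig(qc_threshold=0.35)},
    ]
    out = {}
    for entry in grid:
        feats, _ = extract_features(
            cohort,
            preprocess_config=entry.get("pcfg"),
            feature_config=entry.get("fcfg"),
        )
        X, y, subjects, _ = feature_matrix(feats, labels)
        out[entry["name"]] = nested_loso(
            X, y, subjects, _default_screener(seed, n_estimators=n_estimators), seed=seed
        )
    return out
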