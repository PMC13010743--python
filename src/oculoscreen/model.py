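"""Calibrated trial-level random-forest screener with subject-wise evaluation.

The estimator consumes trial-level feature vectors x_{i,t} (subject i,
trial t). Standardization and median imputation are learned from training
rows only; a random forest produces trial posteriors p_{i,t} by averaging
tree posteriors; an isotonic map g fitted on inner out-of-fold predictions
calibrates them (p~_{i,t} = g(p_{i,t})); subject evidence is the median of
calibrated trial probabilities (p~_i = median_t p~_{i,t}); and the decision
threshold tau maximizes Youden's J on inner out-of-fold subject
probabilities. Everything learned transfers unchanged to held-out subjects,
so the outer leave-one-subject-out loop is leakage-free by construction.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression

from .stats import calibration_metrics, confusion_metrics, discrimination_metrics

__all__ = [
    "TrialForestScreener",
    "EvaluationReport",
    "select_threshold_youden",
    "calibrate_isotonic",
    "aggregate_and_decide",
    "nested_loso",
    "permutation_importance",
    "bundle_fingerprint",
]


def select_threshold_youden(probs: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1 for rule p >= tau.

    Candidates are the midpoints between adjacent sorted unique
    probabilities plus the boundary candidates (the smallest value, which
    calls everything positive, and just above the largest, which calls
    everything negative). Ties resolve to the smallest maximizing tau.
    Returns (tau, J).
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to select a threshold")
    u = np.unique(probs)
    cands = np.concatenate([[u[0]], (u[:-1] + u[1:]) / 2.0, [np.nextafter(u[-1], np.inf)]])
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_tau, best_j = cands[0], -np.inf
    for tau in cands:
        pred = probs >= tau
        j = (pred & (labels == 1)).sum() / n_pos + (~pred & (labels == 0)).sum() / n_neg - 1.0
        if j > best_j + 1e-12:
            best_tau, best_j = float(tau), float(j)
    return best_tau, best_j


def calibrate_isotonic(raw: np.ndarray, labels: np.ndarray) -> IsotonicRegression:
    """Pool-adjacent-violators isotonic map from raw scores to probabilities.

    Non-decreasing least-squares step function; queries outside the fitted
    range clamp to the boundary values. A single-class input yields a
    degenerate constant map (with a warning).
    """
    raw = np.asarray(raw, float)
    labels = np.asarray(labels).astype(float)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class calibration data: constant calibration map", stacklevel=2)
    iso = IsotonicRegression(out_of_bounds="clip")
    iso.fit(raw, labels)
    return iso


def aggregate_and_decide(
    trial_probs: np.ndarray, subjects: np.ndarray, tau: float
) -> pd.DataFrame:
    """Median-aggregate calibrated trial probabilities and threshold them.

    One row per subject: p~_i = median over that subject's valid (finite)
    trial probabilities, decision = 1 iff p~_i >= tau (boundary inclusive).
    Subjects with no valid trial get NaN probability and a missing decision.
    """
    df = pd.DataFrame({"subject_id": subjects, "p": np.asarray(trial_probs, float)})
    agg = df.groupby("subject_id")["p"].median()
    out = pd.DataFrame({"p_subject": agg})
    out["decision"] = np.where(np.isnan(agg), np.nan, (agg >= tau).astype(float))
    return out


def _grouped_stratified_folds(
    subjects: np.ndarray, labels: np.ndarray, n_splits: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Subject-wise folds, stratified by subject label. Returns subject-id arrays."""
    uniq = pd.DataFrame({"subject_id": subjects, "y": labels}).drop_duplicates("subject_id")
    folds: list[list] = [[] for _ in range(n_splits)]
    for _, sub in uniq.groupby("y"):
        ids = sub["subject_id"].to_numpy()
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            folds[i % n_splits].append(sid)
    return [np.array(f) for f in folds]


class TrialForestScreener(BaseEstimator, ClassifierMixin):
    """Random-forest screening classifier over trial-level feature vectors.

    Parameters
    ----------
    n_estimators, max_depth, min_samples_leaf, max_features:
        Forest shape; 300 Gini trees with per-node sqrt(p) feature
        subsampling and inverse-class-frequency weights by default.
    param_grid:
        Optional list of {max_depth, min_samples_leaf} dicts tuned in the
        inner loop by subject-level AUC; None fits the configured setting.
    inner_splits:
        Subject-wise stratified folds used to produce out-of-fold trial
        predictions for isotonic calibration and threshold selection.
    estimator:
        Optional alternative trial-level classifier (baselines); must expose
        predict_proba or decision_function.
    """

    def __init__(
        self,
        n_estimators: int = 300,
        max_depth: int | None = 8,
        min_samples_leaf: int = 3,
        max_features: str | int = "sqrt",
        param_grid: list[dict] | None = None,
        inner_splits: int = 5,
        calibrate: bool = True,
        estimator: BaseEstimator | None = None,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.param_grid = param_grid
        self.inner_splits = inner_splits
        self.calibrate = calibrate
        self.estimator = estimator
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _make_base(self, params: dict, seed: int) -> BaseEstimator:
        if self.estimator is not None:
            est = clone(self.estimator)
            if "random_state" in est.get_params():
                est.set_params(random_state=seed)
            return est
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            criterion="gini",
            max_depth=params.get("max_depth", self.max_depth),
            min_samples_leaf=params.get("min_samples_leaf", self.min_samples_leaf),
            max_features=self.max_features,
            class_weight="balanced",
            bootstrap=True,
            n_jobs=1,
            random_state=seed,
        )

    def _transform(self, X: np.ndarray) -> np.ndarray:
        Z = np.asarray(X, float).copy()
        for j in range(Z.shape[1]):
            col = Z[:, j]
            col[np.isnan(col)] = self.feature_medians_[j]
        return (Z - self.feature_means_) / self.feature_scales_

    @staticmethod
    def _score(est: BaseEstimator, Z: np.ndarray) -> np.ndarray:
        if hasattr(est, "predict_proba"):
            return est.predict_proba(Z)[:, 1]
        return est.decision_function(Z)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, subjects):
        """Learn scaler, imputer, forest, calibration map and threshold.

        ``X``: (n_trials, p); ``y``: 0/1 trial labels (the subject's label
        replicated over trials); ``subjects``: per-trial subject ids. All
        statistics are estimated from these rows only.
        """
        X = np.asarray(X, float)
        y = np.asarray(y).astype(int)
        subjects = np.asarray(subjects)
        if X.ndim != 2 or len(X) != len(y) or len(y) != len(subjects):
            raise ValueError("X, y and subjects must be aligned")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]

        self.feature_medians_ = np.nanmedian(X, axis=0)
        self.feature_medians_ = np.where(
            np.isnan(self.feature_medians_), 0.0, self.feature_medians_
        )
        Ximp = X.copy()
        for j in range(X.shape[1]):
            col = Ximp[:, j]
            col[np.isnan(col)] = self.feature_medians_[j]
        self.feature_means_ = Ximp.mean(axis=0)
        scales = Ximp.std(axis=0, ddof=0)
        zero_var = scales == 0
        if zero_var.any():
            warnings.warn(
                f"{int(zero_var.sum())} feature(s) with zero training variance left unscaled",
                stacklevel=2,
            )
            scales[zero_var] = 1.0
        self.feature_scales_ = scales
        Z = (Ximp - self.feature_means_) / self.feature_scales_

        rng = np.random.default_rng(self.random_state)
        folds = _grouped_stratified_folds(subjects, y, self.inner_splits, rng)
        grid = self.param_grid or [{}]

        oof_raw = {params_idx: np.full(len(y), np.nan) for params_idx in range(len(grid))}
        for params_idx, params in enumerate(grid):
            for f, fold_subjects in enumerate(folds):
                val = np.isin(subjects, fold_subjects)
                if val.all() or (~val).all() or len(np.unique(y[~val])) < 2:
                    continue
                est = self._make_base(params, seed=self.random_state + 131 * f + 7)
                est.fit(Z[~val], y[~val])
                oof_raw[params_idx][val] = self._score(est, Z[val])

        def subject_auc(raw: np.ndarray) -> float:
            ok = ~np.isnan(raw)
            sub = pd.DataFrame({"s": subjects[ok], "p": raw[ok], "y": y[ok]})
            per = sub.groupby("s").agg(p=("p", "median"), y=("y", "first"))
            if per["y"].nunique() < 2:
                return 0.5
            return discrimination_metrics(per["p"].to_numpy(), per["y"].to_numpy())["auc"]

        aucs = [subject_auc(oof_raw[i]) for i in range(len(grid))]
        best = int(np.argmax(aucs))
        self.best_params_ = grid[best]
        self.inner_auc_ = float(aucs[best])
        raw = oof_raw[best]
        ok = ~np.isnan(raw)

        if self.calibrate:
            self.calibrator_ = calibrate_isotonic(raw[ok], y[ok])
            cal = self.calibrator_.predict(raw[ok])
        else:
            self.calibrator_ = None
            cal = raw[ok]
        per = (
            pd.DataFrame({"s": subjects[ok], "p": cal, "y": y[ok]})
            .groupby("s")
            .agg(p=("p", "median"), y=("y", "first"))
        )
        if per["y"].nunique() < 2:
            # inner folds too small to produce out-of-fold scores for both
            # classes; fall back to a neutral threshold
            warnings.warn(
                "inner out-of-fold predictions cover a single class; threshold fixed at 0.5",
                stacklevel=2,
            )
            self.threshold_, self.inner_youden_j_ = 0.5, 0.0
        else:
            self.threshold_, self.inner_youden_j_ = select_threshold_youden(
                per["p"].to_numpy(), per["y"].to_numpy()
            )

        final = self._make_base(self.best_params_, seed=self.random_state)
        final.fit(Z, y)
        self.forest_ = final
        return self

    def predict_trial_proba(self, X) -> np.ndarray:
        """Calibrated trial-level probabilities p~_{i,t} = g(p_{i,t})."""
        Z = self._transform(np.asarray(X, float))
        raw = self._score(self.forest_, Z)
        if self.calibrator_ is None:
            return raw
        return self.calibrator_.predict(raw)

    def predict_subject(self, X, subjects) -> pd.DataFrame:
        """Aggregated subject probabilities and thresholded decisions."""
        return aggregate_and_decide(self.predict_trial_proba(X), subjects, self.threshold_)

    def predict_proba(self, X):
        p = self.predict_trial_proba(X)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_trial_proba(X) >= self.threshold_).astype(int)


def bundle_fingerprint(est: TrialForestScreener, probe: np.ndarray) -> np.ndarray:
    """Deterministic numeric digest of every learned fold artifact."""
    parts = [
        est.feature_medians_,
        est.feature_means_,
        est.feature_scales_,
        np.array([est.threshold_, est.inner_youden_j_]),
        est.predict_trial_proba(probe),
    ]
    return np.concatenate([np.asarray(p, float).ravel() for p in parts])


@dataclass
class EvaluationReport:
    """Subject-level scores and summary metrics from a subject-wise evaluation."""

    subject_scores: pd.DataFrame  # index subject_id: p_subject, decision, label
    metrics: dict[str, float]
    confusion: dict[str, int]
    thresholds: list[float] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def auc(self) -> float:
        return self.metrics["auc"]


def _fold_seed(master_seed: int, subject_id) -> int:
    return (int(master_seed) * 1000003 + zlib.crc32(str(subject_id).encode())) % (2**31 - 1)


def summarize_subject_scores(scores: pd.DataFrame, thresholds: list[float] | None = None) -> EvaluationReport:
    """Discrimination, calibration and operating-point metrics from scores."""
    ok = scores["p_subject"].notna()
    s = scores[ok]
    disc = discrimination_metrics(s["p_subject"].to_numpy(), s["label"].to_numpy())
    calm = calibration_metrics(s["p_subject"].to_numpy(), s["label"].to_numpy())
    pred = s["decision"].to_numpy()
    lab = s["label"].to_numpy()
    tp = int(((pred == 1) & (lab == 1)).sum())
    fn = int(((pred == 0) & (lab == 1)).sum())
    tn = int(((pred == 0) & (lab == 0)).sum())
    fp = int(((pred == 1) & (lab == 0)).sum())
    mt = confusion_metrics(tp, fn, tn, fp)
    metrics = {**disc, **calm, **mt.as_dict()}
    return EvaluationReport(
        subject_scores=scores,
        metrics=metrics,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        thresholds=thresholds or [],
    )


def nested_loso(
    X,
    y,
    subjects,
    estimator: TrialForestScreener | None = None,
    seed: int = 0,
    collect_fingerprints: bool = False,
    probe: np.ndarray | None = None,
    corrupt_heldout=None,
) -> EvaluationReport:
    """Nested leave-one-subject-out evaluation.

    One outer fold per subject; within each outer training set the
    estimator's own inner subject-wise cross-validation tunes, calibrates
    and selects the threshold, and the learned bundle is applied unchanged
    to the held-out subject. Per-fold seeds derive only from ``seed`` and
    the held-out subject id, so reruns are reproducible and fold artifacts
    cannot depend on held-out rows.

    ``corrupt_heldout(subject_id, block) -> block`` is a leakage-audit seam:
    when given, each fold's held-out feature block is replaced by its output
    before any fitting or prediction in that fold. Learned fold artifacts
    must be bit-identical with and without it.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    subjects = np.asarray(subjects)
    proto = estimator if estimator is not None else TrialForestScreener()
    uniq = pd.unique(subjects)
    if len(uniq) < 4:
        raise ValueError("nested LOSO needs at least 4 subjects")
    rows = []
    taus = []
    fingerprints = {}
    for sid in uniq:
        test = subjects == sid
        X_fold = X
        if corrupt_heldout is not None:
            X_fold = X.copy()
            X_fold[test] = corrupt_heldout(sid, X_fold[test])
        est = clone(proto)
        est.set_params(random_state=_fold_seed(seed, sid))
        est.fit(X_fold[~test], y[~test], subjects[~test])
        taus.append(est.threshold_)
        if collect_fingerprints:
            probe_x = probe if probe is not None else np.zeros((2, X.shape[1]))
            fingerprints[sid] = bundle_fingerprint(est, probe_x)
        pred = est.predict_subject(X_fold[test], subjects[test])
        rows.append(
            {
                "subject_id": sid,
                "p_subject": float(pred["p_subject"].iloc[0]),
                "decision": float(pred["decision"].iloc[0]),
                "label": int(y[test][0]),
                "tau": est.threshold_,
            }
        )
    scores = pd.DataFrame(rows).set_index("subject_id")
    report = summarize_subject_scores(scores, thresholds=taus)
    if collect_fingerprints:
        report.extra["fingerprints"] = fingerprints
    return report


def permutation_importance(
    estimator: TrialForestScreener,
    X,
    y,
    subjects,
    feature_names: list[str] | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean decrease in subject-level AUC under subject-block permutation.

    For each feature, whole-subject blocks of the column are reassigned
    among subjects (values tiled/truncated to the receiving subject's trial
    count), the subject-level AUC is recomputed, and the drop from baseline
    is averaged over repeats. Importances are also normalized to sum to 1
    (negative drops clipped at 0).
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    subjects = np.asarray(subjects)
    rng = np.random.default_rng(seed)
    uniq = pd.unique(subjects)
    idx_by_subject = {s: np.where(subjects == s)[0] for s in uniq}
    labels = np.array([y[idx_by_subject[s]][0] for s in uniq])

    def subject_auc(Xv: np.ndarray) -> float:
        p = estimator.predict_trial_proba(Xv)
        med = np.array([np.median(p[idx_by_subject[s]]) for s in uniq])
        return discrimination_metrics(med, labels)["auc"]

    base = subject_auc(X)
    p_feat = X.shape[1]
    drops = np.zeros(p_feat)
    for j in range(p_feat):
        acc = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            perm = rng.permutation(len(uniq))
            for s_to, s_from in zip(uniq, uniq[perm]):
                dst = idx_by_subject[s_to]
                src_vals = X[idx_by_subject[s_from], j]
                reps = int(np.ceil(len(dst) / len(src_vals)))
                Xp[dst, j] = np.tile(src_vals, reps)[: len(dst)]
            acc += base - subject_auc(Xp)
        drops[j] = acc / n_repeats
    names = feature_names or [f"f{j}" for j in range(p_feat)]
    clipped = np.clip(drops, 0, None)
    total = clipped.sum()
    return pd.DataFrame(
        {
            "feature": names,
            "auc_drop": drops,
            "importance": clipped / total if total > 0 else clipped,
        }
    ).sort_values("auc_drop", ascending=False, ignore_index=True)
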