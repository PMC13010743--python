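"""Statistical reporting layer for the screening pipeline.

Group comparisons with effect sizes and Benjamini-Hochberg FDR control,
operating-point metrics with Wilson intervals, discrimination and calibration
metrics with subject-level bootstrap CIs, order-effect checks, and
prevalence-adjusted predictive values for community screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, brier_score_loss, roc_auc_score
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MetricTable",
    "PrevalenceRow",
    "confusion_metrics",
    "wilson_ci",
    "prevalence_ppv_npv",
    "prevalence_table",
    "cohens_d",
    "rank_biserial",
    "group_compare",
    "discrimination_metrics",
    "calibration_metrics",
    "bootstrap_ci",
    "order_effect_check",
]


@dataclass
class MetricTable:
    """Operating-point metrics computed from a 2x2 confusion matrix.

    Undefined metrics (empty margin, e.g. PPV with no positive calls) are NaN.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass
class PrevalenceRow:
    prevalence: float
    ppv: float
    npv: float


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(tp: int, fn: int, tn: int, fp: int, *, ci_level: float = 0.95) -> MetricTable:
    """All five operating-point metrics from confusion counts.

    Sensitivity/specificity (and accuracy) carry Wilson score intervals at
    ``ci_level``; metrics with an empty margin come back as NaN.
    """
    counts = (tp, fn, tn, fp)
    if any(c < 0 for c in counts) or not all(float(c).is_integer() for c in counts):
        raise ValueError("confusion counts must be non-negative integers")
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion matrix")
    table = MetricTable(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, n),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )
    for name, k, m in [
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("accuracy", tp + tn, n),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ]:
        if m > 0:
            table.ci[name] = wilson_ci(k, m, level=ci_level)
    return table


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    lo = 0.0 if k == 0 else float(np.clip(lo, 0.0, 1.0))  # exact boundary cases
    hi = 1.0 if k == n else float(np.clip(hi, 0.0, 1.0))
    return lo, hi


def prevalence_ppv_npv(sens: float, spec: float, prevalence: float) -> PrevalenceRow:
    """Expected PPV/NPV at a given disease prevalence via Bayes' rule.

    PPV = sens*pi / (sens*pi + (1-spec)(1-pi));
    NPV = spec(1-pi) / (spec(1-pi) + (1-sens)pi).
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be strictly inside (0, 1)")
    for name, v in [("sensitivity", sens), ("specificity", spec)]:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    pi = prevalence
    ppv_den = sens * pi + (1.0 - spec) * (1.0 - pi)
    npv_den = spec * (1.0 - pi) + (1.0 - sens) * pi
    ppv = sens * pi / ppv_den if ppv_den > 0 else float("nan")
    npv = spec * (1.0 - pi) / npv_den if npv_den > 0 else float("nan")
    return PrevalenceRow(prevalence=pi, ppv=ppv, npv=npv)


def prevalence_table(sens: float, spec: float, prevalences: list[float]) -> pd.DataFrame:
    rows = [prevalence_ppv_npv(sens, spec, pi) for pi in prevalences]
    return pd.DataFrame(
        {"prevalence": [r.prevalence for r in rows], "ppv": [r.ppv for r in rows], "npv": [r.npv for r in rows]}
    )


def cohens_d(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Cohen's d with the pooled standard deviation.

    d = (m2 - m1) / s_pooled,  s_pooled^2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2).
    Equal group sizes reduce to s_pooled = sqrt((s1^2 + s2^2)/2).
    """
    if s1 < 0 or s2 < 0 or n1 < 2 or n2 < 2:
        raise ValueError("need s >= 0 and n >= 2 per group")
    pooled = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        return float("nan")
    return (m2 - m1) / pooled


def rank_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-biserial correlation r = 2U/(n1 n2) - 1 from the Mann-Whitney U of y vs x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    u = sps.mannwhitneyu(y, x, alternative="two-sided").statistic
    return 2.0 * u / (len(x) * len(y)) - 1.0


def group_compare(
    aggregates: pd.DataFrame,
    labels: pd.Series,
    q: float = 0.05,
    *,
    family: pd.Series | None = None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-group comparison with normality-gated test choice.

    Uses a two-sided t-test with Cohen's d when Shapiro-Wilk does not reject
    normality (p >= ``normality_alpha``) in both groups, otherwise a
    Mann-Whitney U with rank-biserial correlation. BH step-up adjustment is
    applied within each feature family (``family`` maps column -> family id,
    default: one family for all columns).

    ``aggregates``: one row per subject, one column per feature.
    ``labels``: 0/1 per subject (1 = case group).
    """
    labels = np.asarray(labels).astype(int)
    records = []
    for col in aggregates.columns:
        v = aggregates[col].to_numpy(float)
        g0 = v[(labels == 0) & ~np.isnan(v)]
        g1 = v[(labels == 1) & ~np.isnan(v)]
        fam = family[col] if family is not None else "all"
        if len(g0) < 3 or len(g1) < 3:
            records.append((col, fam, "skipped", np.nan, np.nan, np.nan, "too few subjects"))
            continue
        if np.std(g0) == 0 and np.std(g1) == 0:
            records.append((col, fam, "skipped", np.nan, np.nan, np.nan, "constant feature"))
            continue
        normal = (
            sps.shapiro(g0).pvalue >= normality_alpha and sps.shapiro(g1).pvalue >= normality_alpha
        )
        if normal:
            p = sps.ttest_ind(g0, g1).pvalue
            eff = cohens_d(np.mean(g0), np.std(g0, ddof=1), len(g0), np.mean(g1), np.std(g1, ddof=1), len(g1))
            test = "t"
        else:
            p = sps.mannwhitneyu(g0, g1, alternative="two-sided").pvalue
            eff = rank_biserial(g0, g1)
            test = "mannwhitney"
        records.append((col, fam, test, float(p), np.nan, float(eff), ""))
    out = pd.DataFrame(
        records, columns=["feature", "family", "test", "p", "p_adj", "effect_size", "note"]
    )
    for fam in out["family"].unique():
        mask = (out["family"] == fam) & out["p"].notna()
        if mask.sum() > 0:
            out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], alpha=q, method="fdr_bh")[1]
    out["rejected"] = out["p_adj"] < q
    return out


def discrimination_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Subject-level AUC (rank statistic, tie-corrected) and average precision."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for discrimination metrics")
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "ap": float(average_precision_score(labels, scores)),
    }


def calibration_metrics(probs: np.ndarray, labels: np.ndarray, n_bins: int = 10) -> dict[str, float]:
    """Brier score and expected calibration error over equal-width bins.

    ECE = sum_b (n_b/n) |acc_b - conf_b| with bins [0, 1/n_bins), ...,
    [1-1/n_bins, 1].
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels).astype(int)
    if probs.size == 0:
        raise ValueError("empty input")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    brier = brier_score_loss(labels, probs)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1], right=False), 0, n_bins - 1)
    ece = 0.0
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        ece += mask.mean() * abs(labels[mask].mean() - probs[mask].mean())
    return {"brier": float(brier), "ece": float(ece)}


def bootstrap_ci(
    metric_fn,
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI resampling subjects (the grouped unit), never trials.

    Resamples for which the metric is undefined (e.g. a single class drawn)
    are skipped and counted toward n_boot.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    n = len(scores)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(labels[idx])) < 2:
            continue
        vals.append(metric_fn(scores[idx], labels[idx]))
    alpha = 1.0 - level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def order_effect_check(qc: pd.DataFrame) -> pd.DataFrame:
    """Early-vs-late invalid-fraction shift per task and group.

    For each subject and task, retained trials are split into an early half
    and a late half (the early half receives the extra trial when the count is
    odd) and the difference of mean invalid fractions (late - early, in
    percentage points) is tested with a two-sided paired Wilcoxon signed-rank
    test (Pratt zero handling). Subjects with fewer than 2 retained trials in
    a task are excluded from that task's row.

    ``qc`` needs columns subject_id, group, task_id, trial_id, invalid_fraction,
    retained.
    """
    rows = []
    kept = qc[qc["retained"]]
    for (task, grp), sub in kept.groupby(["task_id", "group"]):
        deltas = []
        for _, s in sub.groupby("subject_id"):
            s = s.sort_values("trial_id")
            frac = s["invalid_fraction"].to_numpy(float) * 100.0
            if len(frac) < 2:
                continue
            cut = (len(frac) + 1) // 2  # early half gets the extra trial
            deltas.append(frac[cut:].mean() - frac[:cut].mean())
        deltas = np.asarray(deltas)
        if len(deltas) == 0:
            continue
        if np.all(deltas == 0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(deltas, zero_method="pratt").pvalue)
        rows.append(
            {
                "task_id": task,
                "group": grp,
                "n_subjects": len(deltas),
                "delta_invalid_pct_mean": float(deltas.mean()),
                "delta_invalid_pct_sd": float(deltas.std(ddof=1)) if len(deltas) > 1 else np.nan,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
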