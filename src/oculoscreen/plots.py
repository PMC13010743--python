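"""Static diagnostic figures: ROC, precision-recall, reliability, probability
strip, learning curve and permutation importance."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.calibration import calibration_curve
from sklearn.metrics import precision_recall_curve, roc_curve

from .model import EvaluationReport


def plot_report(report: EvaluationReport, out_dir: str | Path, prefix: str = "model") -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = report.subject_scores.dropna(subset=["p_subject"])
    y = s["label"].to_numpy()
    p = s["p_subject"].to_numpy()
    paths = []

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    fpr, tpr, _ = roc_curve(y, p)
    axes[0, 0].plot(fpr, tpr)
    axes[0, 0].plot([0, 1], [0, 1], "--", color="gray")
    axes[0, 0].set(xlabel="1 - specificity", ylabel="sensitivity",
                   title=f"ROC (AUC = {report.metrics['auc']:.3f})")
    prec, rec, _ = precision_recall_curve(y, p)
    axes[0, 1].plot(rec, prec)
    axes[0, 1].set(xlabel="recall", ylabel="precision",
                   title=f"PR (AP = {report.metrics['ap']:.3f})")
    frac_pos, mean_pred = calibration_curve(y, p, n_bins=5, strategy="uniform")
    axes[1, 0].plot(mean_pred, frac_pos, "o-")
    axes[1, 0].plot([0, 1], [0, 1], "--", color="gray")
    axes[1, 0].set(xlabel="predicted probability", ylabel="observed fraction",
                   title=f"Reliability (Brier = {report.metrics['brier']:.3f})")
    jitter = np.random.default_rng(0).uniform(-0.08, 0.08, len(p))
    axes[1, 1].scatter(y + jitter, p, alpha=0.6, s=18)
    if report.thresholds:
        axes[1, 1].axhline(float(np.median(report.thresholds)), ls="--", color="red")
    axes[1, 1].set(xticks=[0, 1], xticklabels=["control", "amblyopia"],
                   ylabel="aggregated probability", title="Subject probabilities")
    fig.tight_layout()
    path = out / f"{prefix}_performance.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)
    return paths


def plot_learning_curve(curve: pd.DataFrame, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["n_subjects"], curve["auc"], "o-")
    ax.set(xlabel="training subjects", ylabel="subject-level AUC", title="Learning curve")
    fig.tight_layout()
    path = out / "learning_curve.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_importance(table: pd.DataFrame, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    t = table.sort_values("importance")
    ax.barh(t["feature"], t["importance"])
    ax.set(xlabel="normalized permutation importance")
    fig.tight_layout()
    path = out / "permutation_importance.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
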