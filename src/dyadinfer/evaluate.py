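"""Model assessment: prediction accuracies, classification metrics, power,
and per-trial trajectory summaries.

Partner prediction is scored by thresholding the predicted touch
probability at 0.5 (ties count as predicting a touch); self prediction by
exact match between the argmin-G action and the observed action.  The
binary-classification suite (precision/recall/F1/AUC/MCC) treats a partner
touch (a_p = 1) as the positive class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import (
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

__all__ = [
    "self_accuracy",
    "partner_accuracy",
    "harmonic_f1",
    "classification_report",
    "ztest_power",
    "trajectory_summary",
    "evaluate_trace",
    "plot_trajectories",
]


def self_accuracy(predicted, observed) -> float:
    """Proportion of trials where the predicted self action matches the
    observed one."""
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("predicted and observed must be equal-length and non-empty")
    return float(np.mean(predicted == observed))


def partner_accuracy(probabilities, observed, threshold: float = 0.5) -> float:
    """Proportion of trials where thresholding P(A_p = 1) at >= threshold
    reproduces the observed partner action."""
    probabilities = np.asarray(probabilities, dtype=float)
    observed = np.asarray(observed)
    if probabilities.shape != observed.shape or probabilities.size == 0:
        raise ValueError("probabilities and observed must be equal-length and non-empty")
    if np.any((probabilities < 0) | (probabilities > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    predicted = (probabilities >= threshold).astype(int)
    return float(np.mean(predicted == observed))


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 from a (precision, recall) pair; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def classification_report(predicted, observed, scores=None) -> dict[str, float]:
    """Precision, recall, F1, MCC and AUC for binary partner prediction.

    ``scores`` (continuous, e.g. predicted probabilities) feed the AUC;
    without them AUC is reported as NaN.  MCC and AUC are NaN when the
    observed vector contains a single class — undefined, not zero.
    Precision (recall) is NaN when there are no predicted (observed)
    positives.
    """
    predicted = np.asarray(predicted).astype(int)
    observed = np.asarray(observed).astype(int)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("predicted and observed must be equal-length and non-empty")

    precision = (
        float(precision_score(observed, predicted, zero_division=np.nan))
        if predicted.sum() > 0 else float("nan")
    )
    recall = (
        float(recall_score(observed, predicted, zero_division=np.nan))
        if observed.sum() > 0 else float("nan")
    )
    if math.isnan(precision) or math.isnan(recall):
        f1 = float("nan")
    else:
        f1 = harmonic_f1(precision, recall)

    both_classes = len(np.unique(observed)) == 2
    mcc = float(matthews_corrcoef(observed, predicted)) if both_classes else float("nan")
    if scores is not None and both_classes:
        auc = float(roc_auc_score(observed, np.asarray(scores, dtype=float)))
    else:
        auc = float("nan")
    return {"precision": precision, "recall": recall, "f1": f1, "mcc": mcc, "auc": auc}


def ztest_power(effect: float, se: float, alpha: float = 0.05,
                two_tailed: bool = True) -> float:
    """Power of a z test with noncentrality |effect|/se.

    Two-tailed: Phi(|mu|/sigma - z_{1-alpha/2}) + Phi(-|mu|/sigma - z_{1-alpha/2});
    at effect = 0 this reduces to alpha.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    ncp = abs(effect) / se
    if two_tailed:
        zcrit = norm.ppf(1.0 - alpha / 2.0)
        return float(norm.cdf(ncp - zcrit) + norm.cdf(-ncp - zcrit))
    zcrit = norm.ppf(1.0 - alpha)
    return float(norm.cdf(ncp - zcrit))


def evaluate_trace(trace: pd.DataFrame, hard_only: bool = False) -> dict[str, float]:
    """Score one session trace.

    Returns self/partner prediction accuracy plus the classification suite
    over the partner predictions (positive class: partner touch).  With
    ``hard_only`` the metrics are restricted to Hard-object trials, the
    subset where the category is genuinely ambiguous.
    """
    df = trace[trace["difficulty"] == 1] if hard_only else trace
    if df.empty:
        raise ValueError("trace has no rows for the requested subset")
    probs = df["predicted_partner_prob"].to_numpy()
    pred_partner = (probs >= 0.5).astype(int)
    out = {
        "acc_self": self_accuracy(df["predicted_self_action"].to_numpy(),
                                  df["a_s"].to_numpy()),
        "acc_partner": partner_accuracy(probs, df["a_p"].to_numpy()),
    }
    out.update(classification_report(pred_partner, df["a_p"].to_numpy(), scores=probs))
    out["mean_fe_min"] = float(df["fe_min"].mean())
    return out


def trajectory_summary(traces: list[pd.DataFrame], hard_only: bool = True) -> pd.DataFrame:
    """Per-trial-position mean curves over a collection of session traces.

    Trials are ranked within each trace (Hard-object subset by default, so
    positions run 1..12 for a standard session); at each position the mean
    partner-prediction correctness, self-prediction correctness and minimum
    free energy are averaged across traces, with the contributing count.
    """
    if not traces:
        raise ValueError("need at least one trace")
    parts = []
    for k, tr in enumerate(traces):
        df = (tr[tr["difficulty"] == 1] if hard_only else tr).copy()
        df = df.sort_values("trial_index").reset_index(drop=True)
        df["position"] = np.arange(1, len(df) + 1)
        df["partner_correct"] = (
            (df["predicted_partner_prob"] >= 0.5).astype(int) == df["a_p"]
        ).astype(float)
        df["self_correct"] = (df["predicted_self_action"] == df["a_s"]).astype(float)
        df["trace"] = k
        parts.append(df[["position", "partner_correct", "self_correct", "fe_min", "trace"]])
    pooled = pd.concat(parts, ignore_index=True)
    summary = pooled.groupby("position").agg(
        partner_accuracy=("partner_correct", "mean"),
        self_accuracy=("self_correct", "mean"),
        mean_fe_min=("fe_min", "mean"),
        n=("trace", "count"),
    ).reset_index()
    return summary


def plot_trajectories(summaries: dict[str, pd.DataFrame], out_path: str) -> None:
    """Plot accuracy and free-energy trajectories for labelled conditions.

    ``summaries`` maps a condition label (e.g. "bot gamma0=0.9") to a
    trajectory_summary frame; writes a three-panel figure to ``out_path``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    panels = [
        ("partner_accuracy", "Partner prediction accuracy"),
        ("self_accuracy", "Self prediction accuracy"),
        ("mean_fe_min", "Mean minimum free energy"),
    ]
    for ax, (col, title) in zip(axes, panels):
        for label, summ in summaries.items():
            ax.plot(summ["position"], summ[col], marker="o", label=label)
        ax.set_xlabel("Hard-object trial position")
        ax.set_title(title)
        ax.grid(alpha=0.3)
    axes[0].set_ylim(-0.05, 1.05)
    axes[1].set_ylim(-0.05, 1.05)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
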