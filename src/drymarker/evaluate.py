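"""Validation metrics for three-class tolerance prediction.

Confusion matrices follow the convention rows = predicted class, columns =
observed class (class order low / intermediate / high), so column totals
are the observed class sizes. Sensitivity of a class is its true-positive
rate, counts[c, c] / column total; specificity is one-vs-rest, TN / (TN +
FP) on the collapsed 2x2 table. Overall accuracy is the trace over the
grand total. Per-trial accuracies quantify how stable a model's
predictions are across independent validation environments.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .tolerance import TOLERANCE_CLASSES

__all__ = ["ConfusionSummary", "confusion", "per_trial_accuracy"]


@dataclasses.dataclass
class ConfusionSummary:
    """3x3 confusion counts (rows predicted, columns observed) + metrics."""

    counts: pd.DataFrame
    n_total: int
    overall_accuracy: float
    sensitivity: dict
    specificity: dict

    def to_dict(self) -> dict:
        return {
            "counts": {r: self.counts.loc[r].to_dict() for r in self.counts.index},
            "n_total": self.n_total,
            "overall_accuracy": self.overall_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def to_frame(self) -> pd.DataFrame:
        """Display table in percent rounded to one decimal, counts intact."""
        df = self.counts.copy()
        df.loc["total"] = self.counts.sum(axis=0)
        df.loc["sensitivity_pct"] = [
            round(100 * self.sensitivity[c], 1) if np.isfinite(self.sensitivity[c]) else np.nan
            for c in df.columns
        ]
        df.loc["specificity_pct"] = [
            round(100 * self.specificity[c], 1) if np.isfinite(self.specificity[c]) else np.nan
            for c in df.columns
        ]
        return df


def summarize_counts(counts: pd.DataFrame) -> ConfusionSummary:
    """Metrics from an existing confusion-count table (predicted x observed)."""
    counts = counts.astype(int)
    n_total = int(counts.to_numpy().sum())
    if n_total == 0:
        raise ValueError("empty confusion table")
    mat = counts.to_numpy()
    diag = np.diag(mat)
    overall = float(diag.sum() / n_total)
    sensitivity = {}
    specificity = {}
    for i, c in enumerate(counts.columns):
        col_total = mat[:, i].sum()
        sensitivity[c] = float(diag[i] / col_total) if col_total > 0 else float("nan")
        fp = mat[i, :].sum() - mat[i, i]
        tn = n_total - mat[i, :].sum() - mat[:, i].sum() + mat[i, i]
        specificity[c] = float(tn / (tn + fp)) if (tn + fp) > 0 else float("nan")
    return ConfusionSummary(
        counts=counts,
        n_total=n_total,
        overall_accuracy=overall,
        sensitivity=sensitivity,
        specificity=specificity,
    )


def confusion(pred, obs, classes=TOLERANCE_CLASSES) -> ConfusionSummary:
    """Confusion summary of predicted versus observed class labels.

    Labels outside ``classes`` raise; a class absent from the observations
    gets NaN sensitivity. Empty input raises.
    """
    pred = np.asarray(pred)
    obs = np.asarray(obs)
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have the same length")
    unknown = set(pred) | set(obs) - set(classes)
    unknown -= set(classes)
    if unknown:
        raise ValueError(f"label(s) outside the class set {classes}: {sorted(unknown)}")
    counts = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for p, o in zip(pred, obs):
        counts.loc[p, o] += 1
    counts.index.name = "predicted"
    counts.columns.name = "observed"
    return summarize_counts(counts)


def per_trial_accuracy(pred, obs, trials) -> pd.DataFrame:
    """Prediction accuracy within each trial, plus the pooled overall row.

    Returns a DataFrame indexed by trial id (with a final ``overall`` row)
    with columns ``n`` and ``accuracy``.
    """
    df = pd.DataFrame({"pred": np.asarray(pred), "obs": np.asarray(obs), "trial": np.asarray(trials)})
    if df.empty:
        raise ValueError("empty input")
    rows = {}
    for trial, sub in df.groupby("trial", sort=True):
        rows[trial] = {"n": len(sub), "accuracy": float((sub["pred"] == sub["obs"]).mean())}
    rows["overall"] = {"n": len(df), "accuracy": float((df["pred"] == df["obs"]).mean())}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "trial"
    out["n"] = out["n"].astype(int)
    return out
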