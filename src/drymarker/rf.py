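"""Random-Forest classification and backward-elimination marker selection.

A bagged ensemble of decision trees (scikit-learn's
:class:`~sklearn.ensemble.RandomForestClassifier`) predicts the tolerance
class of a sample from its feature profile. Model quality is estimated
out-of-bag (OOB): each sample is voted on only by trees whose bootstrap
sample excluded it, giving an internally cross-validated error rate.
Feature relevance is the Gini importance (mean decrease in impurity).

Marker panels are extracted by iterative backward elimination: starting
from the full model, a fixed fraction of the least-important features is
removed at each step and the model refit, recording the OOB error and its
binomial standard error. The final panel is picked by the 1-SE rule — the
smallest feature set whose OOB error is within one standard error of the
minimum across all steps — trading a negligible loss of accuracy for a
much smaller assay.

Defaults: ntree = 1000 trees and mtry = floor(sqrt(p)) features per split
(the standard classification default; mtry is configurable, and mtry = p
turns the ensemble into plain bagged trees). Elimination order is taken
from the full model's importance and not recomputed at later steps, which
avoids selection bias from re-ranking on ever-smaller models;
``recompute_importance=True`` switches to per-step re-ranking.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .containers import FeatureMatrix

__all__ = [
    "RFFit",
    "SelectionStep",
    "SelectionTrace",
    "train_rf",
    "oob_se",
    "backward_eliminate",
    "apply_one_se_rule",
    "predict",
]


@dataclasses.dataclass
class RFFit:
    """A fitted Random-Forest classifier with OOB summaries."""

    feature_ids: list
    classes: list
    oob_error: float
    per_class_oob: dict
    importance: pd.Series  # Gini importance per feature
    ntree: int
    mtry: int
    seed: int
    model: RandomForestClassifier

    def save(self, path) -> None:
        """Serialize to a directory: JSON summary + joblib model bundle."""
        import joblib

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        summary = {
            "feature_ids": list(self.feature_ids),
            "classes": list(self.classes),
            "oob_error": self.oob_error,
            "per_class_oob": self.per_class_oob,
            "importance": {k: float(v) for k, v in self.importance.items()},
            "ntree": self.ntree,
            "mtry": self.mtry,
            "seed": self.seed,
        }
        (path / "model.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        joblib.dump(self.model, path / "model.joblib")

    @classmethod
    def load(cls, path) -> "RFFit":
        import joblib

        path = Path(path)
        summary = json.loads((path / "model.json").read_text())
        model = joblib.load(path / "model.joblib")
        return cls(
            feature_ids=summary["feature_ids"],
            classes=summary["classes"],
            oob_error=summary["oob_error"],
            per_class_oob=summary["per_class_oob"],
            importance=pd.Series(summary["importance"]),
            ntree=summary["ntree"],
            mtry=summary["mtry"],
            seed=summary["seed"],
            model=model,
        )


@dataclasses.dataclass
class SelectionStep:
    n_features: int
    feature_ids: list
    oob_error: float
    oob_se: float


@dataclasses.dataclass
class SelectionTrace:
    """Ordered backward-elimination record; step 0 is the full model."""

    steps: list
    chosen_step: int
    n_samples: int

    @property
    def chosen(self) -> SelectionStep:
        return self.steps[self.chosen_step]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "n_features": [s.n_features for s in self.steps],
                "oob_error": [s.oob_error for s in self.steps],
                "oob_se": [s.oob_se for s in self.steps],
            }
        )
        df.index.name = "step"
        df["chosen"] = False
        df.loc[self.chosen_step, "chosen"] = True
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _resolve_mtry(mtry, p: int) -> int:
    if mtry in (None, "auto", "sqrt"):
        return max(1, math.floor(math.sqrt(p)))
    mtry = int(mtry)
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}], got {mtry}")
    return mtry


def oob_se(err: float, n_samples: int) -> float:
    """Binomial standard error of an OOB error rate: sqrt(e(1-e)/n)."""
    if not 0.0 <= err <= 1.0:
        raise ValueError(f"error rate must lie in [0, 1], got {err}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return math.sqrt(err * (1.0 - err) / n_samples)


def train_rf(
    fm: FeatureMatrix,
    labels,
    ntree: int = 1000,
    mtry=None,
    seed: int = 0,
    expected_classes=None,
) -> RFFit:
    """Fit a Random Forest and summarize its OOB performance.

    ``labels`` is a sequence/Series of class labels aligned with the
    samples of ``fm`` (a Series is aligned by index). With
    ``expected_classes`` given, an error is raised if any expected class is
    absent from the training labels. The matrix must be complete.
    """
    if not fm.is_complete():
        raise ValueError("training matrix contains missing cells; impute first")
    if isinstance(labels, pd.Series):
        labels = labels.loc[fm.sample_ids]
    y = np.asarray(labels)
    if len(y) != fm.n_samples:
        raise ValueError("labels and matrix disagree in length")
    present = set(np.unique(y))
    if expected_classes is not None:
        absent = [c for c in expected_classes if c not in present]
        if absent:
            raise ValueError(f"class(es) absent from training labels: {absent}")
    if len(present) < 2:
        raise ValueError("training requires at least two classes")

    p = fm.n_features
    mtry_val = _resolve_mtry(mtry, p)
    model = RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry_val,
        bootstrap=True,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    X = fm.values.to_numpy(float)
    model.fit(X, y)

    votes = model.oob_decision_function_
    voted = votes.sum(axis=1) > 0
    pred = model.classes_[np.argmax(votes, axis=1)]
    wrong = pred != y
    oob_error = float(wrong[voted].mean())
    per_class = {}
    for c in model.classes_:
        mask = (y == c) & voted
        per_class[str(c)] = float(wrong[mask].mean()) if mask.any() else float("nan")
    importance = pd.Series(model.feature_importances_, index=fm.feature_ids)
    return RFFit(
        feature_ids=list(fm.feature_ids),
        classes=[str(c) for c in model.classes_],
        oob_error=oob_error,
        per_class_oob=per_class,
        importance=importance,
        ntree=ntree,
        mtry=mtry_val,
        seed=int(seed),
        model=model,
    )


def apply_one_se_rule(trace: SelectionTrace | list) -> int:
    """Index of the smallest model within one SE of the minimum OOB error.

    Let e* be the minimum OOB error over all steps and s* the standard
    error recorded at the first step attaining e*. The chosen step is the
    one with the fewest features among those with error <= e* + s*; ties on
    feature count go to the earlier step.
    """
    steps = trace.steps if isinstance(trace, SelectionTrace) else list(trace)
    if not steps:
        raise ValueError("empty selection trace")
    errors = [s.oob_error for s in steps]
    i_min = int(np.argmin(errors))  # first occurrence of the minimum
    threshold = errors[i_min] + steps[i_min].oob_se
    best = None
    for i, s in enumerate(steps):
        if s.oob_error <= threshold:
            if best is None or s.n_features < steps[best].n_features:
                best = i
    return best


def backward_eliminate(
    fm: FeatureMatrix,
    labels,
    drop_fraction: float = 0.2,
    min_features: int = 2,
    ntree: int = 1000,
    mtry=None,
    seed: int = 0,
    recompute_importance: bool = False,
) -> SelectionTrace:
    """Iterative backward elimination of least-important features.

    Step 0 fits the full model. Each later step removes
    ``max(1, floor(drop_fraction * current count))`` features with the
    smallest Gini importance (ties broken by feature id for determinism),
    refits, and records the feature set, OOB error and its binomial
    standard error, until ``min_features`` is reached. By default the
    elimination order comes from the full model's importance ranking;
    ``recompute_importance=True`` re-ranks after every refit. The returned
    trace's ``chosen_step`` applies the 1-SE rule.
    """
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in (0, 1)")
    if min_features < 1:
        raise ValueError("min_features must be >= 1")

    def rank(imp: pd.Series) -> list:
        # least important first; stable tie-break on feature id
        order = sorted(imp.index, key=lambda f: (imp[f], str(f)))
        return order

    current = list(fm.feature_ids)
    fit = train_rf(fm, labels, ntree=ntree, mtry=mtry, seed=seed)
    order = rank(fit.importance)
    steps = [
        SelectionStep(
            n_features=len(current),
            feature_ids=list(current),
            oob_error=fit.oob_error,
            oob_se=oob_se(fit.oob_error, fm.n_samples),
        )
    ]
    while len(current) > min_features:
        n_drop = max(1, math.floor(drop_fraction * len(current)))
        n_keep = max(min_features, len(current) - n_drop)
        drop = [f for f in order if f in set(current)][: len(current) - n_keep]
        current = [f for f in current if f not in set(drop)]
        sub = fm.subset(features=current)
        fit = train_rf(sub, labels, ntree=ntree, mtry=mtry, seed=seed)
        if recompute_importance:
            order = rank(fit.importance)
        steps.append(
            SelectionStep(
                n_features=len(current),
                feature_ids=list(current),
                oob_error=fit.oob_error,
                oob_se=oob_se(fit.oob_error, fm.n_samples),
            )
        )
    trace = SelectionTrace(steps=steps, chosen_step=0, n_samples=fm.n_samples)
    trace.chosen_step = apply_one_se_rule(trace)
    return trace


def predict(fit: RFFit, fm: FeatureMatrix) -> pd.Series:
    """Majority-vote class predictions for new samples.

    The matrix must contain every feature of the fit (any column order);
    extra columns are ignored. Deterministic given the fitted ensemble.
    """
    missing = [f for f in fit.feature_ids if f not in fm.feature_ids]
    if missing:
        raise ValueError(f"matrix lacks feature(s) required by the model: {missing}")
    X = fm.values.loc[:, fit.feature_ids]
    if X.isna().to_numpy().any():
        raise ValueError("prediction matrix contains missing cells; impute first")
    pred = fit.model.predict(X.to_numpy(float))
    return pd.Series(pred, index=fm.sample_ids, name="predicted_class")


def plot_selection_trace(trace: SelectionTrace, ax=None):
    """OOB error (+/- one SE) versus panel size; marks the chosen panel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = trace.to_frame()
    ax.errorbar(df["n_features"], df["oob_error"], yerr=df["oob_se"], fmt="o-", capsize=3)
    chosen = df[df["chosen"]]
    ax.plot(chosen["n_features"], chosen["oob_error"], "D", color="red", markersize=9)
    ax.set_xlabel("number of predictors")
    ax.set_ylabel("OOB error rate")
    ax.invert_xaxis()
    return ax
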