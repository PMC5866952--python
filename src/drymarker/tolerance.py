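"""Drought-tolerance quantification from starch-yield trials.

Tolerance of a cultivar is defined as yield *stability* under water
limitation, not absolute yield. For each cultivar c and trial t the
relative starch yield is

    rel(c, t) = mean drought yield of c in t / mean control yield of c in t

and the tolerance index DRYM (Deviation of Relative starch Yield from the
experimental Median) is

    DRYM(c, t) = rel(c, t) - median over cultivars of rel(., t).

Subtracting the per-trial median removes trial-level severity so that DRYM
values are comparable across years and sites: positive values mark
tolerant cultivars, negative ones sensitive cultivars, and the per-trial
median is zero by construction. Trial-level drought severity itself is
summarized by the stress index

    SI(t) = 1 - mean drought yield over all cultivars / mean control yield,

which is 0 for an ineffective treatment and 1 for total yield loss.

Cultivars are ranked by their mean DRYM across trials and split into
tertile classes (low / intermediate / high tolerance), which serve as the
class labels for the downstream Random-Forest models.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .containers import validate_yield_table

TOLERANCE_CLASSES = ("low", "intermediate", "high")


@dataclasses.dataclass
class StressIndex:
    """Trial-level drought severity: 1 - mean drought / mean control yield."""

    trial_id: str
    si: float


@dataclasses.dataclass
class ToleranceScore:
    """Per-cultivar tolerance summary across trials."""

    cultivar_id: str
    drym_by_trial: dict
    mean_drym: float
    se_drym: float  # NaN when only one trial
    tolerance_class: str | None = None


def _cell_means(yields: pd.DataFrame) -> pd.DataFrame:
    """Mean starch yield per (cultivar, trial, treatment) cell."""
    return (
        yields.groupby(["cultivar", "trial", "treatment"], sort=True)["starch_yield"]
        .mean()
        .rename("mean_yield")
        .reset_index()
    )


def relative_starch_yield(yields: pd.DataFrame) -> pd.DataFrame:
    """Per-(cultivar, trial) ratio of drought to control mean starch yield.

    Replicates are averaged within each (cultivar, trial, treatment) cell
    first. Cells whose control mean is zero or whose drought arm is absent
    are excluded with a warning.

    Returns a DataFrame with columns ``cultivar``, ``trial``, ``rel_yield``.
    """
    validate_yield_table(yields)
    cells = _cell_means(yields)
    wide = cells.pivot_table(
        index=["cultivar", "trial"], columns="treatment", values="mean_yield"
    )
    for arm in ("control", "drought"):
        if arm not in wide.columns:
            wide[arm] = np.nan
    bad = wide["control"].isna() | (wide["control"] <= 0) | wide["drought"].isna()
    if bad.any():
        flagged = wide.index[bad].tolist()
        warnings.warn(
            f"excluding {int(bad.sum())} cultivar-trial cell(s) with zero/absent "
            f"control or absent drought yield: {flagged[:5]}",
            stacklevel=2,
        )
    out = wide.loc[~bad]
    rel = (out["drought"] / out["control"]).rename("rel_yield").reset_index()
    return rel


def stress_index(yields: pd.DataFrame, trial: str) -> StressIndex:
    """Drought severity of one trial over all cultivars.

    SI = 1 - (mean drought starch yield) / (mean control starch yield),
    where the means run over all cultivar replicates of the trial.
    """
    sub = yields[yields["trial"] == trial]
    if sub.empty:
        raise ValueError(f"trial {trial!r} not present in yield table")
    arm_means = sub.groupby("treatment")["starch_yield"].mean()
    for arm in ("control", "drought"):
        if arm not in arm_means.index:
            raise ValueError(f"trial {trial!r} is missing its {arm} arm")
    if arm_means["control"] <= 0:
        raise ValueError(f"trial {trial!r} has non-positive mean control yield")
    return StressIndex(trial_id=trial, si=float(1.0 - arm_means["drought"] / arm_means["control"]))


def drym(rel: pd.DataFrame) -> pd.DataFrame:
    """DRYM per (cultivar, trial): relative yield minus the trial median.

    Requires at least two cultivars per trial (a single-cultivar trial has a
    degenerate median and identically-zero DRYM).

    Returns a DataFrame with columns ``cultivar``, ``trial``, ``drym``.
    """
    counts = rel.groupby("trial")["cultivar"].nunique()
    degenerate = counts.index[counts < 2].tolist()
    if degenerate:
        raise ValueError(f"trial(s) with fewer than two cultivars: {degenerate}")
    med = rel.groupby("trial")["rel_yield"].transform("median")
    out = rel[["cultivar", "trial"]].copy()
    out["drym"] = rel["rel_yield"] - med
    return out


def aggregate_drym(drym_table: pd.DataFrame) -> list[ToleranceScore]:
    """Average per-trial DRYM into one score per cultivar.

    The mean is unweighted over trials; the standard error is the sample
    standard deviation across trials divided by sqrt(#trials), reported as
    NaN for cultivars observed in a single trial.
    """
    scores = []
    for cultivar, sub in drym_table.groupby("cultivar", sort=True):
        vals = sub.set_index("trial")["drym"]
        n = len(vals)
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        scores.append(
            ToleranceScore(
                cultivar_id=cultivar,
                drym_by_trial=vals.to_dict(),
                mean_drym=float(vals.mean()),
                se_drym=se,
            )
        )
    return scores


def classify_tolerance(scores: list[ToleranceScore], n_classes: int = 3) -> list[ToleranceScore]:
    """Assign tertile tolerance classes by mean DRYM.

    Cultivars are split at the empirical 1/3 and 2/3 quantiles of their mean
    DRYM values into low / intermediate / high tolerance. A value exactly on
    a boundary goes to the lower class, so tied values always share a class
    and the assignment is independent of input order and strictly monotone
    in mean DRYM.

    Returns new :class:`ToleranceScore` objects with ``tolerance_class`` set.
    """
    if n_classes != 3:
        raise NotImplementedError("tolerance classes are defined as tertiles (n_classes=3)")
    if len(scores) < n_classes:
        raise ValueError(f"need at least {n_classes} cultivars, got {len(scores)}")
    values = np.array([s.mean_drym for s in scores], dtype=float)
    if not np.isfinite(values).all():
        bad = [s.cultivar_id for s, v in zip(scores, values) if not np.isfinite(v)]
        raise ValueError(f"non-finite mean DRYM for cultivar(s): {bad}")
    if np.ptp(values) == 0:
        raise ValueError("degenerate tolerance distribution: all mean DRYM values identical")
    q_low, q_high = np.quantile(values, [1 / 3, 2 / 3])
    out = []
    for s, v in zip(scores, values):
        if v <= q_low:
            cls = "low"
        elif v <= q_high:
            cls = "intermediate"
        else:
            cls = "high"
        out.append(dataclasses.replace(s, tolerance_class=cls))
    return out


def score_yield_table(yields: pd.DataFrame) -> tuple[list[ToleranceScore], list[StressIndex]]:
    """Full tolerance workflow: yields -> classified scores + per-trial SI."""
    rel = relative_starch_yield(yields)
    scores = classify_tolerance(aggregate_drym(drym(rel)))
    sis = [stress_index(yields, t) for t in sorted(yields["trial"].unique())]
    return scores, sis


def scores_to_frame(scores: list[ToleranceScore]) -> pd.DataFrame:
    """Tabulate tolerance scores (cultivar, mean_drym, se_drym, class)."""
    return pd.DataFrame(
        {
            "cultivar": [s.cultivar_id for s in scores],
            "mean_drym": [s.mean_drym for s in scores],
            "se_drym": [s.se_drym for s in scores],
            "tolerance_class": [s.tolerance_class for s in scores],
        }
    ).set_index("cultivar")
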