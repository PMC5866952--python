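"""Screening of reference genes and transcript marker candidates.

Two screens precede qRT-PCR marker measurement:

* Reference genes for Ct normalization must be expressed in an easily
  measurable window and be stable across cultivars, cultivation types and
  treatments. Candidates are taken from an RNA-Seq expression matrix
  (genes whose mean FPKM falls in a fixed window, ranked by variance of
  log2 FPKM) and then re-ranked on measured Ct values by coefficient of
  variation, flagging genes whose Ct shows a significant effect of
  cultivation type, cultivar or treatment in an additive ANOVA.

* Transcript marker candidates are genes constitutively higher expressed
  in tolerant than in sensitive cultivars under control conditions — in
  field and glasshouse material alike — and abundant enough to quantify
  (median CPM across tolerant-cultivar samples above a threshold).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .containers import ExpressionMatrix

__all__ = [
    "select_reference_candidates",
    "rank_references_by_cv",
    "filter_marker_candidates",
]


def select_reference_candidates(
    expr: ExpressionMatrix, window: tuple[float, float] = (5.0, 45.0), k: int = 15
) -> pd.DataFrame:
    """Pick the ``k`` most stable genes inside an absolute FPKM window.

    Genes whose mean FPKM over all samples lies in ``window`` (inclusive)
    are ranked ascending by the variance of their log2 FPKM values; the top
    ``k`` are returned as a DataFrame (gene, mean_fpkm, log2_variance). If
    fewer than ``k`` genes fall in the window, all of them are returned
    with a warning. The window is an absolute expression range, so the
    selection is deliberately not scale-invariant.
    """
    if expr.unit != "FPKM":
        raise ValueError(f"reference-gene screening expects FPKM, got {expr.unit}")
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = expr.values
    mean_fpkm = vals.mean(axis=1)
    in_window = (mean_fpkm >= window[0]) & (mean_fpkm <= window[1])
    sub = vals.loc[in_window]
    if sub.empty:
        raise ValueError(f"no gene has mean FPKM inside {window}")
    with np.errstate(divide="ignore"):
        log2v = np.log2(sub.where(sub > 0))
    variance = log2v.var(axis=1, ddof=1)
    out = pd.DataFrame(
        {"mean_fpkm": mean_fpkm.loc[in_window], "log2_variance": variance}
    ).sort_values(["log2_variance", "mean_fpkm"], kind="mergesort")
    out.index.name = "gene"
    if len(out) < k:
        warnings.warn(
            f"only {len(out)} gene(s) inside the FPKM window {window}; "
            f"returning all of them (k={k} requested)",
            stacklevel=2,
        )
        return out
    return out.head(k)


def rank_references_by_cv(
    qpcr: pd.DataFrame, candidates, alpha: float = 0.05
) -> pd.DataFrame:
    """Rank candidate reference genes by Ct coefficient of variation.

    For each candidate, CV = sd(Ct) / mean(Ct) over all samples (raw Ct
    scale) and an additive ANOVA of Ct on cultivation type, cultivar and
    treatment is fit; a gene is flagged unstable if any factor is
    significant at ``alpha``. The qPCR table must carry ``cultivation``,
    ``cultivar`` and ``treatment`` columns alongside (sample, gene, ct).

    Returns a DataFrame indexed by gene, sorted ascending by CV, with
    columns cv, p_cultivation, p_cultivar, p_treatment, stable.
    """
    factors = ["cultivation", "cultivar", "treatment"]
    rows = {}
    for gene in candidates:
        sub = qpcr[qpcr["gene"] == gene].dropna(subset=["ct"])
        if sub.empty:
            raise ValueError(f"candidate gene {gene!r} has no Ct measurements")
        ct = sub["ct"].to_numpy(float)
        cv = float(np.std(ct, ddof=1) / np.mean(ct))
        pvals = {}
        usable = [f for f in factors if f in sub.columns and sub[f].nunique() > 1]
        if usable:
            formula = "ct ~ " + " + ".join(f"C({f})" for f in usable)
            fit = smf.ols(formula, data=sub).fit()
            table = sm.stats.anova_lm(fit, typ=2)
            for f in usable:
                pvals[f] = float(table.loc[f"C({f})", "PR(>F)"])
        for f in factors:
            pvals.setdefault(f, np.nan)
        stable = all(not (p < alpha) for p in pvals.values() if np.isfinite(p))
        rows[gene] = {
            "cv": cv,
            "p_cultivation": pvals["cultivation"],
            "p_cultivar": pvals["cultivar"],
            "p_treatment": pvals["treatment"],
            "stable": stable,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").sort_values("cv", kind="mergesort")
    out.index.name = "gene"
    return out


def filter_marker_candidates(
    expr: ExpressionMatrix, min_median_cpm: float = 5.0
) -> list:
    """Filter marker-candidate genes by direction and abundance.

    A gene passes when (i) its mean expression in control-condition samples
    is strictly higher in tolerant than in sensitive cultivars, separately
    within field and within glasshouse material, and (ii) its median CPM
    across all samples of tolerant cultivars is strictly above
    ``min_median_cpm``. If one cultivation type has no usable control
    samples, the direction criterion is evaluated on the available type
    with a warning.
    """
    if expr.unit != "CPM":
        raise ValueError(f"marker-candidate filtering expects CPM, got {expr.unit}")
    meta = expr.sample_meta
    for col in ("tolerance_group", "treatment", "cultivation"):
        if col not in meta.columns:
            raise KeyError(f"sample metadata lacks required column {col!r}")
    vals = expr.values
    control = meta["treatment"] == "control"
    tolerant = meta["tolerance_group"] == "tolerant"
    sensitive = meta["tolerance_group"] == "sensitive"

    direction_ok = pd.Series(True, index=vals.index)
    evaluated = 0
    for cultivation in ("field", "glasshouse"):
        env = meta["cultivation"] == cultivation
        tol_cols = meta.index[control & tolerant & env]
        sen_cols = meta.index[control & sensitive & env]
        if len(tol_cols) == 0 or len(sen_cols) == 0:
            warnings.warn(
                f"no usable control samples for cultivation type {cultivation!r}; "
                "direction criterion evaluated on the remaining type only",
                stacklevel=2,
            )
            continue
        evaluated += 1
        direction_ok &= vals[tol_cols].mean(axis=1) > vals[sen_cols].mean(axis=1)
    if evaluated == 0:
        raise ValueError("no cultivation type has both tolerant and sensitive control samples")

    tol_samples = meta.index[tolerant]
    abundance_ok = vals[tol_samples].median(axis=1) > min_median_cpm
    keep = direction_ok & abundance_ok
    return vals.index[keep].tolist()
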