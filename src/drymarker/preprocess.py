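"""Feature-table preprocessing: log transform, nuisance removal, imputation.

GC-MS metabolite profiles measured over several campaigns carry strong
technical structure: additive batch offsets, a run-order (sequence) drift
and sample-to-sample differences in overall signal response. The pipeline
removes these with a per-feature additive linear model — fit genotype
together with the nuisance terms, then subtract only the fitted nuisance
part — so that biological (genotype) differences survive while batch,
run-order and response effects are projected out.

Missing cells (undetected analytes, failed reactions) are completed by
NIPALS PCA, which estimates scores and loadings on the present cells only
and fills missing cells from the low-rank reconstruction. qRT-PCR Ct
values are converted to relative expression against the mean of a set of
validated reference genes (2^-dCt, then log10).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

__all__ = [
    "log_transform",
    "anova_correct",
    "nipals_impute",
    "pca_scores",
    "qpcr_normalize",
]


def log_transform(fm: FeatureMatrix, base: float = 10.0) -> FeatureMatrix:
    """Elementwise logarithm of all present cells; missing cells stay missing.

    Raises if any present value is non-positive, naming the offending cell.
    """
    vals = fm.values
    bad = (vals <= 0) & vals.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-positive value {vals.iat[i, j]!r} at sample "
            f"{vals.index[i]!r}, feature {vals.columns[j]!r}; log undefined"
        )
    out = np.log(vals) / np.log(base)
    return fm.with_values(out)


# ---------------------------------------------------------------------------
# ANOVA-based nuisance correction
# ---------------------------------------------------------------------------

RESPONSE_COLUMN = "response"


def _sum_coded(series: pd.Series, name: str) -> pd.DataFrame:
    """Sum-to-zero (deviation) coding of a categorical column.

    Levels sorted lexically; the first level is the reference whose indicator
    rows carry -1. Returns an empty frame for a single-level factor.
    """
    levels = sorted(pd.unique(series.astype(str)))
    if len(levels) < 2:
        return pd.DataFrame(index=series.index)
    cols = {}
    ref = levels[0]
    s = series.astype(str)
    for lev in levels[1:]:
        col = np.where(s == lev, 1.0, 0.0)
        col = np.where(s == ref, -1.0, col)
        cols[f"{name}[{lev}]"] = col
    return pd.DataFrame(cols, index=series.index)


def _design_block(meta: pd.DataFrame, factors, center: bool) -> pd.DataFrame:
    """Design columns for a list of factors: sum coding for categoricals,
    centered numeric columns for continuous covariates."""
    blocks = []
    for f in factors:
        col = meta[f]
        if pd.api.types.is_numeric_dtype(col):
            x = col.astype(float)
            if center:
                x = x - x.mean()
            if np.ptp(x.to_numpy()) > 0:
                blocks.append(x.rename(f).to_frame())
        else:
            blocks.append(_sum_coded(col, f))
    if not blocks:
        return pd.DataFrame(index=meta.index)
    return pd.concat(blocks, axis=1)


def _warn_if_confounded(meta: pd.DataFrame, nuisance, keep) -> None:
    for nf in nuisance:
        if nf not in meta.columns or pd.api.types.is_numeric_dtype(meta[nf]):
            continue
        for kf in keep:
            nest = meta.groupby(nf, sort=False)[kf].nunique()
            if (nest == 1).any() and meta[nf].nunique() > 1:
                warnings.warn(
                    f"nuisance factor {nf!r} has level(s) nested within a single "
                    f"{kf!r} level; their effects are not separable and the fit "
                    "attributes shared variation to the kept factor",
                    stacklevel=3,
                )


def anova_correct(
    fm: FeatureMatrix,
    nuisance: tuple[str, ...] = ("batch", "sequence", RESPONSE_COLUMN),
    keep: tuple[str, ...] = ("cultivar",),
) -> FeatureMatrix:
    """Remove additive nuisance effects from every feature by linear modelling.

    For each feature an ordinary-least-squares model with the kept factors
    (sum-to-zero coded) and the nuisance terms is fit on that feature's
    present cells, and the fitted nuisance contribution (mean-centred over
    the fitted samples) is subtracted. The returned matrix therefore keeps
    grand mean, kept-factor effects and residual; refitting the same model
    on the corrected data yields nuisance coefficients of zero, which also
    makes the correction idempotent.

    The special nuisance term ``"response"`` is each sample's mean intensity
    over all features. It is computed from the input matrix on first use and
    stored in the returned metadata, so repeated corrections reuse the
    original covariate rather than recomputing it from corrected values.

    Categorical nuisance factors with a single level and constant continuous
    covariates drop out (output equals input in the all-constant case).
    """
    meta = fm.meta.copy()
    if RESPONSE_COLUMN in nuisance and RESPONSE_COLUMN not in meta.columns:
        meta[RESPONSE_COLUMN] = fm.values.mean(axis=1, skipna=True)
    for f in list(nuisance) + list(keep):
        if f not in meta.columns:
            raise KeyError(f"metadata has no column {f!r} required by the correction model")
    _warn_if_confounded(meta, nuisance, keep)

    keep_block = _design_block(meta, keep, center=False)
    nuis_block = _design_block(meta, nuisance, center=True)
    intercept = pd.DataFrame({"Intercept": np.ones(fm.n_samples)}, index=fm.sample_ids)
    design = pd.concat([intercept, keep_block, nuis_block], axis=1)
    X = design.to_numpy(float)
    n_nuis = nuis_block.shape[1]
    if n_nuis == 0:
        return FeatureMatrix(fm.values.copy(), meta)

    V = fm.values.to_numpy(float)
    corrected = V.copy()
    Xn = nuis_block.to_numpy(float)
    present_all = ~np.isnan(V)
    for j in range(V.shape[1]):
        present = present_all[:, j]
        if present.sum() <= X.shape[1]:
            warnings.warn(
                f"feature {fm.feature_ids[j]!r}: too few present cells to fit the "
                "correction model; left uncorrected",
                stacklevel=2,
            )
            continue
        beta, *_ = np.linalg.lstsq(X[present], V[present, j], rcond=None)
        nuis_effect = Xn[present] @ beta[-n_nuis:]
        corrected[present, j] = V[present, j] - (nuis_effect - nuis_effect.mean())
    out = pd.DataFrame(corrected, index=fm.sample_ids, columns=fm.feature_ids)
    return FeatureMatrix(out, meta)


def refit_nuisance_coefficients(
    fm: FeatureMatrix,
    nuisance: tuple[str, ...] = ("batch", "sequence", RESPONSE_COLUMN),
    keep: tuple[str, ...] = ("cultivar",),
) -> pd.DataFrame:
    """Nuisance-term coefficients of the correction model refit per feature.

    Diagnostic companion to :func:`anova_correct`: on corrected data all
    coefficients are ~0. Rows are features, columns nuisance design terms.
    """
    meta = fm.meta.copy()
    if RESPONSE_COLUMN in nuisance and RESPONSE_COLUMN not in meta.columns:
        meta[RESPONSE_COLUMN] = fm.values.mean(axis=1, skipna=True)
    keep_block = _design_block(meta, keep, center=False)
    nuis_block = _design_block(meta, nuisance, center=True)
    intercept = pd.DataFrame({"Intercept": np.ones(fm.n_samples)}, index=fm.sample_ids)
    design = pd.concat([intercept, keep_block, nuis_block], axis=1)
    X = design.to_numpy(float)
    n_nuis = nuis_block.shape[1]
    V = fm.values.to_numpy(float)
    rows = []
    for j in range(V.shape[1]):
        present = ~np.isnan(V[:, j])
        beta, *_ = np.linalg.lstsq(X[present], V[present, j], rcond=None)
        rows.append(beta[-n_nuis:])
    return pd.DataFrame(rows, index=fm.feature_ids, columns=nuis_block.columns)


# ---------------------------------------------------------------------------
# NIPALS imputation and PCA
# ---------------------------------------------------------------------------


def _nipals_components(
    X: np.ndarray,
    present: np.ndarray,
    n_components: int,
    max_iter: int,
    tol: float,
    warn: bool = True,
):
    """Sequential NIPALS on a column-centred matrix with missing cells.

    All inner products run over present cells only. Returns (scores T,
    loadings P) with unit-norm loadings; X is deflated in place on present
    cells.
    """
    n, p = X.shape
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Xw = np.where(present, X, 0.0)
    for a in range(n_components):
        # deterministic start: column with the largest present-cell variance
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_var = np.nanvar(np.where(present, Xw, np.nan), axis=0)
        start = int(np.nanargmax(col_var))
        t = Xw[:, start].copy()
        if not np.any(t):
            t = np.ones(n)
        converged = False
        for _ in range(max_iter):
            # loadings: p_j = sum_i t_i x_ij / sum_i t_i^2 over present cells
            tw = np.where(present, t[:, None], 0.0)
            denom_p = (tw**2).sum(axis=0)
            denom_p[denom_p == 0] = np.finfo(float).eps
            pvec = (tw * Xw).sum(axis=0) / denom_p
            norm = np.linalg.norm(pvec)
            if norm == 0:
                break
            pvec /= norm
            # scores: t_i = sum_j x_ij p_j / sum_j p_j^2 over present cells
            pw = np.where(present, pvec[None, :], 0.0)
            denom_t = (pw**2).sum(axis=1)
            denom_t[denom_t == 0] = np.finfo(float).eps
            t_new = (Xw * pw).sum(axis=1) / denom_t
            delta = np.linalg.norm(t_new - t)
            t = t_new
            if delta <= tol * max(np.linalg.norm(t), 1.0):
                converged = True
                break
        if not converged and warn:
            warnings.warn(
                f"NIPALS component {a + 1} did not converge in {max_iter} iterations "
                f"(last score change {delta:.3e})",
                stacklevel=3,
            )
        T[:, a] = t
        P[:, a] = pvec
        Xw = Xw - np.where(present, np.outer(t, pvec), 0.0)
    return T, P


def nipals_impute(
    fm: FeatureMatrix,
    n_components: int = 5,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int | None = None,
    max_feature_missing: float = 0.4,
    refine_tol: float = 1e-6,
    max_refine: int = 30,
) -> FeatureMatrix:
    """Complete a feature matrix by NIPALS PCA reconstruction.

    Components are estimated on present cells only; missing cells are
    replaced by the rank-``n_components`` reconstruction (column mean plus
    scores x loadings), with the column means and imputed cells refined
    jointly until they change by less than ``refine_tol`` (relative) or
    ``max_refine`` passes. Present cells are returned unchanged. Features
    missing more than ``max_feature_missing`` of their cells are dropped
    before imputation with a warning.

    ``seed`` is accepted for interface symmetry with the other stochastic
    stages; the algorithm itself is deterministic (variance-ordered start
    columns).
    """
    del seed  # deterministic algorithm
    vals = fm.values
    frac = vals.isna().mean(axis=0)
    drop = frac.index[frac > max_feature_missing]
    if len(drop):
        warnings.warn(
            f"dropping {len(drop)} feature(s) with >{max_feature_missing:.0%} "
            f"missing cells before imputation: {list(drop[:5])}",
            stacklevel=2,
        )
        vals = vals.drop(columns=drop)
    X = vals.to_numpy(float)
    present = ~np.isnan(X)
    if not present.any(axis=0).all():
        empty = vals.columns[~present.any(axis=0)].tolist()
        raise ValueError(f"feature(s) with no present values: {empty}")
    if not present.any(axis=1).all():
        empty = vals.index[~present.any(axis=1)].tolist()
        raise ValueError(f"sample(s) with no present values: {empty}")
    if present.all():
        return FeatureMatrix(vals.copy(), fm.meta.copy())
    k = min(n_components, min(X.shape) - 1)
    if k < n_components:
        warnings.warn(
            f"n_components reduced from {n_components} to {k} for a "
            f"{X.shape[0]}x{X.shape[1]} matrix",
            stacklevel=2,
        )
    # Outer refinement: the column means used for centring depend on the
    # missing-cell estimates, so alternate present-cell NIPALS with an
    # update of the imputed cells until they stabilize. On data that are
    # exactly low rank this converges to the exact completion; on noisy
    # data it settles within a few passes.
    mu = np.array([X[present[:, j], j].mean() for j in range(X.shape[1])])
    out = np.where(present, X, mu)
    prev_delta = np.inf
    for it in range(max_refine):
        mu = out.mean(axis=0)
        last = it == max_refine - 1
        T, P = _nipals_components(
            X - mu,
            present,
            k,
            max_iter=max_iter if last else min(max_iter, 100),
            tol=tol,
            warn=last,
        )
        recon = mu + T @ P.T
        new = np.where(present, X, recon)
        delta = np.abs(new - out)[~present].max()
        out = new
        if delta <= max(refine_tol, tol) * max(1.0, np.abs(out[~present]).max()):
            break
        if delta > 0.95 * prev_delta:
            break  # refinement stalled (noise floor reached)
        prev_delta = delta
    return FeatureMatrix(
        pd.DataFrame(out, index=vals.index, columns=vals.columns), fm.meta.copy()
    )


def nipals_scores(
    fm: FeatureMatrix, n_components: int = 2, max_iter: int = 500, tol: float = 1e-9
) -> pd.DataFrame:
    """NIPALS scores of a (possibly incomplete) matrix, for cross-checks."""
    X = fm.values.to_numpy(float)
    present = ~np.isnan(X)
    mu = np.array([X[present[:, j], j].mean() for j in range(X.shape[1])])
    T, _ = _nipals_components(X - mu, present, n_components, max_iter, tol)
    cols = [f"PC{i + 1}" for i in range(T.shape[1])]
    return pd.DataFrame(T, index=fm.sample_ids, columns=cols)


def pca_scores(fm: FeatureMatrix, n_components: int = 2):
    """Centred PCA of a complete matrix for quality control.

    Returns ``(scores, explained)``: a samples x components score frame and
    the explained-variance fractions (non-increasing, summing to <= 1).
    """
    from sklearn.decomposition import PCA

    if not fm.is_complete():
        raise ValueError("pca_scores requires a complete matrix; impute first")
    n_components = min(n_components, min(fm.values.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(fm.values.to_numpy(float))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=fm.sample_ids, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# qRT-PCR normalization
# ---------------------------------------------------------------------------


def qpcr_normalize(
    qpcr: pd.DataFrame,
    reference_gene_ids,
    sample_meta: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Reference-gene normalization of qPCR Ct values.

    For every sample, dCt(gene) = Ct(gene) - mean Ct over the reference
    genes of that sample; relative expression is 2^-dCt, returned on the
    log10 scale used for modelling. Samples missing any reference-gene Ct
    are excluded with a warning; target genes with missing Ct stay missing.
    Reference genes themselves are not part of the output matrix.

    Because the reference mean is subtracted per sample, adding a constant
    to every Ct of a sample (targets and references alike) leaves the
    expressions unchanged.
    """
    reference_gene_ids = list(reference_gene_ids)
    # groupby/unstack keeps genes whose Ct is missing everywhere (pivot_table
    # would silently drop the all-NaN column); replicate wells are averaged
    wide = qpcr.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    missing_ref = [g for g in reference_gene_ids if g not in wide.columns]
    if missing_ref:
        raise ValueError(f"reference gene(s) absent from the table: {missing_ref}")
    ref = wide[reference_gene_ids]
    ok = ref.notna().all(axis=1)
    if (~ok).any():
        warnings.warn(
            f"excluding {int((~ok).sum())} sample(s) with missing reference Ct: "
            f"{wide.index[~ok][:5].tolist()}",
            stacklevel=2,
        )
    wide = wide.loc[ok]
    ref_mean = wide[reference_gene_ids].mean(axis=1)
    targets = [g for g in wide.columns if g not in reference_gene_ids]
    delta_ct = wide[targets].sub(ref_mean, axis=0)
    log10_expr = -delta_ct * np.log10(2.0)  # log10(2^-dCt)
    if sample_meta is not None:
        meta = sample_meta.loc[log10_expr.index].copy()
    else:
        meta = pd.DataFrame(index=log10_expr.index)
    return FeatureMatrix(log10_expr, meta)
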