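"""Preprocessing: log transform, nuisance correction, NIPALS, qPCR normalization."""

import numpy as np
import pandas as pd
import pytest

from drymarker import preprocess as pp
from drymarker.containers import FeatureMatrix

from conftest import feature_matrix


class TestLogTransform:
    def test_powers_and_identity(self):
        fm = feature_matrix([[1000.0, 1.0], [10.0, np.nan]])
        out = pp.log_transform(fm, base=10)
        assert out.values.iloc[0, 0] == pytest.approx(3.0)
        assert out.values.iloc[0, 1] == pytest.approx(0.0)
        assert np.isnan(out.values.iloc[1, 1])

    def test_nonpositive_value_named(self):
        fm = feature_matrix([[1.0, 0.0]])
        with pytest.raises(ValueError, match="f1"):
            pp.log_transform(fm)


def balanced_two_batch(seed=0, n_per=10, offset=1.0):
    """Balanced genotype x batch design with a planted batch-B offset."""
    rng = np.random.default_rng(seed)
    n = 4 * n_per
    meta = {
        "cultivar": (["A"] * n_per + ["B"] * n_per) * 2,
        "batch": ["b1"] * (2 * n_per) + ["b2"] * (2 * n_per),
        "sequence": [1] * n,
    }
    base = rng.normal(5, 1, size=(n, 3))
    base[np.asarray(meta["cultivar"]) == "B"] += 0.5  # genotype effect to keep
    clean = feature_matrix(base.copy(), meta)
    base[np.asarray(meta["batch"]) == "b2"] += offset
    return feature_matrix(base, meta), clean


class TestAnovaCorrect:
    def test_removes_planted_batch_offset_keeps_genotype(self):
        # pure two-group centering: batch is the only varying nuisance term
        fm, clean = balanced_two_batch()
        out = pp.anova_correct(fm, nuisance=("batch", "sequence"))
        b1 = out.values[np.asarray(out.meta["batch"]) == "b1"].mean()
        b2 = out.values[np.asarray(out.meta["batch"]) == "b2"].mean()
        assert np.allclose(b1, b2, atol=1e-10)
        # pairwise genotype mean differences unchanged
        for mat in (fm, out):
            diffs = (
                mat.values[np.asarray(mat.meta["cultivar"]) == "A"].mean()
                - mat.values[np.asarray(mat.meta["cultivar"]) == "B"].mean()
            )
            assert np.allclose(
                diffs,
                fm.values[np.asarray(fm.meta["cultivar"]) == "A"].mean()
                - fm.values[np.asarray(fm.meta["cultivar"]) == "B"].mean(),
                atol=1e-10,
            )

    def test_no_nuisance_variation_is_identity(self):
        rng = np.random.default_rng(1)
        fm = feature_matrix(
            rng.normal(size=(8, 2)),
            {"cultivar": list("ABABABAB"), "batch": ["b"] * 8, "sequence": [3] * 8},
        )
        out = pp.anova_correct(fm, nuisance=("batch", "sequence"))
        assert np.allclose(out.values.to_numpy(), fm.values.to_numpy())

    def test_refit_coefficients_vanish_and_idempotent(self):
        fm, _ = balanced_two_batch(seed=2)
        out = pp.anova_correct(fm)
        coef = pp.refit_nuisance_coefficients(out)
        assert np.abs(coef.to_numpy()).max() < 1e-8
        twice = pp.anova_correct(out)
        assert np.allclose(twice.values.to_numpy(), out.values.to_numpy(), atol=1e-8)

    def test_grand_mean_preserved(self):
        fm, _ = balanced_two_batch(seed=3)
        out = pp.anova_correct(fm)
        assert np.allclose(out.values.mean(), fm.values.mean(), atol=1e-10)

    def test_confounded_design_warns(self):
        rng = np.random.default_rng(4)
        fm = feature_matrix(
            rng.normal(size=(8, 2)),
            {
                "cultivar": ["A"] * 4 + ["B"] * 4,
                "batch": ["b1"] * 4 + ["b2"] * 4,  # nested within cultivar
                "sequence": list(range(8)),
            },
        )
        with pytest.warns(UserWarning, match="nested"):
            pp.anova_correct(fm, nuisance=("batch", "sequence"))


class TestNipals:
    def test_rank1_masked_cell_recovered(self):
        rng = np.random.default_rng(0)
        u, v = rng.normal(size=12), rng.normal(size=6)
        full = np.outer(u, v)
        masked = full.copy()
        masked[3, 2] = np.nan
        out = pp.nipals_impute(feature_matrix(masked), n_components=1)
        assert abs(out.values.iloc[3, 2] - full[3, 2]) < 1e-6

    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        out = pp.nipals_impute(feature_matrix(X), n_components=2)
        assert np.array_equal(out.values.to_numpy(), X)

    def test_present_cells_never_altered(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 6))
        mask = rng.random(size=X.shape) < 0.1
        Xm = np.where(mask, np.nan, X)
        out = pp.nipals_impute(feature_matrix(Xm), n_components=2)
        assert np.array_equal(out.values.to_numpy()[~mask], X[~mask])

    def test_component_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5)) @ np.diag([3.0, 1.5, 1.0, 0.5, 0.2])
        Xc = X - X.mean(axis=0)
        scores = pp.nipals_scores(feature_matrix(X), n_components=1)
        w, V = np.linalg.eigh(Xc.T @ Xc)
        lead = Xc @ V[:, np.argmax(w)]
        t = scores["PC1"].to_numpy()
        cos = abs(t @ lead) / (np.linalg.norm(t) * np.linalg.norm(lead))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_error_decreases_at_matched_rank(self):
        rng = np.random.default_rng(4)
        U = rng.normal(size=(40, 3))
        V = rng.normal(size=(3, 12))
        full = U @ V
        mask = rng.random(size=full.shape) < 0.08
        masked = np.where(mask, np.nan, full)
        errs = {}
        for k in (1, 3):
            out = pp.nipals_impute(feature_matrix(masked), n_components=k)
            errs[k] = np.abs(out.values.to_numpy()[mask] - full[mask]).mean()
        assert errs[3] < errs[1]

    def test_empty_feature_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan], [1.5, np.nan]])
        with pytest.raises(ValueError, match="no present values"):
            pp.nipals_impute(feature_matrix(X), n_components=1, max_feature_missing=1.0)


class TestPcaScores:
    def test_collinear_features_explained_by_pc1(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        fm = feature_matrix(np.column_stack([x, 2 * x]))
        _, explained = pp.pca_scores(fm, n_components=2)
        assert explained[0] == pytest.approx(1.0)

    def test_fractions_non_increasing_and_scores_orthogonal(self):
        rng = np.random.default_rng(1)
        fm = feature_matrix(rng.normal(size=(40, 6)))
        scores, explained = pp.pca_scores(fm, n_components=4)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1 + 1e-9
        g = scores.to_numpy().T @ scores.to_numpy()
        assert abs(g[0, 1]) < 1e-8

    def test_incomplete_matrix_rejected(self):
        fm = feature_matrix([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            pp.pca_scores(fm)


def qpcr_table(records):
    return pd.DataFrame(records, columns=["sample", "gene", "ct", "is_reference"])


class TestQpcrNormalize:
    def test_hand_example(self):
        q = qpcr_table(
            [("s1", "g", 25.0, False), ("s1", "r1", 19.0, True), ("s1", "r2", 21.0, True)]
        )
        out = pp.qpcr_normalize(q, ["r1", "r2"])
        assert 10 ** out.values.loc["s1", "g"] == pytest.approx(0.03125)

    def test_ct_equal_reference_mean_gives_unity(self):
        q = qpcr_table(
            [("s1", "g", 20.0, False), ("s1", "r1", 19.0, True), ("s1", "r2", 21.0, True)]
        )
        out = pp.qpcr_normalize(q, ["r1", "r2"])
        assert out.values.loc["s1", "g"] == pytest.approx(0.0)

    def test_missing_target_stays_missing(self):
        q = qpcr_table(
            [
                ("s1", "g", np.nan, False),
                ("s1", "h", 22.0, False),
                ("s1", "r1", 20.0, True),
            ]
        )
        out = pp.qpcr_normalize(q, ["r1"])
        assert np.isnan(out.values.loc["s1", "g"])
        assert np.isfinite(out.values.loc["s1", "h"])

    def test_sample_missing_reference_excluded(self):
        q = qpcr_table(
            [
                ("s1", "g", 22.0, False),
                ("s1", "r1", 20.0, True),
                ("s2", "g", 23.0, False),
            ]
        )
        with pytest.warns(UserWarning, match="missing reference"):
            out = pp.qpcr_normalize(q, ["r1"])
        assert list(out.sample_ids) == ["s1"]

    @pytest.mark.parametrize("offset", [-3.0, 1.5, 7.0])
    def test_per_sample_ct_offset_invariance(self, offset):
        base = qpcr_table(
            [
                ("s1", "g", 24.0, False),
                ("s1", "h", 26.5, False),
                ("s1", "r1", 19.0, True),
                ("s1", "r2", 21.0, True),
            ]
        )
        shifted = base.copy()
        shifted["ct"] += offset
        a = pp.qpcr_normalize(base, ["r1", "r2"])
        b = pp.qpcr_normalize(shifted, ["r1", "r2"])
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())
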