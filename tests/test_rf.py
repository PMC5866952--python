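"""Random-Forest training, OOB statistics, backward elimination, 1-SE rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drymarker import rf

from conftest import feature_matrix


def gaussian_classes(n_per, centers, seed=0, n_noise=0):
    """Well-separated Gaussian blobs plus optional pure-noise features."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label, center in centers.items():
        pts = rng.normal(loc=center, scale=1.0, size=(n_per, len(center)))
        X.append(pts)
        y += [label] * n_per
    X = np.vstack(X)
    if n_noise:
        X = np.hstack([X, rng.normal(size=(len(X), n_noise))])
    return feature_matrix(X), np.array(y)


class TestTrainRf:
    def test_large_margin_low_oob(self):
        fm, y = gaussian_classes(100, {"a": (0, 0), "b": (6, 6)}, seed=0)
        fit = rf.train_rf(fm, y, ntree=300, seed=1)
        assert fit.oob_error < 0.05

    def test_permuted_labels_hit_chance(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fm = feature_matrix(rng.normal(size=(150, 5)))
            y = np.repeat(["a", "b", "c"], 50)
            fit = rf.train_rf(fm, rng.permutation(y), ntree=150, seed=seed)
            errs.append(fit.oob_error)
        assert np.mean(errs) == pytest.approx(2 / 3, abs=0.07)

    def test_constant_feature_zero_importance(self):
        fm, y = gaussian_classes(60, {"a": (0,), "b": (5,)}, seed=2)
        fm.values["const"] = 1.0
        fit = rf.train_rf(fm, y, ntree=200, seed=0)
        assert fit.importance["const"] == 0.0

    def test_expected_class_absent_rejected(self):
        fm, y = gaussian_classes(30, {"a": (0,), "b": (5,)}, seed=3)
        with pytest.raises(ValueError, match="absent"):
            rf.train_rf(fm, y, expected_classes=["a", "b", "c"], ntree=50)

    def test_missing_cells_rejected(self):
        fm = feature_matrix([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0], [5.0, 2.0]])
        with pytest.raises(ValueError, match="missing"):
            rf.train_rf(fm, ["a", "b", "a", "b"], ntree=10)

    def test_fixed_seed_bit_reproducible(self):
        fm, y = gaussian_classes(50, {"a": (0, 0), "b": (2, 2)}, seed=4, n_noise=3)
        fits = [rf.train_rf(fm, y, ntree=100, seed=7) for _ in range(2)]
        assert fits[0].oob_error == fits[1].oob_error
        assert fits[0].importance.equals(fits[1].importance)

    def test_duplicate_feature_splits_importance(self):
        fm, y = gaussian_classes(120, {"a": (0,), "b": (2,)}, seed=5, n_noise=4)
        single = rf.train_rf(fm, y, ntree=300, seed=0)
        dup = fm.copy()
        dup.values["f0_copy"] = dup.values["f0"]
        paired = rf.train_rf(dup, y, ntree=300, seed=0)
        combined = paired.importance["f0"] + paired.importance["f0_copy"]
        assert combined >= 0.8 * single.importance["f0"]


class TestOobSe:
    @pytest.mark.parametrize(
        "err,n,expected",
        [(0.0, 10, 0.0), (0.5, 100, 0.05), (0.09, 200, 0.02024), (1.0, 7, 0.0)],
    )
    def test_binomial_formula(self, err, n, expected):
        assert rf.oob_se(err, n) == pytest.approx(expected, abs=1e-5)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            rf.oob_se(1.2, 10)
        with pytest.raises(ValueError):
            rf.oob_se(0.1, 0)


def make_trace(entries, n_samples=200):
    steps = [
        rf.SelectionStep(
            n_features=k,
            feature_ids=[f"f{i}" for i in range(k)],
            oob_error=e,
            oob_se=rf.oob_se(e, n_samples),
        )
        for k, e in entries
    ]
    return rf.SelectionTrace(steps=steps, chosen_step=0, n_samples=n_samples)


def brute_force_one_se(steps):
    """Independent enumeration oracle for the 1-SE rule."""
    errors = [s.oob_error for s in steps]
    e_star = min(errors)
    s_star = steps[errors.index(e_star)].oob_se
    eligible = [i for i, s in enumerate(steps) if s.oob_error <= e_star + s_star]
    k_min = min(steps[i].n_features for i in eligible)
    for i in eligible:
        if steps[i].n_features == k_min:
            return i
    raise AssertionError("unreachable")


class TestOneSeRule:
    def test_worked_example(self):
        trace = make_trace([(40, 0.10), (32, 0.09), (26, 0.09), (21, 0.10), (17, 0.12)])
        chosen = rf.apply_one_se_rule(trace)
        assert trace.steps[chosen].n_features == 21

    def test_single_step(self):
        trace = make_trace([(10, 0.2)])
        assert rf.apply_one_se_rule(trace) == 0

    def test_full_model_forced(self):
        trace = make_trace([(40, 0.01), (32, 0.30), (26, 0.40)], n_samples=10_000)
        assert rf.apply_one_se_rule(trace) == 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_steps = rng.integers(1, 12)
        sizes = np.sort(rng.choice(np.arange(2, 200), size=n_steps, replace=False))[::-1]
        entries = [(int(k), float(rng.uniform(0, 1))) for k in sizes]
        trace = make_trace(entries, n_samples=int(rng.integers(10, 500)))
        assert rf.apply_one_se_rule(trace) == brute_force_one_se(trace.steps)


def floor_sequence(start, drop_fraction, min_features):
    """Independent recursion oracle for elimination panel sizes."""
    sizes = [start]
    while sizes[-1] > min_features:
        drop = max(1, math.floor(drop_fraction * sizes[-1]))
        sizes.append(max(min_features, sizes[-1] - drop))
    return sizes


class TestBackwardEliminate:
    def test_feature_count_recursion(self):
        rng = np.random.default_rng(0)
        fm = feature_matrix(rng.normal(size=(60, 115)))
        y = np.repeat(["a", "b"], 30)
        trace = rf.backward_eliminate(fm, y, drop_fraction=0.2, ntree=20, seed=0)
        sizes = [s.n_features for s in trace.steps]
        assert sizes == floor_sequence(115, 0.2, 2)
        assert sizes[:5] == [115, 92, 74, 60, 48]

    def test_tiny_drop_fraction_removes_one(self):
        rng = np.random.default_rng(1)
        fm = feature_matrix(rng.normal(size=(40, 8)))
        y = np.repeat(["a", "b"], 20)
        trace = rf.backward_eliminate(fm, y, drop_fraction=0.01, ntree=20, seed=0)
        assert [s.n_features for s in trace.steps] == list(range(8, 1, -1))

    def test_planted_informative_features_survive(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.repeat(["a", "b", "c"], 70)
            X = rng.normal(size=(210, 20))
            X[:, :3] += 2.0 * (np.array([0, 1, 2]).repeat(70))[:, None]
            fm = feature_matrix(X)
            trace = rf.backward_eliminate(fm, y, ntree=150, seed=seed)
            chosen = set(trace.chosen.feature_ids)
            hits += {"f0", "f1", "f2"} <= chosen
        assert hits >= 9

    def test_trace_strictly_decreasing_and_chosen_valid(self):
        rng = np.random.default_rng(2)
        fm = feature_matrix(rng.normal(size=(50, 12)))
        y = np.repeat(["a", "b"], 25)
        trace = rf.backward_eliminate(fm, y, ntree=30, seed=0)
        sizes = [s.n_features for s in trace.steps]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert trace.chosen_step == brute_force_one_se(trace.steps)


class TestPredict:
    def test_resubstitution_on_separable_data(self):
        fm, y = gaussian_classes(60, {"a": (0, 0), "b": (8, 8)}, seed=0)
        fit = rf.train_rf(fm, y, ntree=100, seed=0)
        assert (rf.predict(fit, fm).to_numpy() == y).all()

    def test_column_order_invariance_and_row_independence(self):
        fm, y = gaussian_classes(40, {"a": (0, 0, 0), "b": (3, 3, 3)}, seed=1)
        fit = rf.train_rf(fm, y, ntree=100, seed=0)
        base = rf.predict(fit, fm)
        shuffled = fm.subset(features=list(fm.feature_ids)[::-1])
        assert (rf.predict(fit, shuffled) == base).all()
        doubled = feature_matrix(
            np.vstack([fm.values.to_numpy(), fm.values.to_numpy()])
        )
        pred = rf.predict(fit, doubled).to_numpy()
        assert (pred[: len(base)] == pred[len(base):]).all()

    def test_missing_feature_listed(self):
        fm, y = gaussian_classes(30, {"a": (0, 0), "b": (4, 4)}, seed=2)
        fit = rf.train_rf(fm, y, ntree=50, seed=0)
        with pytest.raises(ValueError, match="f1"):
            rf.predict(fit, fm.subset(features=["f0"]))


class TestSerialization:
    def test_round_trip(self, tmp_path):
        fm, y = gaussian_classes(30, {"a": (0,), "b": (4,)}, seed=0)
        fit = rf.train_rf(fm, y, ntree=50, seed=3)
        fit.save(tmp_path / "model")
        loaded = rf.RFFit.load(tmp_path / "model")
        assert loaded.oob_error == fit.oob_error
        assert loaded.feature_ids == fit.feature_ids
        assert (rf.predict(loaded, fm) == rf.predict(fit, fm)).all()
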