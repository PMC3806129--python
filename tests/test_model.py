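"""Normalization, SVM training, protein-grouped CV and evaluation metrics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depthsite.model import (EvalReport, Normalizer, cross_validate,
                             default_param_grid, evaluate, grid_search,
                             load_model, predict_proba, protein_folds,
                             save_model, train)


def _toy_classification(n=120, seed=0, informative=True):
    """Separable 2-feature toy data with protein group labels."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 2))
    if informative:
        X[:, 0] += 3.0 * y
    groups = np.array([f"prot{i % 8}" for i in range(n)])
    return X, y, groups


class TestNormalizer:
    def test_min_max_maps_to_unit_interval(self):
        X = np.array([[2.0, 5.0], [4.0, 5.0]])
        nz = Normalizer.fit(X)
        out = nz.transform(X)
        np.testing.assert_allclose(out[:, 0], [0.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        X = np.array([[2.0, 5.0], [4.0, 5.0]])
        out = Normalizer.fit(X).transform(X)
        np.testing.assert_allclose(out[:, 1], [0.0, 0.0])

    def test_test_values_clipped_into_unit_interval(self):
        nz = Normalizer.fit(np.array([[0.0], [10.0]]))
        out = nz.transform(np.array([[-5.0], [15.0], [5.0]]))
        np.testing.assert_allclose(out[:, 0], [0.0, 1.0, 0.5])

    def test_layout_mismatch_raises(self):
        nz = Normalizer.fit(np.zeros((3, 5)))
        with pytest.raises(ValueError):
            nz.transform(np.zeros((2, 4)))


class TestTrain:
    def test_separable_data_trains_to_perfect_accuracy(self):
        X, y, _ = _toy_classification(seed=1)
        X[:, 0] = y * 10.0  # fully separable
        model = train(X, y, C=10.0, gamma=0.5, seed=0)
        probs = predict_proba(model, X)
        assert ((probs >= 0.5).astype(int) == y).mean() == 1.0

    def test_single_class_raises(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            train(X, np.zeros(10, dtype=int), C=1.0, gamma=0.1)

    def test_label_swap_complements_probabilities(self):
        X, y, _ = _toy_classification(n=200, seed=2)
        m1 = train(X, y, C=4.0, gamma=0.5, seed=0)
        m2 = train(X, 1 - y, C=4.0, gamma=0.5, seed=0)
        p1 = predict_proba(m1, X)
        p2 = predict_proba(m2, X)
        # Platt calibration is fit on internal folds, so complementation is
        # approximate
        assert np.abs((p1 + p2) - 1.0).mean() < 0.1

    def test_serialization_round_trip_is_exact(self, tmp_path):
        X, y, _ = _toy_classification(seed=3)
        model = train(X, y, C=2.0, gamma=0.25, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        reloaded = load_model(path)
        np.testing.assert_array_equal(predict_proba(model, X),
                                      predict_proba(reloaded, X))
        assert reloaded.layout_fingerprint == model.layout_fingerprint

    def test_bad_archive_rejected(self, tmp_path):
        import joblib
        path = tmp_path / "junk.joblib"
        joblib.dump({"format": "other"}, path)
        with pytest.raises(ValueError):
            load_model(path)


class TestGridSearch:
    def test_grid_of_size_one_returns_that_point(self):
        X, y, groups = _toy_classification(seed=4)
        got = grid_search(X, y, groups, grid=[(7.0, 0.125)], seed=0)
        assert got == (7.0, 0.125)

    def test_deterministic_given_seed(self):
        X, y, groups = _toy_classification(seed=5)
        grid = [(1.0, 0.1), (10.0, 0.5), (100.0, 1.0)]
        a = grid_search(X, y, groups, grid=grid, seed=42)
        b = grid_search(X, y, groups, grid=grid, seed=42)
        assert a == b

    def test_separable_data_finds_accurate_point(self):
        X, y, groups = _toy_classification(n=160, seed=6)
        X[:, 0] = y * 10.0 + np.random.default_rng(0).normal(0, 0.1, len(y))
        grid = [(1.0, 1e-6), (10.0, 0.5)]  # second point can separate
        C, gamma = grid_search(X, y, groups, grid=grid, seed=0)
        assert (C, gamma) == (10.0, 0.5)

    def test_default_grid_shape(self):
        grid = default_param_grid()
        assert len(grid) == 11 * 10
        cs = {c for c, _ in grid}
        assert min(cs) == 2.0 ** -5 and max(cs) == 2.0 ** 15


class TestCrossValidate:
    def test_folds_partition_proteins(self):
        groups = [f"p{i}" for i in range(10) for _ in range(7)]
        folds = protein_folds(groups, k=5, seed=0)
        # each fold holds exactly 2 proteins' worth of samples
        assert sorted(len(f) for f in folds) == [14] * 5
        all_idx = np.concatenate(folds)
        assert len(all_idx) == len(set(all_idx.tolist())) == 70
        groups = np.asarray(groups)
        for f in folds:
            in_fold = set(groups[f].tolist())
            out_fold = set(groups[np.setdiff1d(np.arange(70), f)].tolist())
            assert not (in_fold & out_fold)

    def test_fewer_proteins_than_folds_raises(self):
        with pytest.raises(ValueError):
            protein_folds(["a", "b"], k=5, seed=0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=2, max_value=6))
    def test_fold_partition_property(self, seed, k):
        rng = np.random.default_rng(seed)
        n_prot = int(rng.integers(k, 15))
        groups = np.repeat([f"p{i}" for i in range(n_prot)],
                           rng.integers(1, 6, size=n_prot))
        folds = protein_folds(groups, k=k, seed=seed)
        assert len(folds) == k
        covered = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(covered, np.arange(len(groups)))
        for f in folds:
            others = np.setdiff1d(np.arange(len(groups)), f)
            assert not (set(groups[f]) & set(groups[others]))

    def test_perfect_signal_recovers_perfect_accuracy(self):
        X, y, groups = _toy_classification(n=200, seed=7)
        X[:, 0] = y * 10.0
        report = cross_validate(X, y, groups, C=10.0, gamma=0.5, k=5, seed=0)
        assert report.accuracy == 1.0
        assert report.auc == pytest.approx(1.0)


class TestEvaluate:
    def test_perfect_tiny_case(self):
        report = evaluate(np.array([0.9, 0.1]), np.array([1, 0]))
        for v in (report.accuracy, report.precision, report.sensitivity,
                  report.specificity, report.mcc, report.auc):
            assert v == pytest.approx(1.0)

    def test_all_positive_predictor_on_balanced_labels(self):
        labels = np.array([1, 1, 0, 0])
        report = evaluate(np.array([0.9, 0.9, 0.9, 0.9]), labels)
        assert report.sensitivity == 1.0
        assert report.specificity == 0.0
        assert report.mcc == 0.0
        assert "mcc" in report.undefined

    def test_undefined_ratios_flagged_as_zero(self):
        # no predicted positives -> precision undefined
        report = evaluate(np.array([0.1, 0.1]), np.array([1, 0]))
        assert report.precision == 0.0
        assert "precision" in report.undefined

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        n = 20_000
        labels = rng.integers(0, 2, size=n)
        scores = rng.uniform(size=n)
        report = evaluate(scores, labels)
        assert report.auc == pytest.approx(0.5, abs=0.03)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_agrees_with_brute_force_confusion_counts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        labels = rng.integers(0, 2, size=n)
        scores = rng.uniform(size=n)
        report = evaluate(scores, labels)
        pred = scores >= 0.5
        tp = sum(1 for p, l in zip(pred, labels) if p and l == 1)
        tn = sum(1 for p, l in zip(pred, labels) if not p and l == 0)
        fp = sum(1 for p, l in zip(pred, labels) if p and l == 0)
        fn = sum(1 for p, l in zip(pred, labels) if not p and l == 1)
        assert report.accuracy == pytest.approx((tp + tn) / n)
        if tp + fp:
            assert report.precision == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert report.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert report.specificity == pytest.approx(tn / (tn + fp))
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom:
            assert report.mcc == pytest.approx(
                (tp * tn - fp * fn) / np.sqrt(denom))

    def test_mcc_agrees_with_sklearn(self):
        from sklearn.metrics import matthews_corrcoef
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=500)
        scores = rng.uniform(size=500)
        report = evaluate(scores, labels)
        assert report.mcc == pytest.approx(
            matthews_corrcoef(labels, scores >= 0.5), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, size=300)
        scores = rng.uniform(size=300)
        a1 = evaluate(scores, labels).auc
        a2 = evaluate(1 / (1 + np.exp(-7 * (scores - 0.3))), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=100)
        report = evaluate(rng.uniform(size=100), labels)
        fpr = [p[0] for p in report.roc]
        tpr = [p[1] for p in report.roc]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.5]), np.array([1, 0]))
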