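"""Splitting, SVC risk models, ROC evaluation and learning curves."""

import numpy as np
import pandas as pd
import pytest

from errmir.evaluation import (
    SplitConfig,
    cv_auc,
    evaluate,
    learning_curve_report,
    risk_score,
    score_report,
    split_train_test,
    train_model,
    youden_threshold,
    decision_values,
)
from errmir.features import FeatureMatrix
from errmir.io import model_from_json, model_to_json


def _fm(values: pd.DataFrame, labels) -> FeatureMatrix:
    meta = pd.DataFrame({"label": labels, "batch": "b1"}, index=values.index)
    return FeatureMatrix(values=values, features=[], metadata=meta)


def _separable(n_per_group=20, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0] * n_per_group + [1] * n_per_group)
    x = 2.0 ** (rng.normal(4, 0.3, size=2 * n_per_group) + 6 * y)
    values = pd.DataFrame({"m1|m2": x}, index=[f"s{i}" for i in range(2 * n_per_group)])
    return values, y


def concordance_auc(scores, labels):
    """Mann-Whitney pairwise-concordance estimator (midrank ties)."""
    s = np.asarray(scores)
    pos, neg = s[np.asarray(labels) == 1], s[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSplit:
    def _balanced(self, n=100):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            {"f": rng.uniform(1, 2, n)}, index=[f"s{i}" for i in range(n)]
        )
        y = np.tile([0, 1], n // 2)
        return _fm(values, y)

    def test_75_25_stratified(self):
        fm = self._balanced(100)
        tr, te = split_train_test(fm, SplitConfig(seed=1))
        assert len(tr.values) == 75 and len(te.values) == 25
        assert (tr.labels == 1).sum() in (37, 38)
        assert (te.labels == 1).sum() in (12, 13)

    def test_disjoint_exhaustive(self):
        fm = self._balanced(40)
        tr, te = split_train_test(fm, SplitConfig(seed=2))
        tr_ids, te_ids = set(tr.values.index), set(te.values.index)
        assert tr_ids.isdisjoint(te_ids)
        assert tr_ids | te_ids == set(fm.values.index)

    def test_seed_reproducible(self):
        fm = self._balanced(60)
        a1 = split_train_test(fm, SplitConfig(seed=7))
        a2 = split_train_test(fm, SplitConfig(seed=7))
        assert list(a1[0].values.index) == list(a2[0].values.index)
        b = split_train_test(fm, SplitConfig(seed=8))
        assert list(a1[0].values.index) != list(b[0].values.index)

    def test_unbalanced_rounding(self):
        values = pd.DataFrame({"f": np.arange(12.0) + 1}, index=[f"s{i}" for i in range(12)])
        y = np.array([0] * 7 + [1] * 5)
        tr, te = split_train_test(_fm(values, y), SplitConfig(seed=0))
        assert len(tr.values) == 9 and len(te.values) == 3  # floor(0.75 * 12)
        # per-class proportions preserved to rounding
        assert (tr.labels == 0).sum() in (5, 6)

    def test_tiny_class_is_error(self):
        values = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(_fm(values, [0, 0, 1]), SplitConfig())


class TestTrainModel:
    def test_separable_training_auc(self):
        values, y = _separable()
        model = train_model(values, y, seed=0)
        rep = score_report(risk_score(model, values), y)
        assert rep.auc == pytest.approx(1.0)

    def test_scores_in_unit_interval_and_monotone_in_margin(self):
        values, y = _separable(seed=3)
        model = train_model(values, y, seed=0)
        s = risk_score(model, values)
        d = decision_values(model, values)
        assert ((0 <= s) & (s <= 1)).all()
        assert (np.argsort(s) == np.argsort(d)).all()

    def test_constant_feature_dropped_with_warning(self, caplog):
        values, y = _separable()
        values = values.assign(const=5.0)
        with caplog.at_level("WARNING"):
            model = train_model(values, y, seed=0)
        assert model.markers == ["m1|m2"]
        assert "constant" in caplog.text

    def test_all_constant_is_error(self):
        values = pd.DataFrame({"c": [1.0] * 10}, index=[f"s{i}" for i in range(10)])
        with pytest.raises(ValueError, match="constant"):
            train_model(values, np.array([0, 1] * 5), seed=0)

    def test_single_class_is_error(self):
        values, _ = _separable()
        with pytest.raises(ValueError, match="both classes"):
            train_model(values, np.zeros(len(values), dtype=int), seed=0)

    def test_shuffled_labels_give_chance_cv_auc(self):
        """Permutation null: mean CV AUC over shuffled labellings is ~0.5."""
        rng = np.random.default_rng(0)
        n = 200
        values = pd.DataFrame(
            {"a": 2.0 ** rng.normal(5, 1, n), "b": 2.0 ** rng.normal(5, 1, n)},
            index=[f"s{i}" for i in range(n)],
        )
        aucs = []
        for _ in range(3):
            y = rng.permutation(np.array([0, 1] * (n // 2)))
            aucs.append(cv_auc(values, y, seed=0))
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_duplicated_feature_preserves_ranking(self):
        rng = np.random.default_rng(1)
        n = 60
        base = 2.0 ** (rng.normal(5, 1, n) + np.array([0, 1] * (n // 2)))
        y = np.array([0, 1] * (n // 2))
        idx = [f"s{i}" for i in range(n)]
        v1 = pd.DataFrame({"f": base}, index=idx)
        v2 = pd.DataFrame({"f": base, "f2": base}, index=idx)
        m1 = train_model(v1, y, seed=0)
        m2 = train_model(v2, y, seed=0)
        r1, r2 = risk_score(m1, v1), risk_score(m2, v2)
        assert (np.argsort(r1) == np.argsort(r2)).all()

    def test_identical_samples_identical_scores(self):
        values, y = _separable()
        model = train_model(values, y, seed=0)
        dup = pd.concat([values.iloc[[0]], values.iloc[[0]]])
        s = risk_score(model, dup)
        assert s[0] == s[1]

    def test_missing_marker_column_named(self):
        values, y = _separable()
        model = train_model(values, y, seed=0)
        with pytest.raises(ValueError, match="m1\\|m2"):
            risk_score(model, values.rename(columns={"m1|m2": "other"}))

    def test_json_round_trip_scores_identical(self):
        values, y = _separable(seed=5)
        model = train_model(values, y, seed=0)
        restored = model_from_json(model_to_json(model))
        assert np.array_equal(risk_score(model, values), risk_score(restored, values))
        assert restored.threshold == model.threshold


class TestEvaluate:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        rep = score_report(y.astype(float), y, threshold=0.5)
        assert rep.sensitivity == rep.specificity == rep.auc == 1.0

    def test_degenerate_equal_scores(self):
        y = np.array([0, 1, 0, 1])
        rep = score_report(np.full(4, 0.5), y)
        assert rep.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_concordance_estimator(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.linspace(0.01, 0.99, 30))  # tie-free
        y = (rng.random(30) < 0.5).astype(int)
        if y.sum() in (0, 30):
            return
        rep = score_report(scores, y)
        assert rep.auc == pytest.approx(concordance_auc(scores, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        y = np.array([0, 1] * 20)
        a1 = score_report(scores, y).auc
        a2 = score_report(np.exp(5 * scores), y).auc
        assert a1 == pytest.approx(a2)

    def test_roc_endpoints_monotone(self):
        rng = np.random.default_rng(3)
        rep = score_report(rng.random(30), np.array([0, 1] * 15))
        pts = np.array(rep.roc_points)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_one_class_is_error(self):
        values, y = _separable()
        model = train_model(values, y, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            evaluate(model, values, np.ones(len(values), dtype=int))

    def test_youden_threshold_separates(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.85, 0.9])
        y = np.array([0, 0, 0, 1, 1, 1])
        t = youden_threshold(scores, y)
        assert 0.3 < t <= 0.8


class TestLearningCurve:
    def test_separable_train_score_one(self):
        values, y = _separable(n_per_group=24, seed=0)
        lc = learning_curve_report(values, y, sizes=[16, 32, 48], seed=0)
        assert all(s == pytest.approx(1.0) for s in lc.train_scores)
        assert list(lc.sizes) == sorted(lc.sizes)

    def test_deterministic_under_seed(self):
        values, y = _separable(n_per_group=16, seed=1)
        a = learning_curve_report(values, y, sizes=[12, 24], seed=4)
        b = learning_curve_report(values, y, sizes=[12, 24], seed=4)
        assert a.cv_scores == b.cv_scores and a.train_scores == b.train_scores
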