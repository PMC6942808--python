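"""Boosted-tree diagnostic model: split, grid search, threshold, metrics, ROC, gain."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ghrspipe import boost, simulate
from ghrspipe.simulate import ClinicalDataset


def make_dataset(X, y, names=None):
    names = names or [f"s{j}" for j in range(X.shape[1])]
    frame = pd.DataFrame(np.asarray(X, dtype=int), columns=names)
    frame.insert(0, "subject_id", [f"S{i}" for i in range(len(frame))])
    frame.insert(1, "gender", "male")
    frame.insert(2, "age_group", "3-6")
    frame["label"] = np.where(np.asarray(y) == 1, "positive", "negative")
    return ClinicalDataset(frame=frame, symptoms=names)


@pytest.fixture(scope="module")
def separable_dataset():
    rng = np.random.default_rng(0)
    X = (rng.random((200, 3)) < 0.5).astype(int)
    y = X[:, 0]  # label equals the first symptom
    return make_dataset(X, y)


class TestSplit:
    def test_sizes_and_stratification(self):
        dataset, _ = simulate.generate_clinical_cohort(seed=0)
        train, test = boost.split_train_test(dataset, 0.3, seed=0)
        assert abs(len(test) - 198) <= 1
        assert len(train) + len(test) == 660
        overall = dataset.y.mean()
        # stratification keeps class proportions within one subject
        assert abs(train.y.sum() - overall * len(train)) <= 1
        assert abs(test.y.sum() - overall * len(test)) <= 1

    def test_determinism_and_disjointness(self):
        dataset, _ = simulate.generate_clinical_cohort(seed=1)
        t1, e1 = boost.split_train_test(dataset, 0.3, seed=5)
        t2, e2 = boost.split_train_test(dataset, 0.3, seed=5)
        assert t1.frame.equals(t2.frame) and e1.frame.equals(e2.frame)
        ids = set(t1.frame["subject_id"]) | set(e1.frame["subject_id"])
        assert len(ids) == 660
        assert not set(t1.frame["subject_id"]) & set(e1.frame["subject_id"])

    def test_invalid_fraction(self):
        dataset, _ = simulate.generate_clinical_cohort(seed=0)
        with pytest.raises(ValueError):
            boost.split_train_test(dataset, 1.0, seed=0)


class TestGridSearch:
    def test_singleton_grid_returned(self, separable_dataset):
        grid = {k: [v] for k, v in boost.PAPER_OPTIMAL_PARAMS.items()}
        best, acc = boost.grid_search(separable_dataset, grid, k=5, seed=0)
        assert best == boost.PAPER_OPTIMAL_PARAMS
        assert 0.0 <= acc <= 1.0

    def test_separable_data_perfect_cv_accuracy(self, separable_dataset):
        grid = {"nrounds": [30], "max_depth": [2], "eta": [0.3], "gamma": [0],
                "min_child_weight": [1], "subsample": [1.0], "colsample_bytree": [1.0]}
        _, acc = boost.grid_search(separable_dataset, grid, k=5, seed=0)
        assert acc == 1.0

    def test_tie_break_prefers_fewer_rounds(self, separable_dataset):
        grid = {"nrounds": [80, 20], "max_depth": [4, 2], "eta": [0.3], "gamma": [0],
                "min_child_weight": [1], "subsample": [1.0], "colsample_bytree": [1.0]}
        best, acc = boost.grid_search(separable_dataset, grid, k=5, seed=0)
        assert acc == 1.0
        assert best["nrounds"] == 20
        assert best["max_depth"] == 2


class TestThreshold:
    def test_separated_scores_tie_to_half(self, separable_dataset):
        class Stub:
            def predict_proba(self, X):
                return np.where(X[:, 0] == 1, 0.9, 0.1)

        model = Stub()
        assert boost.optimal_threshold(model, separable_dataset) == 0.5

    def test_constant_scores_pick_majority(self):
        # majority positive: any threshold <= 0.7 classifies all positive
        rng = np.random.default_rng(1)
        X = (rng.random((100, 2)) < 0.5).astype(int)
        y = np.r_[np.ones(70, dtype=int), np.zeros(30, dtype=int)]
        ds = make_dataset(X, y)

        class Stub:
            def predict_proba(self, X):
                return np.full(len(X), 0.7)

        t = boost.optimal_threshold(Stub(), ds)
        # error is 0.3 for thresholds <= 0.7 (all positive), 0.7 above;
        # tie-break picks the admissible threshold closest to 0.5
        assert t == 0.5

    def test_minimizes_error(self):
        rng = np.random.default_rng(2)
        X = (rng.random((200, 2)) < 0.5).astype(int)
        y = rng.integers(0, 2, 200)
        ds = make_dataset(X, y)
        scores = rng.random(200)

        class Stub:
            def predict_proba(self, X_):
                return scores

        t = boost.optimal_threshold(Stub(), ds)
        errs = {
            round(g, 2): (np.where(scores >= g, 1, 0) != y).mean()
            for g in np.arange(0.01, 1.0, 0.01)
        }
        assert errs[round(t, 2)] == min(errs.values())


class TestMetrics:
    def test_perfect_and_flipped_scores(self):
        y = np.array([1, 1, 0, 0])
        perfect = boost.classification_metrics(y, np.array([0.9, 0.8, 0.1, 0.2]), 0.5)
        assert perfect.accuracy == 1.0
        assert perfect.omission_rate == 0.0
        assert perfect.mistake_rate == 0.0
        flipped = boost.classification_metrics(y, np.array([0.1, 0.2, 0.9, 0.8]), 0.5)
        assert flipped.accuracy == 0.0
        assert flipped.sensitivity == 0.0
        assert flipped.specificity == 0.0

    def test_hand_built_confusion(self):
        # TP=4, FN=1, TN=4, FP=1
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.1, 0.2, 0.3, 0.1, 0.2, 0.9])
        m = boost.classification_metrics(y, s, 0.5)
        assert (m.tp, m.fn, m.tn, m.fp) == (4, 1, 4, 1)
        assert m.accuracy == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.8)
        assert m.omission_rate == pytest.approx(0.2)
        assert m.mistake_rate == pytest.approx(0.2)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_rate_identities_on_random_confusions(self, data):
        """sensitivity + omission = 1 and specificity + mistake = 1, exactly."""
        n = data.draw(st.integers(4, 60))
        y = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        s = np.array(data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
        ))
        t = data.draw(st.floats(0.05, 0.95))
        m = boost.classification_metrics(y, s, t)
        if not math.isnan(m.sensitivity):
            assert m.sensitivity + m.omission_rate == 1.0
        if not math.isnan(m.specificity):
            assert m.specificity + m.mistake_rate == 1.0
        assert m.tp + m.fn + m.tn + m.fp == n

    def test_single_class_flagged(self):
        m = boost.classification_metrics(np.ones(5, dtype=int), np.full(5, 0.9), 0.5)
        assert math.isnan(m.specificity) and math.isnan(m.mistake_rate)
        assert m.sensitivity == 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = boost.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = boost.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_equals_pair_counting_oracle(self):
        """Trapezoid AUC equals concordant-pair counting with ties at 1/2,
        exhaustively on small random score sets."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(6, 21))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            _, auc = boost.roc_auc(y, s)
            pos = s[y == 1]
            neg = s[y == 0]
            pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
            assert auc == pytest.approx(float(np.mean(pairs)), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        _, auc = boost.roc_auc(y, s)
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        _, a1 = boost.roc_auc(y, s)
        _, a2 = boost.roc_auc(y, np.exp(3 * s) / (1 + np.exp(3 * s)))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            boost.roc_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestGainImportance:
    def test_single_feature_share_is_one(self):
        rng = np.random.default_rng(6)
        X = (rng.random((200, 1)) < 0.5).astype(int)
        y = X[:, 0]
        model = boost.fit_model(make_dataset(X, y), seed=0)
        table = boost.gain_importance(model)
        assert len(table) == 1
        assert table["gain_share"].iloc[0] == pytest.approx(1.0)

    def test_shares_sum_to_one_and_sorted(self):
        dataset, _ = simulate.generate_clinical_cohort(seed=2)
        model = boost.fit_model(dataset, seed=2)
        table = boost.gain_importance(model)
        assert table["gain_share"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (table["gain_share"].to_numpy() >= 0).all()
        assert (np.diff(table["gain_share"].to_numpy()) <= 1e-15).all()

    def test_dominant_symptom_ranks_high(self):
        """The largest planted log-odds symptom is in the top gains in most seeds."""
        hits = 0
        for seed in range(20):
            dataset, truth = simulate.generate_clinical_cohort(seed=seed)
            model = boost.fit_model(dataset, seed=seed)
            table = boost.gain_importance(model)
            strongest = max(truth.coefficients, key=lambda s: truth.coefficients[s])
            hits += strongest in set(table["feature"].head(3))
        assert hits >= 10  # median-over-seeds claim: top-3 in at least half


class TestEndToEnd:
    def test_synthetic_cohort_performance(self, model_study):
        """Median test AUC > 0.9 and accuracy > 0.85 on the default cohort
        (70/30 stratified split, reference hyper-parameters), 20 seeds."""
        assert float(np.median(model_study["auc"])) > 0.9
        assert float(np.median(model_study["accuracy"])) > 0.85
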