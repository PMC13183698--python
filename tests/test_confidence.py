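"""Labeling, subject folds, classifiers, ROC/AUC and Pearson correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rppg_confidence import (
    ClassifierConfig,
    evaluate,
    label_windows,
    load_model,
    make_subject_folds,
    pearson_correlation,
    predict_score,
    roc_auc,
    save_model,
    train_confidence_model,
)
from rppg_confidence.confidence import label_counts
from rppg_confidence.synthetic import FEATURE_NAMES, generate_feature_table

from conftest import SUITE_SEED, make_records_from_table


def records_with_errors(errors):
    n = len(errors)
    df = pd.DataFrame({f: np.zeros(n) for f in FEATURE_NAMES})
    df["abs_err_bpm"] = errors
    df["subject_id"] = [f"s{i}" for i in range(n)]
    df["dataset_id"] = "d0"
    df["method"] = "GREEN"
    return df


def brute_force_auc(scores, labels):
    """Mean over all (positive, negative) pairs of 1[s_p > s_n] + 0.5 ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = sum(1.0 if p > n else 0.5 if p == n else 0.0
                for p, n in itertools.product(pos, neg))
    return total / (len(pos) * len(neg))


class TestLabeling:
    def test_threshold_rule_on_printed_errors(self):
        lab = label_windows(records_with_errors([1.5, 1.99, 2.0, 4.0, 6.0, 7.0]))
        expected = [1.0, 1.0, np.nan, np.nan, np.nan, 0.0]
        np.testing.assert_array_equal(lab["label"].to_numpy(), expected)

    def test_counts_partition_all_windows(self):
        errs = [0.1, 1.9, 2.0, 3.0, 5.9, 6.0, 6.1, 50.0, np.nan]
        counts = label_counts(label_windows(records_with_errors(errs)))
        assert counts["reliable"] + counts["unreliable"] + counts["discarded"] \
            == counts["total"] == len(errs)
        assert counts == {"reliable": 2, "unreliable": 2, "discarded": 5, "total": 9}

    def test_missing_reference_gets_distinct_reason(self):
        lab = label_windows(records_with_errors([np.nan, 3.0, 1.0]))
        assert list(lab["discard_reason"]) == ["no_reference", "ambiguous_error", ""]


class TestSubjectFolds:
    def test_each_subject_in_exactly_one_fold(self):
        df = make_records_from_table(generate_feature_table(60, 1.0, seed=0),
                                     n_subjects=10)
        for k in (2, 3, 5):
            for seed in (0, 1, 99):
                folds = make_subject_folds(df, k=k, seed=seed)
                assert set(folds) == set(df["subject_id"].unique())
                assert all(0 <= f < k for f in folds.values())

    def test_equal_counts_balance_exactly(self):
        rows = []
        for s in range(5):
            rows += [{"subject_id": f"s{s}"}] * 100
        df = pd.DataFrame(rows)
        folds = make_subject_folds(df, k=5, seed=0)
        sizes = df["subject_id"].map(folds).value_counts()
        assert set(sizes) == {100}

    def test_greedy_matches_exhaustive_minimum_on_example(self):
        counts = {"a": 90, "b": 80, "c": 70, "d": 30, "e": 30}
        df = pd.DataFrame([{"subject_id": s} for s, c in counts.items()
                           for _ in range(c)])
        folds = make_subject_folds(df, k=2, seed=0)
        greedy_max = df["subject_id"].map(folds).value_counts().max()
        # exhaustive oracle over all 2^5 assignments
        best = min(
            max(sum(c for (s, c), a in zip(counts.items(), assign) if a == side)
                for side in (0, 1))
            for assign in itertools.product((0, 1), repeat=5))
        assert greedy_max == best == 150

    def test_deterministic_given_seed(self):
        df = make_records_from_table(generate_feature_table(40, 1.0, seed=0),
                                     n_subjects=8)
        assert make_subject_folds(df, 4, seed=7) == make_subject_folds(df, 4, seed=7)

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame([{"subject_id": "s0"}, {"subject_id": "s1"}])
        with pytest.raises(ValueError, match="subjects"):
            make_subject_folds(df, k=5, seed=0)


class TestTrainPredict:
    def test_separable_data_training_auc_is_one(self):
        # separation d=10 puts the classes ~7 sd apart: linearly separable
        df = make_records_from_table(generate_feature_table(200, 10.0, seed=5),
                                     n_subjects=10)
        model = train_confidence_model(df, seed=0)
        scores = predict_score(model, df)
        assert roc_auc(scores, df["label"]).auc == 1.0

    def test_permuted_labels_give_chance_auc(self):
        df = make_records_from_table(generate_feature_table(1000, 2.0, seed=1),
                                     n_subjects=10)
        rng = np.random.default_rng(SUITE_SEED)
        df["label"] = rng.permutation(df["label"].to_numpy())
        df["abs_err_bpm"] = np.where(df["label"] == 1, 1.0, 8.0)
        rep = evaluate(df, scheme="combined", k=5, seed=SUITE_SEED)
        assert rep["methods"]["GREEN"]["auc"] == pytest.approx(0.5, abs=0.05)

    def test_deterministic_scores_on_rerun(self, gaussian_records):
        s1 = predict_score(train_confidence_model(gaussian_records, seed=3),
                           gaussian_records)
        s2 = predict_score(train_confidence_model(gaussian_records, seed=3),
                           gaussian_records)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_training_rejected(self, gaussian_records):
        only_pos = gaussian_records[gaussian_records["label"] == 1]
        with pytest.raises(ValueError, match="both"):
            train_confidence_model(only_pos, seed=0)

    def test_centroid_scores_ordered(self, gaussian_records):
        model = train_confidence_model(gaussian_records, seed=0)
        feats = gaussian_records[list(FEATURE_NAMES)]
        c1 = feats[gaussian_records["label"] == 1].mean().to_frame().T
        c0 = feats[gaussian_records["label"] == 0].mean().to_frame().T
        s1 = predict_score(model, c1)[0]
        s0 = predict_score(model, c0)[0]
        assert s1 > 0.9
        assert s0 < 0.1

    def test_scores_bounded_and_finite_input_required(self, gaussian_records):
        model = train_confidence_model(gaussian_records, seed=0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 4)) * 2
        s = predict_score(model, x)
        assert np.all((s >= 0) & (s <= 1))
        with pytest.raises(ValueError, match="finite"):
            predict_score(model, np.array([[1.0, np.nan, 0.0, 0.0]]))

    def test_model_roundtrip_on_disk(self, gaussian_records, tmp_path):
        model = train_confidence_model(gaussian_records, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(predict_score(loaded, gaussian_records),
                                      predict_score(model, gaussian_records))

    @pytest.mark.parametrize("kind", ["fine_tree", "lda", "logistic",
                                      "naive_bayes", "knn1", "boosted_trees",
                                      "neural_network"])
    def test_classifier_roster_trains_and_scores(self, gaussian_records, kind):
        model = train_confidence_model(gaussian_records,
                                       ClassifierConfig(kind), seed=0)
        s = predict_score(model, gaussian_records)
        assert np.all((s >= 0) & (s <= 1))
        assert roc_auc(s, gaussian_records["label"]).auc > 0.9


class TestROCAUC:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_three_of_four_pairs_concordant(self):
        assert roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]).auc == 0.75

    def test_matches_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(SUITE_SEED)
        for _ in range(50):
            n = rng.integers(4, 41)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(size=n), 2)  # induce ties
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels),
                                          abs=1e-12)

    def test_curve_monotone_and_auc_is_trapezoid(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        r = roc_auc(scores, labels)
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)
        assert r.auc == pytest.approx(np.trapezoid(r.tpr, r.fpr), abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=15, deadline=None)
    def test_invariant_under_strictly_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(size=25)
        labels = rng.integers(0, 2, size=25)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores) + 1, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.2, 0.4], [1, 1])


class TestPearson:
    def test_identity_and_affine(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -2 * x + 3)[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        # direct evaluation of the covariance / product-of-sds ratio
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(num / den, abs=1e-12)
        assert 0 < p <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEvaluate:
    def shared_mechanism_records(self):
        """Three pseudo-datasets drawn from one generating mechanism."""
        parts = []
        for d in range(3):
            t = generate_feature_table(120, 2.0, seed=100 + d)
            part = make_records_from_table(t, n_subjects=6, seed=d)
            part["dataset_id"] = f"d{d}"
            part["subject_id"] = f"d{d}_" + part["subject_id"]
            part["video_id"] = part["subject_id"] + "_v0"
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    def test_combined_cv_at_least_within_dataset_mean(self):
        df = self.shared_mechanism_records()
        combined = evaluate(df, scheme="combined", k=5, seed=SUITE_SEED)
        within = evaluate(df, scheme="within", k=5, seed=SUITE_SEED)
        m = "GREEN"
        assert combined["methods"][m]["auc"] >= within["methods"][m]["mean_auc"]

    def test_cross_dataset_runs_and_tallies_partition(self):
        df = self.shared_mechanism_records()
        rep = evaluate(df, scheme="cross", k=5, seed=0)
        entry = rep["methods"]["GREEN"]
        assert set(entry["datasets"]) == {"d0", "d1", "d2"}
        c = entry["counts"]
        assert c["reliable"] + c["unreliable"] + c["discarded"] == c["total"]

    def test_cross_dataset_needs_two_datasets(self, gaussian_records):
        with pytest.raises(ValueError, match="datasets"):
            evaluate(gaussian_records, scheme="cross", k=5, seed=0)

    def test_unknown_scheme_rejected(self, gaussian_records):
        with pytest.raises(ValueError, match="scheme"):
            evaluate(gaussian_records, scheme="bootstrap")
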