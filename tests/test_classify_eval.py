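"""Splits, training, metrics and the Model/Results interface."""

import numpy as np
import pandas as pd
import pytest

from cardiocycle.classify_eval import (
    CycleClassifier,
    MLPConfig,
    evaluate,
    grouped_kfold,
    make_patient_split,
    train_mlp,
)


def blob_features(n_per_class=100, separation=10.0, n_subjects=4, seed=0):
    """Two well-separated Gaussian blobs in feature space."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, offset in (("healthy", 0.0), ("epilepsy", separation)):
        for i in range(n_per_class):
            rows.append({
                "subject_id": f"{label[:1]}{i % n_subjects}",
                "label": label,
                "center_kind": "median",
                "center": 0.0,
                "variance": offset + rng.normal(),
                "skewness": offset + rng.normal(),
                "kurtosis": 3.0 + rng.normal(),
            })
    return pd.DataFrame(rows)


class TestPatientSplit:
    def test_cohort_sex_stratification(self):
        # 5 male + 13 female subjects at 70% training:
        # floor(5*0.7)=3 M and floor(13*0.7)=9 F train; 2 M + 4 F test
        subjects = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(18)],
            "label": ["healthy"] * 18,
            "sex": ["M"] * 5 + ["F"] * 13,
        })
        # a second class so the single-class guard does not fire
        extra = pd.DataFrame({
            "subject_id": ["e1", "e2"], "label": ["epilepsy"] * 2, "sex": ["F", "F"]})
        plan = make_patient_split(pd.concat([subjects, extra]), 0.7, seed=4)
        healthy = subjects.set_index("subject_id")
        train = [s for s, v in plan.assignment.items()
                 if v == "train" and s in healthy.index]
        test = [s for s, v in plan.assignment.items()
                if v == "test" and s in healthy.index]
        assert sum(healthy.loc[s, "sex"] == "M" for s in train) == 3
        assert sum(healthy.loc[s, "sex"] == "F" for s in train) == 9
        assert sum(healthy.loc[s, "sex"] == "M" for s in test) == 2
        assert sum(healthy.loc[s, "sex"] == "F" for s in test) == 4

    def test_deterministic_and_partition(self):
        subs = [(f"s{i}", "healthy" if i % 2 else "epilepsy") for i in range(10)]
        p1 = make_patient_split(subs, 0.7, seed=9)
        p2 = make_patient_split(subs, 0.7, seed=9)
        assert p1.assignment == p2.assignment
        assert set(p1.assignment) == {s for s, _ in subs}
        assert set(p1.assignment.values()) == {"train", "test"}

    def test_single_subject_class_rejected(self):
        with pytest.raises(ValueError):
            make_patient_split([("a", "healthy"), ("b", "healthy"),
                                ("c", "epilepsy")], 0.7, seed=0)


class TestGroupedKFold:
    def test_twenty_subjects_ten_folds(self):
        subs = [(f"h{i}", "healthy") for i in range(10)] + \
               [(f"e{i}", "epilepsy") for i in range(10)]
        plan = grouped_kfold(subs, k=10, seed=1)
        assert plan.k == 10
        counts = pd.Series(list(plan.assignment.values())).value_counts()
        assert (counts == 2).all()  # each fold tests exactly 2 subjects
        assert set(plan.assignment) == {s for s, _ in subs}

    def test_union_covers_each_subject_once(self):
        subs = [(f"s{i}", "healthy" if i < 6 else "epilepsy") for i in range(12)]
        plan = grouped_kfold(subs, k=4, seed=3)
        assert sorted(plan.assignment) == sorted(s for s, _ in subs)
        assert set(plan.assignment.values()) <= set(range(4))

    def test_two_folds_of_two(self):
        plan = grouped_kfold([("a", "x"), ("b", "x"), ("c", "x"), ("d", "x")],
                             k=2, seed=0)
        counts = pd.Series(list(plan.assignment.values())).value_counts()
        assert sorted(counts) == [2, 2]

    def test_fewer_subjects_than_folds(self):
        plan = grouped_kfold([("a", "x"), ("b", "x"), ("c", "y")], k=10, seed=0)
        assert plan.k == 3

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold([("a", "x"), ("b", "y")], k=1, seed=0)


class StubModel:
    """Fixed-prediction model for metric arithmetic tests."""

    feature_columns_ = ["variance", "skewness", "kurtosis"]

    def __init__(self, preds):
        self.preds = np.asarray(preds)

    def predict(self, X):
        return self.preds


def confusion_table(tp, fn, tn, fp):
    labels = ["epilepsy"] * (tp + fn) + ["healthy"] * (tn + fp)
    preds = (["epilepsy"] * tp + ["healthy"] * fn
             + ["healthy"] * tn + ["epilepsy"] * fp)
    df = pd.DataFrame({
        "subject_id": "s", "label": labels,
        "variance": 0.0, "skewness": 0.0, "kurtosis": 0.0})
    return df, preds


class TestEvaluate:
    def test_metric_arithmetic(self):
        df, preds = confusion_table(tp=97, fn=3, tn=98, fp=2)
        m = evaluate(StubModel(preds), df)
        assert m.sensitivity == pytest.approx(0.97)
        assert m.specificity == pytest.approx(0.98)
        assert m.accuracy == pytest.approx(0.975)
        assert (m.tp, m.tn, m.fp, m.fn) == (97, 98, 2, 3)

    def test_all_correct(self):
        df, preds = confusion_table(tp=5, fn=0, tn=5, fp=0)
        m = evaluate(StubModel(preds), df)
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_constant_healthy_predictor(self):
        df, _ = confusion_table(tp=0, fn=50, tn=50, fp=0)
        m = evaluate(StubModel(["healthy"] * 100), df)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.accuracy == 0.5

    def test_undefined_metric_is_nan_not_zero(self):
        df, preds = confusion_table(tp=0, fn=0, tn=10, fp=0)
        m = evaluate(StubModel(preds), df)
        assert np.isnan(m.sensitivity)
        assert m.specificity == 1.0


class TestTraining:
    def test_separable_blobs_perfect_training_accuracy(self):
        df = blob_features(separation=10.0)
        model = train_mlp(df, MLPConfig(seed=0))
        m = evaluate(model, df)
        assert m.accuracy == 1.0

    def test_single_class_rejected(self):
        df = blob_features()
        with pytest.raises(ValueError):
            train_mlp(df[df.label == "healthy"], MLPConfig())

    def test_seeded_determinism(self):
        df = blob_features(separation=2.0, seed=5)
        preds = []
        for _ in range(2):
            model = train_mlp(df, MLPConfig(seed=11))
            preds.append(model.predict(df[["variance", "skewness", "kurtosis"]].to_numpy()))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestModelResults:
    def test_cv_report_structure_and_identity(self):
        df = blob_features(n_per_class=60, separation=6.0, n_subjects=6, seed=2)
        res = CycleClassifier(df, MLPConfig(seed=0)).fit(mode="cv", k=3, seed=0)
        assert len(res.per_fold) == 3
        for f in res.per_fold:
            total = f.tp + f.tn + f.fp + f.fn
            p, n = f.tp + f.fn, f.tn + f.fp
            # accuracy = (sens*P + spec*N) / (P+N)
            if p and n:
                assert f.accuracy == pytest.approx(
                    (f.sensitivity * p + f.specificity * n) / total)
        txt = res.summary()
        assert "accuracy" in txt and "±" in txt

    def test_formatting_two_decimals(self):
        df = blob_features(n_per_class=40, separation=8.0, seed=3)
        res = CycleClassifier(df, MLPConfig(seed=0)).fit(mode="cv", k=2, seed=0)
        formatted = res.report.format_metric("accuracy")
        assert len(formatted.split(" ± ")) == 2
        for part in formatted.split(" ± "):
            assert len(part.split(".")[1]) == 2

    def test_holdout_mode(self):
        df = blob_features(n_per_class=60, separation=8.0, n_subjects=5, seed=1)
        res = CycleClassifier(df, MLPConfig(seed=0)).fit(mode="holdout", seed=0)
        assert len(res.per_fold) == 1
        assert res.accuracy[0] > 0.9

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(0)
        df = blob_features(n_per_class=150, separation=4.0, n_subjects=6, seed=7)
        df["label"] = rng.permutation(df["label"].to_numpy())
        res = CycleClassifier(df, MLPConfig(seed=0)).fit(mode="cv", k=4, seed=0)
        assert 0.3 <= res.accuracy[0] <= 0.7

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            CycleClassifier(pd.DataFrame({"subject_id": [], "label": []}))
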