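import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from mdrgait import (
    FALLER,
    NON_FALLER,
    SVMModelSpec,
    confusion_and_metrics,
    predict,
    split_train_validation,
    train_svm,
)
from mdrgait.features import FEATURE_COLUMNS


def feature_frame(X: np.ndarray, labels) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df.insert(0, "label", list(labels))
    df.insert(0, "subject_id", [f"s{i}" for i in range(len(df))])
    return df


def gaussian_classes(n_per_class: int, distance: float, seed: int) -> pd.DataFrame:
    """Two isotropic unit-variance Gaussians separated by ``distance`` in 2-D,
    embedded in the four feature columns (last two are pure noise)."""
    rng = np.random.default_rng(seed)
    mu = distance / 2.0
    a = rng.normal([+mu, +mu * 0, 0, 0], 1.0, size=(n_per_class, 4))
    b = rng.normal([-mu, -mu * 0, 0, 0], 1.0, size=(n_per_class, 4))
    X = np.vstack([a, b])
    labels = [FALLER] * n_per_class + [NON_FALLER] * n_per_class
    return feature_frame(X, labels)


def separable_clusters(n_per_class=20, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    a = rng.normal([5, 5, 5, 5], 0.1, size=(n_per_class, 4))
    b = rng.normal([-5, -5, -5, -5], 0.1, size=(n_per_class, 4))
    return feature_frame(np.vstack([a, b]), [FALLER] * n_per_class + [NON_FALLER] * n_per_class)


class TestSplit:
    def test_480_split_sizes(self):
        df = gaussian_classes(240, 1.0, seed=1)
        train, val = split_train_validation(df, 0.7, rng_seed=0)
        assert len(train) == 336
        assert len(val) == 144

    def test_stratified(self):
        df = gaussian_classes(240, 1.0, seed=1)
        train, val = split_train_validation(df, 0.7, rng_seed=0)
        assert (train["label"] == FALLER).sum() == 168
        assert (val["label"] == FALLER).sum() == 72

    def test_disjoint_exhaustive(self):
        df = gaussian_classes(50, 1.0, seed=2)
        train, val = split_train_validation(df, 0.7, rng_seed=3)
        ids = sorted(train["subject_id"]) + sorted(val["subject_id"])
        assert sorted(ids) == sorted(df["subject_id"])

    def test_full_fraction_rejected(self):
        df = gaussian_classes(10, 1.0, seed=1)
        with pytest.raises(ValueError):
            split_train_validation(df, 1.0)

    def test_deterministic(self):
        df = gaussian_classes(30, 1.0, seed=4)
        a1, b1 = split_train_validation(df, 0.7, rng_seed=11)
        a2, b2 = split_train_validation(df, 0.7, rng_seed=11)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_tiny_class_rejected(self):
        df = feature_frame(np.zeros((3, 4)), [FALLER, NON_FALLER, NON_FALLER])
        with pytest.raises(ValueError):
            split_train_validation(df, 0.7)


class TestTrainSVM:
    def test_separable_validation_accuracy(self):
        df = separable_clusters()
        train, val = split_train_validation(df, 0.7, rng_seed=0)
        model = train_svm(train, val)
        assert model.validation_metrics["accuracy"] == 1.0

    def test_bayes_rate_recovered(self):
        # Bayes error 15% => separation 2*z(0.85) between unit Gaussians
        distance = 2 * norm.ppf(0.85)
        accs = []
        for seed in range(20):
            train = gaussian_classes(400, distance, seed=seed)
            val = gaussian_classes(400, distance, seed=10_000 + seed)
            model = train_svm(train, val)
            accs.append(model.validation_metrics["accuracy"])
        assert np.mean(accs) == pytest.approx(0.85, abs=0.05)

    def test_sensitivity_objective_dominates(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n_pos, n_neg = 40, 120
            a = rng.normal(0.5, 1.0, size=(n_pos, 4))
            b = rng.normal(-0.5, 1.0, size=(n_neg, 4))
            df = feature_frame(np.vstack([a, b]), [FALLER] * n_pos + [NON_FALLER] * n_neg)
            train, val = split_train_validation(df, 0.7, rng_seed=seed)
            m_acc = train_svm(train, val, objective="accuracy")
            m_sens = train_svm(train, val, objective="sensitivity")
            assert (
                m_sens.validation_metrics["sensitivity"]
                >= m_acc.validation_metrics["sensitivity"]
            )

    def test_single_class_training_rejected(self):
        df = separable_clusters()
        train = df[df["label"] == FALLER].reset_index(drop=True)
        val = df
        with pytest.raises(ValueError, match="class"):
            train_svm(train, val)

    def test_standardization_uses_training_statistics_only(self):
        df = separable_clusters(seed=5)
        train, val = split_train_validation(df, 0.7, rng_seed=0)
        model = train_svm(train, val)
        expected_mu = train[FEATURE_COLUMNS].to_numpy().mean(axis=0)
        expected_sd = train[FEATURE_COLUMNS].to_numpy().std(axis=0)
        np.testing.assert_allclose(model.scale_mean, expected_mu)
        np.testing.assert_allclose(model.scale_std, expected_sd)


class TestPredict:
    @pytest.fixture
    def trained(self):
        df = separable_clusters(seed=7)
        train, val = split_train_validation(df, 0.7, rng_seed=1)
        return train_svm(train, val), train

    def test_training_labels_recovered(self, trained):
        model, train = trained
        assert predict(model, train) == list(train["label"])

    def test_duplicated_row_identical(self, trained):
        model, train = trained
        row = pd.concat([train.iloc[[0]], train.iloc[[0]]], ignore_index=True)
        preds = predict(model, row)
        assert preds[0] == preds[1]

    def test_far_point_classified_by_side(self, trained):
        model, _ = trained
        far_faller = feature_frame(np.full((1, 4), 50.0), [FALLER])
        far_nonfaller = feature_frame(np.full((1, 4), -50.0), [NON_FALLER])
        assert predict(model, far_faller) == [FALLER]
        assert predict(model, far_nonfaller) == [NON_FALLER]
        # decision-function sign oracle
        assert model.decision_function(far_faller)[0] > 0
        assert model.decision_function(far_nonfaller)[0] < 0

    def test_missing_column_rejected(self, trained):
        model, train = trained
        with pytest.raises(KeyError):
            predict(model, train.drop(columns=["v_u_std"]))

    def test_json_round_trip(self, trained, tmp_path):
        model, train = trained
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = SVMModelSpec.from_json(path)
        np.testing.assert_allclose(
            model.decision_function(train), restored.decision_function(train)
        )
        assert predict(model, train) == predict(restored, train)


class TestConfusionAndMetrics:
    def test_accuracy_tuned_table(self):
        y_true = [FALLER] * 14 + [NON_FALLER] * 19
        y_pred = [FALLER] * 9 + [NON_FALLER] * 5 + [FALLER] * 2 + [NON_FALLER] * 17
        cm, metrics = confusion_and_metrics(y_true, y_pred)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (9, 5, 2, 17)
        pct = metrics.as_percent_dict()
        assert pct["accuracy"] == 78.8
        assert pct["sensitivity"] == 64.3

    def test_sensitivity_tuned_table(self):
        y_true = [FALLER] * 14 + [NON_FALLER] * 19
        y_pred = [FALLER] * 10 + [NON_FALLER] * 4 + [FALLER] * 5 + [NON_FALLER] * 14
        cm, metrics = confusion_and_metrics(y_true, y_pred)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 4, 5, 14)
        pct = metrics.as_percent_dict()
        assert pct["accuracy"] == 72.7
        assert pct["sensitivity"] == 71.4

    def test_perfect_predictions(self):
        y = [FALLER] * 3 + [NON_FALLER] * 4
        _, metrics = confusion_and_metrics(y, y)
        assert metrics.as_percent_dict() == {
            "accuracy": 100.0,
            "sensitivity": 100.0,
            "specificity": 100.0,
            "precision": 100.0,
        }

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([], [])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([FALLER], ["unknown"])

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_accuracy_is_prevalence_weighted(self, tp, fn, fp, tn):
        if tp + fn == 0 or fp + tn == 0:
            return
        y_true = [FALLER] * (tp + fn) + [NON_FALLER] * (fp + tn)
        y_pred = (
            [FALLER] * tp + [NON_FALLER] * fn + [FALLER] * fp + [NON_FALLER] * tn
        )
        cm, metrics = confusion_and_metrics(y_true, y_pred)
        prevalence = (tp + fn) / cm.total
        expected = metrics.sensitivity * prevalence + metrics.specificity * (1 - prevalence)
        assert metrics.accuracy == pytest.approx(expected, abs=1e-12)
        for v in metrics.as_dict().values():
            assert np.isnan(v) or 0.0 <= v <= 1.0  # nan when a denominator is 0

    def test_permutation_safety(self):
        rng = np.random.default_rng(8)
        y_true = [FALLER] * 10 + [NON_FALLER] * 15
        y_pred = list(rng.choice([FALLER, NON_FALLER], size=25))
        cm_a, _ = confusion_and_metrics(y_true, y_pred)
        order = rng.permutation(25)
        cm_b, _ = confusion_and_metrics(
            [y_true[i] for i in order], [y_pred[i] for i in order]
        )
        assert cm_a == cm_b
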