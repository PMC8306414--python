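"""The multinomial ABO classifier and its evaluation battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abokit.classify import (
    ABOGenotypeClassifier,
    binary_metrics,
    fit_abo_classifier,
    multiclass_metrics,
    pr_points,
    predict_probabilities,
    probability_pattern_table,
    roc_auc,
)
from abokit.data import BLOOD_TYPES


@pytest.fixture(scope="module")
def fitted_noiseless(noiseless_design):
    dosages, alleles, sero, gm = noiseless_design
    model = fit_abo_classifier(dosages, sero, snp_ids=list(gm.snp_ids))
    return model, dosages, sero


class TestClassifierFit:
    def test_noiseless_three_tag_model_is_perfect(self, fitted_noiseless):
        model, dosages, sero = fitted_noiseless
        pred = model.predict(dosages)
        assert np.mean(pred == sero) == 1.0

    def test_probabilities_sum_to_one(self, fitted_noiseless):
        model, dosages, _ = fitted_noiseless
        rng = np.random.default_rng(1)
        random_rows = rng.integers(0, 3, size=(1000, 3)).astype(float)
        proba = model.predict_proba(random_rows)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_missing_type_level_rejected(self):
        X = np.array([[0.0], [1], [2], [0]])
        with pytest.raises(ValueError, match="absent"):
            ABOGenotypeClassifier().fit(X, ["O", "A", "B", "O"])

    def test_zero_ridge_rejected(self):
        X = np.tile([[0.0], [1], [2], [1]], (10, 1))
        y = ["O", "A", "B", "AB"] * 10
        with pytest.raises(ValueError, match="ridge"):
            ABOGenotypeClassifier(ridge=0.0).fit(X, y)

    def test_single_o_tag_cannot_separate_a_from_b(self, noiseless_design):
        dosages, alleles, sero, gm = noiseless_design
        j = gm.snp_ids.index("rs8176719")
        model = fit_abo_classifier(dosages[:, [j]], sero)
        pred = set(model.predict(dosages[:, [j]]))
        # A and B are indistinguishable from the O tag alone: at most one of
        # them is ever predicted (the more prevalent of the two)
        assert not {"A", "B"} <= pred
        # for heterozygous-tag carriers, P(A)/P(B) tracks the prevalence
        # ratio of A and B among non-O training samples
        proba = model.predict_proba(np.array([[1.0]]))[0]
        ratio = proba[1] / proba[2]
        prev = model.prevalences_
        assert ratio == pytest.approx(prev["A"] / prev["B"], rel=0.3)

    def test_permuted_labels_give_prevalence_accuracy(self, noiseless_design):
        dosages, _, sero, _ = noiseless_design
        rng = np.random.default_rng(5)
        permuted = rng.permutation(sero)
        model = fit_abo_classifier(dosages, permuted)
        acc = np.mean(model.predict(dosages) == permuted)
        max_prev = max(model.prevalences_.values())
        assert acc == pytest.approx(max_prev, abs=0.05)

    def test_sklearn_api_compat(self, noiseless_design):
        from sklearn.base import clone

        dosages, _, sero, _ = noiseless_design
        model = ABOGenotypeClassifier(ridge=1e-3)
        assert clone(model).get_params()["ridge"] == 1e-3
        model.fit(dosages, sero)
        assert model.coef_.shape == (3, 3)
        assert list(model.classes_) == BLOOD_TYPES
        assert model.score(dosages, sero) == 1.0

    def test_nested_snp_sets_never_lose_training_accuracy(
        self, noiseless_design
    ):
        dosages, _, sero, gm = noiseless_design
        order = [gm.snp_ids.index(s)
                 for s in ("rs8176719", "rs635634", "rs7030248")]
        accs = []
        for k in (1, 2, 3):
            cols = order[:k]
            m = fit_abo_classifier(dosages[:, cols], sero)
            accs.append(np.mean(m.predict(dosages[:, cols]) == sero))
        assert accs[0] <= accs[1] <= accs[2]
        assert accs[2] == 1.0


class TestPredictProbabilities:
    def test_zero_coefficients_give_uniform_probabilities(self):
        model = ABOGenotypeClassifier()
        model.classes_ = np.array(BLOOD_TYPES, dtype=object)
        model.coef_ = np.zeros((3, 2))
        model.intercept_ = np.zeros(3)
        model.n_features_in_ = 2
        model.prevalences_ = {t: 0.25 for t in BLOOD_TYPES}
        model.training_combinations_ = set()
        proba = model.predict_proba(np.zeros((4, 2)))
        assert np.allclose(proba, 0.25)

    def test_unseen_combination_flagged_as_extrapolation(
        self, fitted_noiseless
    ):
        model, dosages, _ = fitted_noiseless
        seen = np.unique(dosages, axis=0)
        all27 = np.array(
            [[a, b, c] for a in (0.0, 1, 2) for b in (0.0, 1, 2)
             for c in (0.0, 1, 2)]
        )
        df = predict_probabilities(model, all27)
        seen_set = {tuple(r) for r in seen}
        expected = np.array([tuple(r) not in seen_set for r in all27])
        assert np.array_equal(df["extrapolated"].to_numpy(), expected)
        assert np.allclose(
            df[["pO", "pA", "pB", "pAB"]].sum(axis=1), 1.0, atol=1e-9
        )

    def test_missing_dosage_rejected(self, fitted_noiseless):
        model, _, _ = fitted_noiseless
        with pytest.raises(ValueError, match="missing"):
            model.predict_proba(np.array([[0.0, np.nan, 1.0]]))


class TestBinaryMetrics:
    def test_perfect_probabilities(self):
        truth = np.array([1, 1, 0, 0], bool)
        m = binary_metrics(truth.astype(float) * 0.98 + 0.01, truth, 0.5)
        for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv",
                  "f1"):
            assert m[k] == 1.0

    def test_constant_probability_at_threshold_predicts_all_positive(self):
        truth = np.array([1, 0, 1, 0], bool)
        m = binary_metrics(np.full(4, 0.4), truth, 0.4)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0

    def test_hand_computed_table(self):
        # TP=45 FN=5 FP=10 TN=40
        prob = np.concatenate(
            [np.ones(45), np.zeros(5), np.ones(10), np.zeros(40)]
        )
        truth = np.concatenate([np.ones(50), np.zeros(50)]).astype(bool)
        m = binary_metrics(prob, truth, 0.5)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(45 / 55)
        assert m["f1"] == pytest.approx(2 * (45 / 55) * 0.9 /
                                        ((45 / 55) + 0.9))

    def test_zero_denominator_reported_missing(self):
        truth = np.zeros(4, bool)  # no positives: sensitivity undefined
        m = binary_metrics(np.zeros(4), truth, 0.5)
        assert np.isnan(m["sensitivity"])
        assert np.isnan(m["ppv"])


class TestROC:
    def test_perfect_separation_auc_one(self):
        auc, curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert {"fpr", "tpr"} <= set(curve.columns)

    def test_null_scores_auc_half(self):
        rng = np.random.default_rng(3)
        prob = rng.random(2000)
        truth = rng.integers(0, 2, 2000)
        auc, _ = roc_auc(prob, truth)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_all_tied_scores_auc_exactly_half(self):
        auc, _ = roc_auc(np.full(10, 0.3), [1, 0] * 5)
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc([0.1, 0.9], [1, 1])

    def test_pr_points_shape(self):
        df = pr_points([0.9, 0.1, 0.8, 0.3], [1, 0, 1, 0])
        assert {"recall", "precision"} == set(df.columns)


class TestMulticlassMetrics:
    def test_perfect_assignment(self, fitted_noiseless):
        model, dosages, sero = fitted_noiseless
        report = multiclass_metrics(model.predict_proba(dosages), sero,
                                    model.prevalences_)
        assert report.accuracy == 1.0
        assert report.f1_micro == 1.0
        assert report.f1_macro == 1.0
        assert np.trace(report.confusion.to_numpy()) == len(sero)

    def test_constructed_confusion_matrix_oracle(self):
        # build probabilities that force a known confusion structure
        truth = np.array(
            ["O"] * 50 + ["A"] * 30 + ["B"] * 15 + ["AB"] * 5, dtype=object
        )
        pred = truth.copy()
        pred[:5] = "A"       # 5 O -> A
        pred[50:53] = "B"    # 3 A -> B
        proba = np.zeros((100, 4))
        for i, t in enumerate(pred):
            proba[i, BLOOD_TYPES.index(t)] = 1.0
        report = multiclass_metrics(proba, truth)
        assert report.accuracy == pytest.approx(0.92)
        conf = report.confusion
        assert conf.loc["O", "A"] == 5
        assert conf.loc["A", "B"] == 3
        assert conf.to_numpy().sum() == 100
        # hand-computed per-type F1 for O: TP=45, FN=5, FP=0
        ppv, sens = 1.0, 0.9
        assert report.per_type.loc["O", "f1"] == pytest.approx(
            2 * ppv * sens / (ppv + sens)
        )
        # micro F1 equals accuracy for single-label assignment
        assert report.f1_micro == pytest.approx(report.accuracy)
        report.validate()

    def test_confusion_rows_sum_to_truth_counts(self, fitted_noiseless):
        model, dosages, sero = fitted_noiseless
        report = multiclass_metrics(model.predict_proba(dosages), sero)
        truth_counts = pd.Series(sero).value_counts()
        for t in BLOOD_TYPES:
            assert report.confusion.loc[t].sum() == truth_counts[t]

    def test_majority_assignment_accuracy_equals_prevalence(self):
        truth = np.array(["O"] * 60 + ["A"] * 25 + ["B"] * 10 + ["AB"] * 5,
                         dtype=object)
        proba = np.tile([0.97, 0.01, 0.01, 0.01], (100, 1))
        report = multiclass_metrics(proba, truth)
        assert report.accuracy == pytest.approx(0.6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_f1_identities_hold(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        truth = rng.choice(np.array(BLOOD_TYPES, dtype=object), n,
                           p=[0.3, 0.3, 0.3, 0.1])
        proba = rng.dirichlet(np.ones(4), size=n)
        report = multiclass_metrics(proba, truth)
        report.validate()
        for t in BLOOD_TYPES:
            row = report.per_type.loc[t]
            if not (np.isnan(row["ppv"]) or np.isnan(row["sensitivity"])
                    or row["ppv"] + row["sensitivity"] == 0):
                assert row["f1"] == pytest.approx(
                    2 * row["ppv"] * row["sensitivity"]
                    / (row["ppv"] + row["sensitivity"])
                )
        # cross-check against scikit-learn's aggregation
        from sklearn.metrics import f1_score

        pred = np.array(BLOOD_TYPES, dtype=object)[np.argmax(proba, axis=1)]
        if len(set(truth) | set(pred)) == 4:
            assert report.f1_micro == pytest.approx(
                f1_score(truth, pred, average="micro")
            )


class TestPatternTable:
    def test_at_most_27_rows_for_three_snps(self, fitted_noiseless):
        model, dosages, _ = fitted_noiseless
        table = probability_pattern_table(model, dosages)
        assert len(table) <= 27
        assert table["count"].sum() == len(dosages)

    def test_noiseless_argmax_matches_mendelian_serotype(
        self, fitted_noiseless, noiseless_design
    ):
        model, dosages, sero = fitted_noiseless
        table = probability_pattern_table(model, dosages)
        truth_of_combo = {}
        for row, t in zip(dosages, sero):
            truth_of_combo[tuple(row)] = t
        snp_cols = table.columns[:3]
        for _, r in table.iterrows():
            combo = tuple(r[c] for c in snp_cols)
            assert r["predicted_type"] == truth_of_combo[combo]

    def test_single_snp_has_at_most_three_rows(self, noiseless_design):
        dosages, _, sero, _ = noiseless_design
        model = fit_abo_classifier(dosages[:, [0]], sero)
        table = probability_pattern_table(model, dosages[:, [0]])
        assert len(table) <= 3


class TestNoOABConfusion:
    def test_never_confuses_o_with_ab(self, fitted_noiseless):
        model, dosages, sero = fitted_noiseless
        report = multiclass_metrics(model.predict_proba(dosages), sero,
                                    model.prevalences_)
        assert report.confusion.loc["O", "AB"] == 0
        assert report.confusion.loc["AB", "O"] == 0
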