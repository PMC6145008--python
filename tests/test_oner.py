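"""One-R induction, Zero-R, prediction, metrics, cross-validation."""

import numpy as np
import pytest

from hrvc.multiscale_entropy import MCS_LABEL, UWS_LABEL
from hrvc.oner import (
    ClassificationReport,
    ClassifierError,
    CohortTable,
    OneRModel,
    SubjectRecord,
    cross_validate,
    discretize_attribute,
    evaluate,
    fit_oner,
    fit_zeror,
    predict,
    stratified_folds,
)
from hrvc.synthetic import generate_planted_cohort


def make_cohort(ci_s, ci_l, labels, crs=None):
    recs = tuple(
        SubjectRecord(
            subject_id=f"s{i:03d}",
            diagnosis=lab,
            crs_r_total=None if crs is None else crs[i],
            ci_s=float(s),
            ci_l=float(l),
        )
        for i, (s, l, lab) in enumerate(zip(ci_s, ci_l, labels))
    )
    return CohortTable(recs)


class TestDiscretize:
    def test_clean_split_puts_boundary_at_midpoint(self):
        boundaries, labels, err = discretize_attribute(
            [3.0, 3.5, 4.0, 5.0, 5.5, 6.0],
            [UWS_LABEL] * 3 + [MCS_LABEL] * 3,
            min_bucket=3,
        )
        assert boundaries == (4.5,)
        assert labels == (UWS_LABEL, MCS_LABEL)
        assert err == 0
        # exhaustive single-split search agrees: no split beats error 0
        assert err == min(
            sum(1 for v, l in zip([3.0, 3.5, 4.0, 5.0, 5.5, 6.0],
                                  [UWS_LABEL] * 3 + [MCS_LABEL] * 3)
                if (l == MCS_LABEL) != (v >= cut))
            for cut in np.arange(2.5, 7.0, 0.25)
        )

    def test_single_class_gives_single_bin(self):
        boundaries, labels, err = discretize_attribute(
            [1.0, 2.0, 3.0, 4.0], [MCS_LABEL] * 4, min_bucket=2
        )
        assert boundaries == ()
        assert labels == (MCS_LABEL,)
        assert err == 0

    def test_interleaved_labels_collapse_to_majority_bin(self):
        values = list(range(10))
        labels = [MCS_LABEL, UWS_LABEL] * 5
        boundaries, bin_labels, err = discretize_attribute(values, labels, min_bucket=10)
        assert boundaries == ()
        assert err == 5  # the minority count

    def test_equal_values_never_split(self):
        values = [1.0, 1.0, 1.0, 1.0, 2.0, 2.0]
        labels = [UWS_LABEL, UWS_LABEL, UWS_LABEL, MCS_LABEL, MCS_LABEL, MCS_LABEL]
        boundaries, _, _ = discretize_attribute(values, labels, min_bucket=2)
        assert all(b != 1.0 for b in boundaries)

    def test_too_few_values_rejected(self):
        with pytest.raises(ClassifierError):
            discretize_attribute([1.0], [MCS_LABEL], min_bucket=2)


class TestFitOneR:
    def test_selects_the_separating_feature(self, rng):
        n = 15
        ci_l = np.r_[rng.uniform(6, 8, n), rng.uniform(2, 4, n)]  # clean
        ci_s = rng.uniform(4, 6, 2 * n)  # overlapping
        labels = [MCS_LABEL] * n + [UWS_LABEL] * n
        model = fit_oner(make_cohort(ci_s, ci_l, labels))
        assert model.attribute == "ci_l"
        assert model.training_error == 0

    def test_symmetric_construction_selects_ci_s(self, rng):
        n = 15
        ci_s = np.r_[rng.uniform(6, 8, n), rng.uniform(2, 4, n)]
        ci_l = rng.uniform(4, 6, 2 * n)
        labels = [MCS_LABEL] * n + [UWS_LABEL] * n
        assert fit_oner(make_cohort(ci_s, ci_l, labels)).attribute == "ci_s"

    def test_identical_columns_tie_break_by_feature_order(self, rng):
        n = 10
        vals = np.r_[rng.uniform(6, 8, n), rng.uniform(2, 4, n)]
        labels = [MCS_LABEL] * n + [UWS_LABEL] * n
        assert fit_oner(make_cohort(vals, vals, labels)).attribute == "ci_s"

    def test_single_class_cohort_degenerate(self):
        model = fit_oner(make_cohort([1, 2, 3], [1, 2, 3], [MCS_LABEL] * 3))
        assert model.degenerate
        assert predict(model, 99.0) == MCS_LABEL

    def test_oner_never_worse_than_zeror_in_training(self, rng):
        for _ in range(20):
            n = int(rng.integers(12, 40))
            labels = [MCS_LABEL if rng.random() < 0.5 else UWS_LABEL for _ in range(n)]
            if len(set(labels)) < 2:
                continue
            cohort = make_cohort(rng.normal(size=n), rng.normal(size=n), labels)
            assert fit_oner(cohort).training_error <= fit_zeror(cohort).training_error


class TestZeroR:
    @pytest.mark.parametrize(
        "n_mcs, n_uws, expected",
        [(16, 14, MCS_LABEL), (14, 16, UWS_LABEL), (15, 15, MCS_LABEL)],
    )
    def test_majority_with_tie_toward_mcs(self, n_mcs, n_uws, expected):
        labels = [MCS_LABEL] * n_mcs + [UWS_LABEL] * n_uws
        cohort = make_cohort(np.zeros(len(labels)), np.zeros(len(labels)), labels)
        model = fit_zeror(cohort)
        assert model.bin_labels == (expected,)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ClassifierError):
            fit_zeror(CohortTable(()))


class TestPredict:
    model = OneRModel("ci_l", (4.876,), (UWS_LABEL, MCS_LABEL), 0, 6)

    @pytest.mark.parametrize(
        "value, expected", [(5.0, MCS_LABEL), (4.876, MCS_LABEL), (1.0, UWS_LABEL)]
    )
    def test_boundary_goes_to_upper_bin(self, value, expected):
        assert predict(self.model, value) == expected

    def test_missing_value_rejected(self):
        with pytest.raises(ClassifierError):
            predict(self.model, float("nan"))


class TestEvaluate:
    def test_reference_full_training_panel(self):
        # 16 MCS of which 15 correct, 14 UWS of which 13 correct
        rep = ClassificationReport(tp=15, fn=1, fp=1, tn=13)
        d = rep.as_dict(rounded=True)
        assert d["accuracy"] == 93
        assert d["f1"] == 94
        assert d["mcc"] == 0.87
        assert d["precision_uws"] == 93
        assert rep.fpr == pytest.approx(1 - rep.specificity)
        assert rep.fnr == pytest.approx(1 - rep.sensitivity)

    def test_reference_holdout_panel(self):
        # 11 MCS / 10 UWS, zero false positives, one false negative
        d = ClassificationReport(tp=10, fn=1, fp=0, tn=10).as_dict(rounded=True)
        assert d["accuracy"] == 95
        assert d["mcc"] == 0.91
        assert d["precision_uws"] == 91

    def test_perfect_predictions(self):
        truth = [MCS_LABEL] * 16 + [UWS_LABEL] * 14
        rep = evaluate(truth, truth)
        assert rep.accuracy == 1.0 and rep.f1 == 1.0 and rep.mcc == 1.0

    def test_constant_mcs_prediction_scores_prevalence(self):
        truth = [MCS_LABEL] * 16 + [UWS_LABEL] * 14
        rep = evaluate([MCS_LABEL] * 30, truth)
        assert rep.as_dict(rounded=True)["accuracy"] == 53
        assert rep.mcc == 0.0 and rep.mcc_undefined

    def test_counts_partition_truth(self, rng):
        truth = [MCS_LABEL if rng.random() < 0.6 else UWS_LABEL for _ in range(50)]
        pred = [MCS_LABEL if rng.random() < 0.5 else UWS_LABEL for _ in range(50)]
        rep = evaluate(pred, truth)
        assert rep.tp + rep.fn == truth.count(MCS_LABEL)
        assert rep.tn + rep.fp == truth.count(UWS_LABEL)

    def test_metrics_match_sklearn(self, rng):
        from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef

        truth = rng.choice([MCS_LABEL, UWS_LABEL], size=60, p=[0.55, 0.45])
        pred = rng.choice([MCS_LABEL, UWS_LABEL], size=60)
        rep = evaluate(pred, truth)
        assert rep.accuracy == pytest.approx(accuracy_score(truth, pred))
        assert rep.f1 == pytest.approx(f1_score(truth, pred, pos_label=MCS_LABEL))
        assert rep.mcc == pytest.approx(matthews_corrcoef(truth, pred))

    def test_unknown_label_rejected(self):
        with pytest.raises(ClassifierError):
            evaluate(["EMCS"], [MCS_LABEL])


class TestCrossValidation:
    def test_folds_partition_and_balance(self):
        labels = [MCS_LABEL] * 16 + [UWS_LABEL] * 14
        folds = stratified_folds(labels, k=10, seed=3)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds)) == list(range(30))

    def test_separable_cohort_scores_perfectly(self):
        cohort = generate_planted_cohort(seed=4)
        pooled, fold_reports = cross_validate(cohort, k=10, seed=4)
        assert pooled.accuracy == 1.0
        assert sum(r.n for r in fold_reports) == len(cohort)

    def test_same_seed_reproduces_byte_identical_reports(self):
        cohort = generate_planted_cohort(seed=8)
        a = cross_validate(cohort, k=10, seed=12)
        b = cross_validate(cohort, k=10, seed=12)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_null_labels_score_near_prevalence(self, rng):
        n = 300
        labels = list(rng.permutation([MCS_LABEL] * 150 + [UWS_LABEL] * 150))
        cohort = make_cohort(rng.normal(size=n), rng.normal(size=n), labels)
        pooled, _ = cross_validate(cohort, k=10, seed=0)
        se = np.sqrt(0.25 / n)
        assert abs(pooled.accuracy - 0.5) < 3 * se + 0.05

    def test_invalid_k_rejected(self):
        cohort = generate_planted_cohort(seed=0)
        with pytest.raises(ClassifierError):
            cross_validate(cohort, k=1)
        with pytest.raises(ClassifierError):
            cross_validate(cohort, k=31)
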