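import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octavd.experiment import (
    METHODS,
    CVResult,
    LeakageError,
    SVMConfig,
    assert_no_leakage,
    auroc,
    classification_metrics,
    cross_validate_method,
    default_grid,
    grouped_kfold,
    grouped_split,
    run_full_experiment,
)
from octavd.synth import generate_cohort

from conftest import small_config


def brute_force_auroc(scores, labels):
    """Independent oracle: exhaustive positive-negative pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def single_eye_records(n, labels=None):
    class _Rec:
        def __init__(self, pid, label):
            self.patient_id = pid
            self.label = label

    if labels is None:
        labels = ["healthy" if i % 2 else "glaucoma" for i in range(n)]
    return [_Rec(f"P{i:03d}", labels[i]) for i in range(n)]


class TestGroupedSplit:
    def test_exact_divisibility_100_patients(self):
        eyes = single_eye_records(100)
        split = grouped_split(eyes, seed=0)
        sizes = {s: len(split.patients(s)) for s in ("train", "validation", "test")}
        assert sizes == {"train": 60, "validation": 20, "test": 20}

    def test_determinism(self):
        eyes = single_eye_records(40)
        a = grouped_split(eyes, seed=5)
        b = grouped_split(eyes, seed=5)
        assert a.assignment == b.assignment

    def test_two_eye_patients_stay_together(self, tiny_cohort):
        split = grouped_split(tiny_cohort, seed=1)
        for rec in tiny_cohort:
            assert split.set_of(rec.patient_id) in ("train", "validation", "test")
        # trivially true by construction (patient-level mapping); check each
        # patient has exactly one assignment entry
        patients = {r.patient_id for r in tiny_cohort}
        assert set(split.assignment) == patients

    def test_each_set_contains_both_classes(self):
        eyes = single_eye_records(30)
        split = grouped_split(eyes, seed=2)
        by_label = {r.patient_id: r.label for r in eyes}
        for s in ("train", "validation", "test"):
            assert {by_label[p] for p in split.patients(s)} == {"healthy", "glaucoma"}

    def test_too_small_cohort_rejected(self):
        eyes = single_eye_records(4, labels=["healthy", "healthy", "glaucoma", "healthy"])
        with pytest.raises(ValueError):
            grouped_split(eyes, seed=0)

    def test_conflicting_patient_labels_rejected(self):
        eyes = single_eye_records(10)
        eyes[1].patient_id = eyes[0].patient_id  # same patient, both labels
        with pytest.raises(ValueError):
            grouped_split(eyes, seed=0)


class TestGroupedKFold:
    def test_partition_covers_all_patients(self):
        labels = {f"P{i}": "healthy" if i % 2 else "glaucoma" for i in range(23)}
        folds = grouped_kfold(labels, k=5, seed=0)
        flat = [p for f in folds for p in f]
        assert sorted(flat) == sorted(labels)
        assert len(set(flat)) == len(flat)

    def test_stratification(self):
        labels = {f"P{i}": "healthy" if i < 20 else "glaucoma" for i in range(40)}
        folds = grouped_kfold(labels, k=10, seed=1)
        for fold in folds:
            classes = {labels[p] for p in fold}
            assert classes == {"healthy", "glaucoma"}

    def test_leakage_guard_fires(self):
        eyes = single_eye_records(20)
        split = grouped_split(eyes, seed=0)
        dev = split.patients("train") + split.patients("validation")
        good_folds = [dev[i::5] for i in range(5)]
        assert_no_leakage(split, good_folds, eyes)
        bad = [list(f) for f in good_folds]
        bad[0].append(split.patients("test")[0])
        with pytest.raises(LeakageError):
            assert_no_leakage(split, bad, eyes)
        dup = [list(f) for f in good_folds]
        dup[1].append(dup[0][0])
        with pytest.raises(LeakageError):
            assert_no_leakage(split, dup, eyes)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert auroc(scores, labels) == 0.75
        assert auroc(scores, labels) == brute_force_auroc(scores, labels)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        # quantized scores so ties actually occur
        scores = rng.integers(0, 6, size=n).astype(float) / 5.0
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        base = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
        assert auroc(3 * scores + 7, labels) == pytest.approx(base, abs=1e-12)


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        truth = np.array([0, 1, 0, 1])
        assert classification_metrics(truth, truth) == (1.0, 1.0, 1.0)

    def test_all_positive_prediction(self):
        truth = np.array([0, 1, 0, 1])
        sens, spec, _ = classification_metrics(np.ones(4, int), truth)
        assert sens == 1.0 and spec == 0.0

    def test_worked_confusion_matrix(self):
        # TP=3 FN=1 TN=4 FP=2
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
        sens, spec, f1 = classification_metrics(pred, truth)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(2 / 3)
        assert f1 == pytest.approx(6 / 9)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.ones(4, int), np.ones(4, int))


class TestSVMConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SVMConfig(kernel="poly", degree=1)
        with pytest.raises(ValueError):
            SVMConfig(c=0.0)
        with pytest.raises(ValueError):
            SVMConfig(kernel="quantum")

    def test_default_grid_covers_all_kernels(self):
        kernels = {c.kernel for c in default_grid()}
        assert kernels == {"linear", "poly", "rbf", "sigmoid"}


def _synthetic_feature_problem(n_patients=60, d=6, effect=0.0, seed=0):
    """Feature-level problem (no images) for fast CV protocol tests."""
    rng = np.random.default_rng(seed)
    eyes = single_eye_records(n_patients)
    y = np.array([1 if r.label == "glaucoma" else 0 for r in eyes])
    X = rng.normal(size=(n_patients, d))
    X[:, 0] += effect * y
    patient_ids = [r.patient_id for r in eyes]
    return eyes, X, y, patient_ids


class TestCrossValidateMethod:
    def test_single_config_grid_selected(self):
        eyes, X, y, pids = _synthetic_feature_problem(seed=1)
        split = grouped_split(eyes, seed=1)
        only = SVMConfig(kernel="linear", c=1.0)
        cv = cross_validate_method(X, y, pids, split, grid=[only], k=5, seed=1)
        assert cv.selected_config == only
        assert cv.k == 5

    def test_separable_coordinate_reaches_auroc_one(self):
        eyes, X, y, pids = _synthetic_feature_problem(effect=50.0, seed=2)
        split = grouped_split(eyes, seed=2)
        cv = cross_validate_method(X, y, pids, split, k=5, seed=2)
        assert np.all(cv.fold_auroc == 1.0)

    def test_label_permutation_null(self):
        """Permutation null: mean validation AUROC within 3 SD of 0.5."""
        means = []
        for seed in range(20):
            eyes, X, y, pids = _synthetic_feature_problem(seed=seed)
            rng = np.random.default_rng(seed)
            y_perm = rng.permutation(y)
            # permuted labels must still be patient-constant: single-eye
            # patients make this trivially true
            split = grouped_split(eyes, seed=seed)
            grid = [SVMConfig(kernel="linear", c=1.0),
                    SVMConfig(kernel="rbf", c=1.0)]
            cv = cross_validate_method(X, y_perm, pids, split, grid=grid,
                                       k=5, seed=seed)
            means.append(cv.fold_auroc.mean())
        means = np.asarray(means)
        assert abs(means.mean() - 0.5) <= 3 * means.std(ddof=1)

    def test_metrics_within_unit_interval(self):
        eyes, X, y, pids = _synthetic_feature_problem(effect=1.0, seed=3)
        split = grouped_split(eyes, seed=3)
        cv = cross_validate_method(X, y, pids, split, k=5, seed=3)
        for arr in (cv.fold_auroc, cv.fold_sensitivity,
                    cv.fold_specificity, cv.fold_f1):
            assert arr.min() >= 0.0 and arr.max() <= 1.0
        assert set(cv.test_metrics) == {"auroc", "sensitivity", "specificity", "f1"}

    def test_empty_grid_rejected(self):
        eyes, X, y, pids = _synthetic_feature_problem(seed=4)
        split = grouped_split(eyes, seed=4)
        with pytest.raises(ValueError):
            cross_validate_method(X, y, pids, split, grid=[], k=5, seed=4)


@pytest.fixture(scope="module")
def experiment_result():
    cfg = small_config(n_patients=30, two_eye_fraction=0.5,
                       dropout_para=0.1, dropout_peri=0.45, seed=13)
    cohort = generate_cohort(cfg)
    return cohort, run_full_experiment(cohort, k=5, seed=13)


class TestRunFullExperiment:
    def test_six_methods_and_shared_folds(self, experiment_result):
        _, res = experiment_result
        assert set(res.results) == set(METHODS)
        ks = {res.results[m].k for m in METHODS}
        assert ks == {5}

    def test_pairwise_table_has_fifteen_pairs(self, experiment_result):
        _, res = experiment_result
        assert res.pairwise.n_pairs == 15

    def test_no_leakage_structurally(self, experiment_result):
        cohort, res = experiment_result
        sets = {res.split.set_of(r.patient_id) for r in cohort}
        assert sets == {"train", "validation", "test"}
        per_patient_sets = {}
        for rec in cohort:
            per_patient_sets.setdefault(rec.patient_id, set()).add(
                res.split.set_of(rec.patient_id))
        assert all(len(s) == 1 for s in per_patient_sets.values())

    def test_reproducible_manifest(self, experiment_result):
        from octavd.experiment import manifest_json

        cohort, res = experiment_result
        res2 = run_full_experiment(cohort, k=5, seed=13)
        assert manifest_json(res) == manifest_json(res2)
        for m in METHODS:
            assert np.array_equal(res.results[m].fold_auroc,
                                  res2.results[m].fold_auroc)

    def test_missing_plexus_rejected(self, tiny_cohort):
        class _Partial:
            patient_id = "PX"
            eye = "OD"
            label = "healthy"
            images = {"SVP": tiny_cohort[0].images["SVP"]}

        with pytest.raises(ValueError):
            run_full_experiment([_Partial()], k=2, seed=0)

    def test_summary_table_shape(self, experiment_result):
        _, res = experiment_result
        table = res.summary_table()
        assert len(table) == 6
        assert "auroc_mean" in table.columns
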