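"""Patient-grouped SVM model selection and evaluation.

Protocol: eyes are split 60/20/20 into train/validation/test at the patient
level (all eyes of a patient stay together).  The 20% test set is withheld;
10 patient-grouped, class-stratified folds are formed over the remaining 80%
so that each fold trains on ~60% and validates on ~20% of the whole cohort.
Every hyperparameter configuration is scored by its mean validation-fold
AUROC; the arg-max configuration is refit on all non-test data and evaluated
once on the test set.  Six methods (three plexuses x two zones) share one
split and one fold partition so their per-fold AUROCs are comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .regions import ZONES, extract_features, layout_for_image
from .stats import PairwiseTable, posthoc_bonferroni
from .synth import PLEXUSES, EyeRecord

__all__ = [
    "SplitAssignment",
    "SVMConfig",
    "CVResult",
    "ExperimentResult",
    "grouped_split",
    "grouped_kfold",
    "auroc",
    "classification_metrics",
    "default_grid",
    "cross_validate_method",
    "run_full_experiment",
]

POSITIVE_LABEL = "glaucoma"
SETS = ("train", "validation", "test")
METHODS = tuple(f"{p}_{z}" for p in PLEXUSES for z in ZONES)


class LeakageError(AssertionError):
    """A patient's eyes crossed a set or fold boundary."""


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitAssignment:
    """Patient-level train/validation/test assignment."""

    assignment: dict[str, str]  # patient_id -> set name
    seed: int

    def patients(self, set_name: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == set_name)

    def set_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]


def _patients_by_class(eyes: list[EyeRecord]):
    """(patient -> label, patient -> eye count), validating consistency."""
    label_of: dict[str, str] = {}
    eye_count: dict[str, int] = {}
    for eye in eyes:
        prev = label_of.setdefault(eye.patient_id, eye.label)
        if prev != eye.label:
            raise ValueError(f"patient {eye.patient_id} has conflicting labels")
        eye_count[eye.patient_id] = eye_count.get(eye.patient_id, 0) + 1
        if eye_count[eye.patient_id] > 2:
            raise ValueError(f"patient {eye.patient_id} has more than 2 eyes")
    return label_of, eye_count


def grouped_split(eyes: list[EyeRecord],
                  ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> SplitAssignment:
    """Assign whole patients to train/validation/test, stratified by class.

    Within each class, patients are shuffled deterministically and assigned
    so that cumulative eye counts approximate the requested ratios.
    """
    if len(ratios) != 3 or abs(sum(ratios) - 1.0) > 1e-9 or min(ratios) <= 0:
        raise ValueError("ratios must be three positive numbers summing to 1")
    label_of, eye_count = _patients_by_class(eyes)
    classes = sorted(set(label_of.values()))
    for cls in classes:
        if sum(1 for p in label_of if label_of[p] == cls) < 3:
            raise ValueError(
                f"need >= 3 patients per class to fill all sets, class {cls!r} is short")

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in classes:
        patients = sorted(p for p in label_of if label_of[p] == cls)
        rng.shuffle(patients)
        total = sum(eye_count[p] for p in patients)
        b1 = ratios[0] * total
        b2 = (ratios[0] + ratios[1]) * total
        cum = 0
        for p in patients:
            if cum < b1:
                assignment[p] = "train"
            elif cum < b2:
                assignment[p] = "validation"
            else:
                assignment[p] = "test"
            cum += eye_count[p]
    split = SplitAssignment(assignment=assignment, seed=seed)
    for set_name in SETS:
        present = {label_of[p] for p in split.patients(set_name)}
        if len(present) < len(classes):
            raise ValueError(
                f"cohort too small/imbalanced: set {set_name!r} lacks a class")
    return split


def grouped_kfold(patient_labels: dict[str, str], k: int, seed: int = 0
                  ) -> list[list[str]]:
    """Deal patients into ``k`` folds, class-stratified, deterministically."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for cls in sorted(set(patient_labels.values())):
        patients = sorted(p for p, c in patient_labels.items() if c == cls)
        rng.shuffle(patients)
        for i, p in enumerate(patients):
            folds[(i + offset) % k].append(p)
        offset += len(patients)
    if any(len(f) == 0 for f in folds):
        raise ValueError(f"too few patients ({len(patient_labels)}) for {k} folds")
    return folds


def assert_no_leakage(split: SplitAssignment, folds: list[list[str]],
                      eyes: list[EyeRecord]) -> None:
    """Structural guard: every patient lives in exactly one set and fold."""
    for eye in eyes:
        if eye.patient_id not in split.assignment:
            raise LeakageError(f"patient {eye.patient_id} missing from the split")
    dev = set(split.patients("train")) | set(split.patients("validation"))
    seen: set[str] = set()
    for fold in folds:
        for p in fold:
            if p in seen:
                raise LeakageError(f"patient {p} appears in more than one fold")
            if p not in dev:
                raise LeakageError(f"test patient {p} leaked into the folds")
            seen.add(p)
    if seen != dev:
        raise LeakageError("fold partition does not cover all non-test patients")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Equals the probability that a random positive outranks a random
    negative, with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(predicted, truth) -> tuple[float, float, float]:
    """(sensitivity, specificity, F1) with the positive class coded 1."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if set(np.unique(truth)) != {0, 1}:
        raise ValueError("truth must contain both classes (coded 0/1)")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return sensitivity, specificity, f1


# ---------------------------------------------------------------------------
# SVM configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVMConfig:
    """One support-vector-machine hyperparameter configuration."""

    kernel: str = "rbf"
    c: float = 1.0
    degree: int = 3
    gamma: float | str = "scale"
    coef0: float = 0.0
    scale_features: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "poly", "rbf", "sigmoid"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if not (self.c > 0):
            raise ValueError("regularization strength c must be positive")
        if self.kernel == "poly" and self.degree < 2:
            raise ValueError("polynomial degree must be >= 2")

    def build(self):
        svc = SVC(kernel=self.kernel, C=self.c, degree=self.degree,
                  gamma=self.gamma, coef0=self.coef0)
        if self.scale_features:
            return make_pipeline(StandardScaler(), svc)
        return make_pipeline(svc)

    def describe(self) -> dict:
        return {"kernel": self.kernel, "C": self.c, "degree": self.degree,
                "gamma": self.gamma, "coef0": self.coef0,
                "scale_features": self.scale_features}


def default_grid() -> list[SVMConfig]:
    """Default hyperparameter grid over all four kernels.

    Log-spaced regularization; polynomial degrees 2-3; the kernel
    coefficient uses scikit-learn's ``scale`` heuristic.  Feature
    standardization is fit on training folds only (inside the pipeline).
    """
    grid: list[SVMConfig] = []
    for c in (0.01, 0.1, 1.0, 10.0, 100.0):
        grid.append(SVMConfig(kernel="linear", c=c))
        grid.append(SVMConfig(kernel="rbf", c=c))
        grid.append(SVMConfig(kernel="sigmoid", c=c))
        for degree in (2, 3):
            grid.append(SVMConfig(kernel="poly", c=c, degree=degree))
    return grid


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVResult:
    """Per-fold metrics of the winning configuration for one method."""

    method: str
    fold_auroc: np.ndarray
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray
    fold_f1: np.ndarray
    selected_config: SVMConfig
    grid_mean_auroc: dict[int, float] = field(repr=False, default_factory=dict)
    test_metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fold_auroc", "fold_sensitivity",
                     "fold_specificity", "fold_f1"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ValueError(f"{name} values must lie in [0, 1]")
            object.__setattr__(self, name, arr)

    @property
    def k(self) -> int:
        return len(self.fold_auroc)

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for metric, arr in (("auroc", self.fold_auroc),
                            ("sensitivity", self.fold_sensitivity),
                            ("specificity", self.fold_specificity),
                            ("f1", self.fold_f1)):
            out[f"{metric}_mean"] = float(arr.mean())
            out[f"{metric}_sd"] = float(arr.std(ddof=1))
        return out


def _eval_config(config: SVMConfig, X, y, train_idx, val_idx):
    model = config.build()
    model.fit(X[train_idx], y[train_idx])
    scores = model.decision_function(X[val_idx])
    return scores, (scores > 0).astype(int)


def cross_validate_method(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: list[str],
    split: SplitAssignment,
    grid: list[SVMConfig] | None = None,
    k: int = 10,
    seed: int = 0,
    folds: list[list[str]] | None = None,
    method: str = "method",
) -> CVResult:
    """Model selection by mean validation AUROC plus held-out test metrics.

    ``X`` rows are eyes, ``y`` is 0/1 (1 = positive class), ``patient_ids``
    maps rows to patients.  The test rows (per ``split``) never participate
    in fold training or selection; the winning configuration is refit on all
    non-test rows and evaluated once on them.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)

    set_of = np.array([split.set_of(p) for p in patient_ids])
    dev_mask = set_of != "test"
    dev_idx = np.flatnonzero(dev_mask)
    test_idx = np.flatnonzero(~dev_mask)

    if folds is None:
        dev_labels = {p: int(yy) for p, yy in zip(patient_ids, y)
                      if split.set_of(p) != "test"}
        folds = grouped_kfold({p: str(c) for p, c in dev_labels.items()}, k, seed)
    if len(folds) != k:
        raise ValueError(f"expected {k} folds, got {len(folds)}")

    fold_sets = [set(f) for f in folds]
    fold_val_idx = []
    for fs in fold_sets:
        val = np.array([i for i in dev_idx if patient_ids[i] in fs])
        train = np.array([i for i in dev_idx if patient_ids[i] not in fs])
        if len(set(y[val])) < 2 or len(set(y[train])) < 2:
            raise ValueError(
                "cohort too small or imbalanced: a fold contains a single "
                "class, AUROC is undefined")
        fold_val_idx.append((train, val))

    grid_mean: dict[int, float] = {}
    per_config_folds: list[list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = []
    for ci, config in enumerate(grid):
        fold_records = []
        aurocs = []
        for train, val in fold_val_idx:
            scores, preds = _eval_config(config, X, y, train, val)
            fold_records.append((scores, preds, y[val]))
            aurocs.append(auroc(scores, y[val]))
        grid_mean[ci] = float(np.mean(aurocs))
        per_config_folds.append(fold_records)

    best = max(range(len(grid)), key=lambda ci: (grid_mean[ci], -ci))
    winner = grid[best]

    fold_auroc, fold_sens, fold_spec, fold_f1 = [], [], [], []
    for scores, preds, truth in per_config_folds[best]:
        fold_auroc.append(auroc(scores, truth))
        s, sp, f1 = classification_metrics(preds, truth)
        fold_sens.append(s)
        fold_spec.append(sp)
        fold_f1.append(f1)

    test_metrics: dict[str, float] = {}
    if len(test_idx) and len(set(y[test_idx])) == 2:
        model = winner.build()
        model.fit(X[dev_idx], y[dev_idx])
        scores = model.decision_function(X[test_idx])
        preds = (scores > 0).astype(int)
        s, sp, f1 = classification_metrics(preds, y[test_idx])
        test_metrics = {"auroc": auroc(scores, y[test_idx]),
                        "sensitivity": s, "specificity": sp, "f1": f1}

    return CVResult(method=method, fold_auroc=np.array(fold_auroc),
                    fold_sensitivity=np.array(fold_sens),
                    fold_specificity=np.array(fold_spec),
                    fold_f1=np.array(fold_f1), selected_config=winner,
                    grid_mean_auroc=grid_mean, test_metrics=test_metrics)


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentResult:
    results: dict[str, CVResult]
    pairwise: PairwiseTable
    split: SplitAssignment
    manifest: dict

    def summary_table(self):
        import pandas as pd

        rows = []
        for method in METHODS:
            cv = self.results[method]
            s = cv.summary()
            rows.append({"method": method, **s,
                         **{f"test_{m}": v for m, v in cv.test_metrics.items()}})
        return pd.DataFrame(rows)


def run_full_experiment(
    cohort: list[EyeRecord],
    grid: list[SVMConfig] | None = None,
    k: int = 10,
    seed: int = 0,
    vessel_params=None,
    layout_kwargs: dict | None = None,
) -> ExperimentResult:
    """Evaluate all six (plexus x zone) methods on one shared split.

    All methods use identical train/validation/test assignment and fold
    partitions so their per-fold AUROCs are directly comparable; the
    pairwise table compares the six methods' fold AUROCs with a one-way
    ANOVA and Bonferroni-corrected post-hoc tests.
    """
    if grid is None:
        grid = default_grid()
    for eye in cohort:
        missing = [p for p in PLEXUSES if p not in eye.images]
        if missing:
            raise ValueError(
                f"eye {eye.patient_id}/{eye.eye} lacks plexus images: {missing}")

    layout = layout_for_image(next(iter(cohort[0].images.values())),
                              **(layout_kwargs or {}))
    features = {m: [] for m in METHODS}
    y = np.array([1 if eye.label == POSITIVE_LABEL else 0 for eye in cohort])
    patient_ids = [eye.patient_id for eye in cohort]
    for eye in cohort:
        fv = extract_features(eye, layout, vessel_params)
        for (plexus, zone), vec in fv.items():
            features[f"{plexus}_{zone}"].append(vec.values)

    split = grouped_split(cohort, seed=seed)
    dev_labels = {eye.patient_id: eye.label for eye in cohort
                  if split.set_of(eye.patient_id) != "test"}
    folds = grouped_kfold(dev_labels, k, seed)
    assert_no_leakage(split, folds, cohort)

    results: dict[str, CVResult] = {}
    for method in METHODS:
        X = np.vstack(features[method])
        results[method] = cross_validate_method(
            X, y, patient_ids, split, grid=grid, k=k, seed=seed,
            folds=folds, method=method)

    pairwise = posthoc_bonferroni(
        [results[m].fold_auroc for m in METHODS], names=list(METHODS))

    manifest = {
        "seed": seed,
        "k_folds": k,
        "n_eyes": len(cohort),
        "n_patients": len({e.patient_id for e in cohort}),
        "selection_rule": "max mean validation-fold AUROC",
        "fold_metrics_source": "validation folds of the winning config",
        "grid": [c.describe() for c in grid],
        "split": {p: split.set_of(p) for p in sorted(split.assignment)},
        "winning_configs": {m: results[m].selected_config.describe()
                            for m in METHODS},
        "mean_val_auroc": {m: float(results[m].fold_auroc.mean())
                           for m in METHODS},
    }
    return ExperimentResult(results=results, pairwise=pairwise, split=split,
                            manifest=manifest)


def manifest_json(result: ExperimentResult) -> str:
    """Deterministic JSON rendering of a run manifest."""
    return json.dumps(result.manifest, indent=2, sort_keys=True)
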