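"""Split-half linear-SVM harness with repeated-permutation statistics.

Each repeat makes one stratified half-split of the cohort, trains a
linear SVM on each half, classifies the other half, and scores the
percentage of all subjects correctly assigned. Repeating over fresh
seeded splits yields an accuracy distribution per feature condition
(e.g. age-corrected vs uncorrected), compared by t-test. The ages of
misclassified subjects are compared between true groups to expose
age-driven misclassification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateSplit, InsufficientMisclassifications

__all__ = [
    "ClassificationResult",
    "AccuracyDistribution",
    "AccuracyComparison",
    "MisclassifiedAgeTest",
    "stratified_half_split",
    "split_half_svm",
    "permutation_accuracy",
    "misclassified_age_test",
]

DEFAULT_C = 1.0
DEFAULT_REPEATS = 60


@dataclass
class ClassificationResult:
    predictions: np.ndarray  # per-subject predicted label (from held-out fold)
    labels: np.ndarray  # true labels, same order
    fold: np.ndarray  # 0/1 half assignment per subject
    accuracy: float  # percent of all subjects correct across both folds
    seed: int

    @property
    def correct(self) -> np.ndarray:
        return self.predictions == self.labels


@dataclass
class AccuracyDistribution:
    accuracies: np.ndarray  # percent, one per repeat
    condition: str

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())


@dataclass
class AccuracyComparison:
    """Independent-samples t between two repeat-level accuracy distributions."""

    t: float
    p_two_tailed: float
    p_one_tailed_b_greater: float
    paired_t: float
    paired_p_two_tailed: float


@dataclass
class MisclassifiedAgeTest:
    t: float
    p_one_tailed: float  # direction: misclassified controls older
    mean_age_misclassified_controls: float
    mean_age_misclassified_patients: float
    n_misclassified_controls: int
    n_misclassified_patients: int


def stratified_half_split(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """0/1 fold per subject; per-class counts differ by at most one."""
    labels = np.asarray(labels)
    fold = np.zeros(len(labels), dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise DegenerateSplit(f"class {cls!r} has < 2 subjects")
        idx = rng.permutation(idx)
        cut = len(idx) - len(idx) // 2
        fold[idx[cut:]] = 1
    return fold


def split_half_svm(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    C: float = DEFAULT_C,
    standardize: bool = False,
) -> ClassificationResult:
    """One seeded stratified half-split, linear SVM both ways.

    Trains on each half and predicts the other, so every subject is
    predicted exactly once while held out; accuracy is the percentage of
    all subjects correctly assigned across both fold directions.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    if features.shape[0] != len(labels):
        raise ValueError("features and labels must be aligned")
    rng = np.random.default_rng(seed)
    fold = stratified_half_split(labels, rng)
    predictions = np.empty(len(labels), dtype=labels.dtype)
    for train_fold in (0, 1):
        train = fold == train_fold
        test = ~train
        if len(np.unique(labels[train])) < 2:
            raise DegenerateSplit("a training half lacks a class")
        X_train, X_test = features[train], features[test]
        if standardize:
            scaler = StandardScaler().fit(X_train)
            X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
        clf = SVC(kernel="linear", C=C)
        clf.fit(X_train, labels[train])
        predictions[test] = clf.predict(X_test)
    accuracy = float((predictions == labels).mean() * 100.0)
    return ClassificationResult(predictions, labels, fold, accuracy, seed)


def permutation_accuracy(
    features_a: np.ndarray,
    features_b: np.ndarray,
    labels: np.ndarray,
    n_repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    C: float = DEFAULT_C,
    standardize: bool = False,
    condition_a: str = "uncorrected",
    condition_b: str = "corrected",
) -> tuple[AccuracyDistribution, AccuracyDistribution, AccuracyComparison]:
    """Repeat the split-half procedure with fresh splits, both conditions.

    Repeat r uses seed ``seed + r``, and the identical split is applied to
    both feature sets so conditions differ only in the features. Returns
    the two accuracy distributions and their comparison (independent
    two-sample t as the primary statistic; a paired t is also reported
    since splits are shared).
    """
    features_a = np.asarray(features_a, dtype=np.float64)
    features_b = np.asarray(features_b, dtype=np.float64)
    if features_a.shape[0] != features_b.shape[0]:
        raise ValueError("both feature sets must describe the same subjects")
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    acc_a = np.empty(n_repeats)
    acc_b = np.empty(n_repeats)
    for r in range(n_repeats):
        rep_seed = seed + r
        acc_a[r] = split_half_svm(features_a, labels, rep_seed, C, standardize).accuracy
        acc_b[r] = split_half_svm(features_b, labels, rep_seed, C, standardize).accuracy
    dist_a = AccuracyDistribution(acc_a, condition_a)
    dist_b = AccuracyDistribution(acc_b, condition_b)

    if np.allclose(acc_a, acc_b):
        t, p = 0.0, 1.0
        pt, pp = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(acc_a, acc_b)
        pt, pp = stats.ttest_rel(acc_a, acc_b)
    # one-tailed: condition b mean greater than condition a
    p_one = stats.t.sf(-t, 2 * n_repeats - 2) if t != 0 else 0.5
    comparison = AccuracyComparison(
        t=float(t),
        p_two_tailed=float(p),
        p_one_tailed_b_greater=float(p_one),
        paired_t=float(pt),
        paired_p_two_tailed=float(pp),
    )
    return dist_a, dist_b, comparison


def misclassified_age_test(
    result: ClassificationResult,
    ages: np.ndarray,
    control_label,
    patient_label,
) -> MisclassifiedAgeTest:
    """Compare mean ages of misclassified controls vs misclassified patients.

    Independent-samples t with a one-tailed p in the direction the age
    confound predicts: misclassified controls older than misclassified
    patients. Raises :class:`InsufficientMisclassifications` when either
    true group has no errors (e.g. a perfect classifier).
    """
    ages = np.asarray(ages, dtype=np.float64)
    wrong = ~result.correct
    mis_controls = ages[wrong & (result.labels == control_label)]
    mis_patients = ages[wrong & (result.labels == patient_label)]
    if len(mis_controls) == 0 or len(mis_patients) == 0:
        raise InsufficientMisclassifications(
            "need at least one misclassified subject in each true group"
        )
    if np.ptp(mis_controls) == 0 and np.ptp(mis_patients) == 0 and (
        mis_controls.mean() == mis_patients.mean()
    ):
        t, p_one = 0.0, 0.5
    else:
        t, _ = stats.ttest_ind(mis_controls, mis_patients)
        df = len(mis_controls) + len(mis_patients) - 2
        p_one = float(stats.t.sf(t, df))
    return MisclassifiedAgeTest(
        t=float(t),
        p_one_tailed=float(p_one),
        mean_age_misclassified_controls=float(mis_controls.mean()),
        mean_age_misclassified_patients=float(mis_patients.mean()),
        n_misclassified_controls=int(len(mis_controls)),
        n_misclassified_patients=int(len(mis_patients)),
    )
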