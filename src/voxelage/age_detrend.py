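"""Voxel-wise linear age detrending estimated on healthy controls only.

Per masked voxel, the model ``y = b0 + b_age * age + e`` is fit by
ordinary least squares over the control subjects alone; the age-explained
component ``b_age * age_i`` is then subtracted from every subject's value
(patients included) at that voxel. Fitting on patients would remove
disease-related change that covaries with age, so the API never lets
patients enter the fit.

A strict cross-validated variant splits the controls in half, fits one
model per half, and applies each model only to data it has never seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateAges, GridMismatch, TooFewSubjects
from .io_cohort import VolumeStack
from .masking import MaskVolume

__all__ = [
    "AgeModelField",
    "CorrectionAssignment",
    "fit_age_model",
    "apply_correction",
    "correct_strict_cv",
    "split_half_indices",
]

_MIN_FIT = 3  # intercept + slope + >=1 residual df


@dataclass
class AgeModelField:
    """Per-voxel intercept and age-slope maps estimated on controls.

    ``beta0`` and ``beta_age`` are full-grid maps; values outside the mask
    are zero and are never applied.
    """

    beta0: np.ndarray
    beta_age: np.ndarray
    mask: MaskVolume
    n_fit: int
    age_mean_fit: float

    def __post_init__(self) -> None:
        if self.beta0.shape != self.mask.shape or self.beta_age.shape != self.mask.shape:
            raise GridMismatch("coefficient maps and mask must share one grid")
        inside0 = self.beta0[self.mask.data]
        inside1 = self.beta_age[self.mask.data]
        if not (np.isfinite(inside0).all() and np.isfinite(inside1).all()):
            raise ValueError("non-finite coefficients inside the mask")


@dataclass
class CorrectionAssignment:
    """Which half-model (1 or 2) corrected each subject under strict CV."""

    model_index: dict[str, int] = field(default_factory=dict)

    def as_covariate(self, subject_ids) -> np.ndarray:
        """0/1 indicator (model 2 -> 1) in the given subject order."""
        return np.array(
            [self.model_index[str(s)] - 1 for s in subject_ids], dtype=np.float64
        )


def fit_age_model(
    controls: VolumeStack, ages: np.ndarray, mask: MaskVolume
) -> AgeModelField:
    """OLS fit of (intercept, age slope) at every masked voxel.

    The closed-form two-parameter solution is used, vectorised over
    voxels: ``b_age = cov(age, y) / var(age)``, ``b0 = mean(y) - b_age *
    mean(age)``. This satisfies the normal equations exactly (up to
    floating point). Voxels with zero response variance get slope 0 and
    intercept equal to the constant — the vanishing-signal limit.
    """
    ages = np.asarray(ages, dtype=np.float64)
    if controls.n_subjects != len(ages):
        raise ValueError("stack and age vector must be aligned")
    if controls.n_subjects < _MIN_FIT:
        raise TooFewSubjects(
            f"need >= {_MIN_FIT} controls to fit, got {controls.n_subjects}"
        )
    if mask.shape != controls.grid_shape:
        raise GridMismatch("mask grid does not match stack grid")
    age_mean = float(ages.mean())
    age_c = ages - age_mean
    ss_age = float(age_c @ age_c)
    if ss_age == 0.0:
        raise DegenerateAges("age variance is zero; slope unidentifiable")

    y = controls.to_matrix(mask)  # n x V
    y_mean = y.mean(axis=0)
    slope = (age_c @ y) / ss_age
    intercept = y_mean - slope * age_mean

    beta0 = np.zeros(mask.shape)
    beta_age = np.zeros(mask.shape)
    beta0[mask.data] = intercept
    beta_age[mask.data] = slope
    return AgeModelField(
        beta0=beta0,
        beta_age=beta_age,
        mask=mask,
        n_fit=controls.n_subjects,
        age_mean_fit=age_mean,
    )


def apply_correction(
    stack: VolumeStack,
    ages: np.ndarray,
    model: AgeModelField,
    mask: MaskVolume | None = None,
    center_age: bool = False,
) -> VolumeStack:
    """Subtract the age-explained component from every subject.

    ``y_c = y - b_age * age_i`` at each masked voxel (controls and
    patients alike); voxels outside the mask pass through unchanged.
    With ``center_age=True`` the subtraction uses ``age_i - age_mean_fit``
    instead — a per-voxel constant shift that leaves two-sample contrasts
    untouched.
    """
    if mask is None:
        mask = model.mask
    if mask.shape != stack.grid_shape:
        raise GridMismatch("mask grid does not match stack grid")
    if model.mask.shape != stack.grid_shape:
        raise GridMismatch("model grid does not match stack grid")
    ages = np.asarray(ages, dtype=np.float64)
    if len(ages) != stack.n_subjects:
        raise ValueError("stack and age vector must be aligned")
    effective_ages = ages - model.age_mean_fit if center_age else ages
    slope = model.beta_age[mask.data]  # V
    corrected = stack.to_matrix(mask) - np.outer(effective_ages, slope)
    return stack.with_matrix(corrected, mask)


def split_half_indices(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle, then deterministic split; first half gets the extra."""
    perm = rng.permutation(n)
    cut = n - n // 2
    return np.sort(perm[:cut]), np.sort(perm[cut:])


def correct_strict_cv(
    controls: VolumeStack,
    control_ages: np.ndarray,
    patients: VolumeStack,
    patient_ages: np.ndarray,
    mask: MaskVolume,
    seed: int = 0,
    center_age: bool = False,
) -> tuple[VolumeStack, VolumeStack, CorrectionAssignment]:
    """Strict cross-validated detrending: no subject sees its own model.

    Controls are shuffled (seeded) and split into two halves (first half
    larger when the count is odd). Model k is fit on control half k and
    applied to the *other* control half. Patients are randomly halved with
    the same seed stream; patient half k is corrected by model k. Returns
    corrected control and patient stacks in the original subject order,
    plus the model assignment for use as a downstream covariate.
    """
    if controls.n_subjects < 6:
        raise TooFewSubjects("strict CV needs >= 6 controls")
    control_ages = np.asarray(control_ages, dtype=np.float64)
    patient_ages = np.asarray(patient_ages, dtype=np.float64)
    rng = np.random.default_rng(seed)
    c1, c2 = split_half_indices(controls.n_subjects, rng)
    p1, p2 = split_half_indices(patients.n_subjects, rng)

    model1 = fit_age_model(controls.subset(c1), control_ages[c1], mask)
    model2 = fit_age_model(controls.subset(c2), control_ages[c2], mask)

    corrected_controls = controls.with_matrix(controls.to_matrix(mask), mask)
    assignment = CorrectionAssignment()
    # control half 2 is unseen by model 1 and vice versa
    for half, model, model_idx in ((c2, model1, 1), (c1, model2, 2)):
        fixed = apply_correction(
            controls.subset(half), control_ages[half], model, mask, center_age
        )
        corrected_controls.data[half] = fixed.data
        for i in half:
            assignment.model_index[controls.subject_ids[i]] = model_idx

    corrected_patients = patients.with_matrix(patients.to_matrix(mask), mask)
    for half, model, model_idx in ((p1, model1, 1), (p2, model2, 2)):
        fixed = apply_correction(
            patients.subset(half), patient_ages[half], model, mask, center_age
        )
        corrected_patients.data[half] = fixed.data
        for i in half:
            assignment.model_index[patients.subject_ids[i]] = model_idx

    return corrected_controls, corrected_patients, assignment
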