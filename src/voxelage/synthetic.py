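"""Phantom cohorts with known baseline, age slope, atrophy and noise.

Each subject volume is built as

    y(v) = baseline(v) + beta_age(v) * age_i + delta(v) * [patient] + noise

with a seeded generator, so every downstream module (detrending, VBM,
classification) can be tested against exact ground truth. The age/disease
confound scenario — patients younger while the age slope is negative, the
two effects pointing the same way — is produced by shifting the patient
age distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import SpecError
from .io_cohort import CohortTable, VolumeStack
from .masking import smooth_volume
import pandas as pd

__all__ = [
    "SphereRegion",
    "BoxRegion",
    "PhantomSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_templates",
]


@dataclass(frozen=True)
class SphereRegion:
    center: tuple[int, int, int]
    radius: float

    def indicator(self, shape) -> np.ndarray:
        grids = np.indices(shape, dtype=np.float64)
        c = np.asarray(self.center, dtype=np.float64)
        dist2 = sum((grids[d] - c[d]) ** 2 for d in range(3))
        return dist2 <= self.radius**2


@dataclass(frozen=True)
class BoxRegion:
    lo: tuple[int, int, int]
    hi: tuple[int, int, int]  # exclusive

    def indicator(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        sl = tuple(slice(a, b) for a, b in zip(self.lo, self.hi))
        out[sl] = True
        return out


def _region_inside(region, shape) -> bool:
    if isinstance(region, SphereRegion):
        c, r = np.asarray(region.center), region.radius
        return bool(np.all(c - r >= 0) and np.all(c + r <= np.asarray(shape) - 1))
    if isinstance(region, BoxRegion):
        lo, hi = np.asarray(region.lo), np.asarray(region.hi)
        return bool(np.all(lo >= 0) and np.all(hi <= np.asarray(shape)) and np.all(lo < hi))
    raise SpecError(f"unknown region type {type(region).__name__}")


@dataclass
class PhantomSpec:
    """Generator parameters for one phantom cohort.

    ``beta_age`` is the age slope (GM units per year) applied everywhere,
    or only inside ``beta_age_region`` when that is set (optionally
    feathered by ``beta_age_smooth_fwhm``). ``patient_age_shift`` moves
    the patient age distribution (negative = patients younger), coupling
    age and disease. ``baseline_texture_sd`` adds a smooth frozen spatial
    texture shared by all subjects.
    """

    shape: tuple[int, int, int] = (16, 16, 16)
    n_controls: int = 40
    n_patients: int = 40
    age_range: tuple[float, float] = (60.0, 90.0)
    baseline: float = 0.6
    baseline_texture_sd: float = 0.0
    beta_age: float = 0.0
    beta_age_region: SphereRegion | BoxRegion | None = None
    beta_age_smooth_fwhm: float = 0.0
    atrophy_delta: float = 0.0
    atrophy_region: SphereRegion | BoxRegion | None = None
    noise_sd: float = 0.02
    patient_age_shift: float = 0.0
    seed: int = 0
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.n_controls < 3 or self.n_patients < 3:
            raise SpecError("need >= 3 subjects per group")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise SpecError("age_range must be a positive increasing interval")
        for region in (self.beta_age_region, self.atrophy_region):
            if region is not None and not _region_inside(region, self.shape):
                raise SpecError("region extends outside the grid")
        if self.atrophy_delta != 0.0 and self.atrophy_region is None:
            raise SpecError("atrophy_delta set but no atrophy_region")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("beta_age_region", "atrophy_region"):
            region = raw.get(key)
            if region is not None:
                if "radius" in region:
                    raw[key] = SphereRegion(tuple(region["center"]), region["radius"])
                else:
                    raw[key] = BoxRegion(tuple(region["lo"]), tuple(region["hi"]))
        for key in ("shape", "age_range", "voxel_size_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    baseline_map: np.ndarray
    beta_age_map: np.ndarray
    atrophy_mask: np.ndarray
    atrophy_delta: float
    ages: np.ndarray
    is_patient: np.ndarray


def _build_beta_age_map(spec: PhantomSpec) -> np.ndarray:
    if spec.beta_age_region is None:
        return np.full(spec.shape, spec.beta_age)
    beta = np.where(spec.beta_age_region.indicator(spec.shape), spec.beta_age, 0.0)
    if spec.beta_age_smooth_fwhm > 0:
        beta = smooth_volume(beta, spec.beta_age_smooth_fwhm, spec.voxel_size_mm)
    return beta


def generate_cohort(spec: PhantomSpec) -> tuple[VolumeStack, CohortTable, GroundTruth]:
    """Generate a seeded phantom cohort plus its ground-truth record.

    Controls come first in the stack (ids ``ctl-*`` then ``pat-*``). Ages
    are uniform on ``age_range``; patient ages are shifted by
    ``patient_age_shift`` years and floored at 1 year.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_controls + spec.n_patients
    is_patient = np.zeros(n, dtype=bool)
    is_patient[spec.n_controls :] = True

    ages = rng.uniform(*spec.age_range, size=n)
    ages[is_patient] = np.maximum(ages[is_patient] + spec.patient_age_shift, 1.0)
    sexes = rng.integers(0, 2, size=n)

    baseline_map = np.full(spec.shape, spec.baseline)
    if spec.baseline_texture_sd > 0:
        texture = rng.normal(0.0, 1.0, size=spec.shape)
        texture = smooth_volume(texture, 6.0, spec.voxel_size_mm)
        sd = texture.std()
        if sd > 0:
            baseline_map = baseline_map + texture * (spec.baseline_texture_sd / sd)

    beta_age_map = _build_beta_age_map(spec)
    if spec.atrophy_region is not None:
        atrophy_mask = spec.atrophy_region.indicator(spec.shape)
    else:
        atrophy_mask = np.zeros(spec.shape, dtype=bool)
    delta_map = np.where(atrophy_mask, spec.atrophy_delta, 0.0)

    data = np.empty((n,) + tuple(spec.shape))
    for i in range(n):
        y = baseline_map + beta_age_map * ages[i]
        if is_patient[i]:
            y = y + delta_map
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        data[i] = y

    subject_ids = [f"ctl-{i:03d}" for i in range(spec.n_controls)] + [
        f"pat-{i:03d}" for i in range(spec.n_patients)
    ]
    stack = VolumeStack(data, spec.affine, subject_ids)
    table = CohortTable(
        pd.DataFrame(
            {
                "subject_id": subject_ids,
                "group": np.where(is_patient, "patient", "control"),
                "age": ages,
                "sex": np.where(sexes == 1, "F", "M"),
            }
        )
    )
    truth = GroundTruth(
        baseline_map=baseline_map,
        beta_age_map=beta_age_map,
        atrophy_mask=atrophy_mask,
        atrophy_delta=spec.atrophy_delta,
        ages=ages,
        is_patient=is_patient,
    )
    return stack, table, truth


def generate_templates(
    shape=(16, 16, 16),
    kind: str = "box",
    rim: int = 2,
    radius: float | None = None,
    falloff: float = 1.0,
    high: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Two smooth probability templates with a sub-0.2 rim.

    ``kind='box'``: probability ``high`` in the interior, decaying to
    ~0 across a ``rim``-voxel border. ``kind='sphere'``: radial sigmoid
    around the grid centre with half-maximum at ``radius``; the 0.2
    level set then sits at the closed-form radius
    ``radius + falloff * ln(high / 0.2 - 1)``, so mask sizes are
    checkable against plain voxel-counting geometry.
    """
    shape = tuple(shape)
    if kind == "sphere":
        if radius is None:
            radius = min(shape) / 2.0 - rim
        grids = np.indices(shape, dtype=np.float64)
        center = (np.asarray(shape, dtype=np.float64) - 1) / 2.0
        dist = np.sqrt(sum((grids[d] - center[d]) ** 2 for d in range(3)))
        template = high / (1.0 + np.exp((dist - radius) / falloff))
    elif kind == "box":
        interior = np.zeros(shape)
        sl = tuple(slice(rim, s - rim) for s in shape)
        interior[sl] = 1.0
        template = smooth_volume(interior, 2.0, (1.0, 1.0, 1.0)) * high
    else:
        raise SpecError("kind must be 'box' or 'sphere'")
    # second template: slightly tighter copy so both must agree
    template_b = np.clip(template * 0.97, 0.0, 1.0)
    return template, template_b
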