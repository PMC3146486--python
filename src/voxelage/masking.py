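"""Analysis-mask construction and Gaussian smoothing.

The analysis mask keeps a voxel only if its tissue probability strictly
exceeds the threshold in *both* templates (default 0.2). Smoothing is a
separable Gaussian parameterised by FWHM in mm; boundary handling is plain
zero-padded convolution (no renormalisation), so interior impulses follow
the closed-form kernel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyMask, GridMismatch
from .io_cohort import VolumeStack

__all__ = ["MaskVolume", "build_mask", "smooth_gaussian", "smooth_volume", "fwhm_to_sigma"]

DEFAULT_THRESHOLD = 0.2
DEFAULT_FWHM_MM = 12.0

#: FWHM = sigma * 2*sqrt(2*ln 2)
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class MaskVolume:
    """Boolean inclusion grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D boolean grid")

    @property
    def n_in(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @classmethod
    def full(cls, shape) -> "MaskVolume":
        return cls(np.ones(shape, dtype=bool))


def build_mask(
    template_a: np.ndarray,
    template_b: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> MaskVolume:
    """Voxels strictly above ``threshold`` in both probability templates.

    Strict inequality: a voxel equal to the threshold in either template
    is excluded.
    """
    a = np.asarray(template_a, dtype=np.float64)
    b = np.asarray(template_b, dtype=np.float64)
    if a.shape != b.shape:
        raise GridMismatch(f"template shapes differ: {a.shape} vs {b.shape}")
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    data = (a > threshold) & (b > threshold)
    if not data.any():
        raise EmptyMask(f"no voxel exceeds {threshold} in both templates")
    return MaskVolume(data)


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, dtype=np.float64), (3,))
    if np.any(voxel_size_mm <= 0):
        raise ValueError("voxel sizes must be positive")
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    return fwhm_mm / (voxel_size_mm * _FWHM_FACTOR)


def smooth_volume(volume: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Smooth one 3-D volume; ``fwhm_mm == 0`` is the identity."""
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=np.float64).copy()
    sigma = fwhm_to_sigma(fwhm_mm, voxel_size_mm)
    return ndimage.gaussian_filter(
        np.asarray(volume, dtype=np.float64), sigma=sigma, mode="constant", cval=0.0
    )


def smooth_gaussian(
    stack: VolumeStack, fwhm_mm: float = DEFAULT_FWHM_MM, voxel_size_mm=None
) -> VolumeStack:
    """Smooth every volume in the stack with one isotropic-FWHM kernel.

    ``voxel_size_mm`` defaults to the voxel size implied by the affine.
    """
    if voxel_size_mm is None:
        voxel_size_mm = stack.voxel_size
    smoothed = np.stack(
        [smooth_volume(vol, fwhm_mm, voxel_size_mm) for vol in stack.data]
    )
    return VolumeStack(smoothed, stack.affine.copy(), list(stack.subject_ids))


def apply_mask(stack: VolumeStack, mask: MaskVolume) -> VolumeStack:
    """Zero out voxels outside the mask (separate, reusable step)."""
    if mask.shape != stack.grid_shape:
        raise GridMismatch(f"mask shape {mask.shape} != grid {stack.grid_shape}")
    data = stack.data * mask.data[None]
    return VolumeStack(data, stack.affine.copy(), list(stack.subject_ids))
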