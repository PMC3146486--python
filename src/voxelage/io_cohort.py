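"""Volume stacks and cohort tables.

Reads sets of co-registered NIfTI volumes into a single subjects-first
array, and per-subject metadata from TSV files. Alignment between the two
is explicit: volumes are never resampled or reordered implicitly, and any
grid disagreement is a hard error.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DuplicateSubject, GridMismatch, MissingSubject, ParseError

__all__ = [
    "VolumeStack",
    "CohortTable",
    "load_stack",
    "save_stack",
    "load_volume",
    "save_volume",
    "align",
]

#: decimal places to which affines are rounded before equality comparison
_AFFINE_DECIMALS = 4

_REQUIRED_COLUMNS = ("subject_id", "group", "age", "sex")


@dataclass
class VolumeStack:
    """A set of subject volumes on one shared grid.

    Parameters
    ----------
    data
        Array of shape ``(n_subjects, nx, ny, nz)``.
    affine
        Shared 4x4 voxel-to-world transform.
    subject_ids
        Ordered, unique subject identifiers, one per volume.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_subjects, nx, ny, nz)")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:04d}" for i in range(len(self.data))]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != len(self.data):
            raise ValueError("one subject_id per volume required")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise DuplicateSubject("subject_ids are not unique")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def to_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Flatten to a subjects x voxels matrix (mask-aware, fixed grid order)."""
        if mask is None:
            return self.data.reshape(self.n_subjects, -1)
        mask = _as_mask_array(mask, self.grid_shape)
        return self.data[:, mask]

    def with_matrix(self, matrix: np.ndarray, mask: np.ndarray | None = None) -> "VolumeStack":
        """Return a copy whose masked voxels are replaced by ``matrix`` rows."""
        data = self.data.copy()
        if mask is None:
            data = np.asarray(matrix, dtype=np.float64).reshape(self.data.shape)
        else:
            mask = _as_mask_array(mask, self.grid_shape)
            data[:, mask] = matrix
        return VolumeStack(data, self.affine.copy(), list(self.subject_ids))

    def subset(self, indices: Sequence[int]) -> "VolumeStack":
        idx = list(indices)
        return VolumeStack(
            self.data[idx], self.affine.copy(), [self.subject_ids[i] for i in idx]
        )


def _as_mask_array(mask, shape) -> np.ndarray:
    arr = getattr(mask, "data", mask)
    arr = np.asarray(arr, dtype=bool)
    if arr.shape != tuple(shape):
        raise GridMismatch(f"mask shape {arr.shape} != grid shape {tuple(shape)}")
    return arr


class CohortTable:
    """Per-subject metadata: id, group, age, sex (extra columns kept, ignored)."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"cohort table missing columns: {missing}")
        df["subject_id"] = df["subject_id"].astype(str)
        if df["subject_id"].duplicated().any():
            dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise DuplicateSubject(f"duplicate subject ids: {dups}")
        df["age"] = pd.to_numeric(df["age"], errors="raise")
        if df["age"].isna().any() or (df["age"] <= 0).any():
            raise ParseError("age must be present and > 0 for every subject")
        if df["group"].isna().any():
            raise ParseError("group must be present for every subject")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortTable) and self.df.equals(other.df)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].tolist()

    @property
    def ages(self) -> np.ndarray:
        return self.df["age"].to_numpy(dtype=np.float64)

    @property
    def groups(self) -> np.ndarray:
        return self.df["group"].to_numpy()

    @property
    def sexes(self) -> np.ndarray:
        return self.df["sex"].to_numpy()

    def subset(self, rows) -> "CohortTable":
        return CohortTable(self.df.iloc[list(rows)].reset_index(drop=True))

    def where_group(self, label) -> "CohortTable":
        return CohortTable(self.df[self.df["group"] == label].reset_index(drop=True))

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CohortTable":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
        except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
            raise ParseError(f"cannot read cohort table {path}: {exc}") from exc
        return cls(df)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def load_volume(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read one 3-D NIfTI volume; returns (data, affine)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:  # nibabel raises a zoo of types
        raise ParseError(f"cannot read volume {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ParseError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return data, np.asarray(img.affine, dtype=np.float64)


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_stack(
    paths: Iterable[str | os.PathLike], subject_ids: Sequence[str] | None = None
) -> VolumeStack:
    """Load co-registered volumes, in input order, onto one shared grid.

    Fails with :class:`GridMismatch` if any shape or affine (rounded to
    1e-4) differs from the first volume — never resamples.
    """
    paths = list(paths)
    if not paths:
        raise ParseError("no volume paths given")
    volumes = []
    ref_affine = None
    ref_shape = None
    for p in paths:
        data, affine = load_volume(p)
        if ref_affine is None:
            ref_affine, ref_shape = affine, data.shape
        else:
            if data.shape != ref_shape:
                raise GridMismatch(
                    f"{p}: shape {data.shape} != reference {ref_shape}"
                )
            if not np.array_equal(
                np.round(affine, _AFFINE_DECIMALS),
                np.round(ref_affine, _AFFINE_DECIMALS),
            ):
                raise GridMismatch(f"{p}: affine differs from reference")
        volumes.append(data)
    if subject_ids is None:
        subject_ids = [_stem(p) for p in paths]
    return VolumeStack(np.stack(volumes), ref_affine, list(subject_ids))


def save_stack(stack: VolumeStack, directory: str | os.PathLike, suffix: str = ".nii") -> list[str]:
    """Write one NIfTI per subject into ``directory``; returns the paths."""
    os.makedirs(directory, exist_ok=True)
    out = []
    for sid, vol in zip(stack.subject_ids, stack.data):
        path = os.path.join(str(directory), f"{sid}{suffix}")
        save_volume(vol, stack.affine, path)
        out.append(path)
    return out


def _stem(path) -> str:
    name = os.path.basename(str(path))
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return name[: -len(ext)]
    return os.path.splitext(name)[0]


def align(stack: VolumeStack, table: CohortTable) -> tuple[VolumeStack, CohortTable]:
    """Reorder the cohort table to stack order; ids must match one-to-one.

    Raises :class:`MissingSubject` if any stack id is absent from the
    table. Extra table rows (subjects without volumes) are dropped.
    """
    index = {sid: i for i, sid in enumerate(table.subject_ids)}
    rows = []
    for sid in stack.subject_ids:
        if sid not in index:
            raise MissingSubject(f"subject {sid!r} not in cohort table")
        rows.append(index[sid])
    return stack, table.subset(rows)
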