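"""Reading and writing voxel maps, dataset assembly, and motion quality control.

All 3-D maps are NIfTI-1 images handled through :mod:`nibabel`.  In-mask
voxels are linearised in one fixed order shared by every stage of the
pipeline: ascending flat index with the *first* grid axis varying fastest
(Fortran order), 0-based.  Maps are written as 32-bit floats with out-of-mask
voxels set to 0.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

AFFINE_ATOL = 1e-4  # tolerance on affine agreement between maps and mask


@dataclasses.dataclass
class VolumeImage:
    """A 3-D scalar grid in a world space (e.g. MNI152).

    Parameters
    ----------
    data : ndarray, shape (i, j, k)
        Scalar values (z-statistic units for contrast maps, bool for masks).
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform in mm; must be invertible.
    space_tag : str
        Free-text label of the reference space.
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class SubjectRecord:
    """One scanning session of one subject, with its motion summary."""

    subject_id: str
    session_id: str
    mean_rel_rms: float  # mm, nonnegative
    path: str = ""

    def __post_init__(self) -> None:
        if self.mean_rel_rms < 0:
            raise ValueError(
                f"mean_rel_rms must be nonnegative, got {self.mean_rel_rms} "
                f"for subject {self.subject_id!r}"
            )


@dataclasses.dataclass
class ActivationDataset:
    """Subjects x masked-voxels matrix of contrast z-statistics.

    ``data[s, v]`` is subject ``s`` at in-mask voxel ``v`` in the shared
    linearisation (see :func:`mask_index`).
    """

    data: np.ndarray  # (n_subjects, V)
    mask: VolumeImage  # boolean grid
    subject_ids: list[str]
    contrast: str = "faces>shapes"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n_vox = int(self.mask.data.sum())
        if self.data.ndim != 2 or self.data.shape[1] != n_vox:
            raise ValueError(
                f"data must be (n_subjects, {n_vox}), got {self.data.shape}"
            )
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length must match data rows")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def subset(self, subject_ids: Sequence[str]) -> "ActivationDataset":
        """Rows restricted to ``subject_ids``, in the order given."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown subject ids: {missing[:5]}")
        rows = [pos[s] for s in subject_ids]
        return ActivationDataset(
            self.data[rows], self.mask, list(subject_ids), self.contrast
        )


# ---------------------------------------------------------------------------
# voxel linearisation
# ---------------------------------------------------------------------------

def mask_index(mask_data: np.ndarray) -> np.ndarray:
    """Flat (Fortran-order) indices of the true voxels of a boolean grid.

    This defines the canonical voxel order: the first grid axis varies
    fastest.  Every (n, V) matrix in the package uses this order.
    """
    flat = np.asarray(mask_data, dtype=bool).reshape(-1, order="F")
    return np.nonzero(flat)[0]


def extract_masked(volume: np.ndarray, mask_data: np.ndarray) -> np.ndarray:
    """In-mask values of a 3-D volume as a length-V vector (canonical order)."""
    return np.asarray(volume).reshape(-1, order="F")[mask_index(mask_data)]


def embed_masked(values: np.ndarray, mask_data: np.ndarray) -> np.ndarray:
    """Place a length-V vector back on the 3-D grid; out-of-mask voxels 0."""
    idx = mask_index(mask_data)
    values = np.asarray(values)
    if values.shape != idx.shape:
        raise ValueError(
            f"expected {idx.size} values for this mask, got {values.shape}"
        )
    flat = np.zeros(int(np.prod(mask_data.shape)), dtype=values.dtype)
    flat[idx] = values
    return flat.reshape(mask_data.shape, order="F")


# ---------------------------------------------------------------------------
# NIfTI reading / writing
# ---------------------------------------------------------------------------

def load_volume(path: str | Path, space_tag: str = "") -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(np.asarray(img.dataobj, dtype=float), img.affine, space_tag)


def load_mask(path: str | Path, space_tag: str = "") -> VolumeImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return VolumeImage(data > 0, img.affine, space_tag)


def _check_geometry(shape, affine, mask: VolumeImage, name: str) -> None:
    if tuple(shape) != tuple(mask.shape):
        raise ValueError(
            f"{name}: grid shape {tuple(shape)} does not match mask {mask.shape}"
        )
    if not np.allclose(affine, mask.affine, atol=AFFINE_ATOL):
        raise ValueError(f"{name}: affine does not match the mask affine")


def load_activation_dataset(
    paths: Sequence[str | Path],
    mask: VolumeImage,
    subject_ids: Sequence[str] | None = None,
    contrast: str = "faces>shapes",
) -> ActivationDataset:
    """Assemble per-subject 3-D maps into a subjects x voxels matrix.

    Every map must share the mask's grid shape and affine (within
    ``AFFINE_ATOL``); non-finite values inside the mask are rejected with the
    offending subject named.
    """
    if mask.data.dtype != bool:
        raise ValueError("mask must be boolean")
    if subject_ids is None:
        subject_ids = [Path(p).name.split(".")[0] for p in paths]
    if len(subject_ids) != len(paths):
        raise ValueError("subject_ids must match paths")
    idx = mask_index(mask.data)
    rows = np.empty((len(paths), idx.size))
    for i, path in enumerate(paths):
        img = nib.load(str(path))
        _check_geometry(img.shape, img.affine, mask, str(path))
        vals = np.asarray(img.dataobj, dtype=float).reshape(-1, order="F")[idx]
        bad = ~np.isfinite(vals)
        if bad.any():
            raise ValueError(
                f"subject {subject_ids[i]!r} ({path}): {int(bad.sum())} "
                "non-finite values inside the mask"
            )
        rows[i] = vals
    return ActivationDataset(rows, mask, list(subject_ids), contrast)


def load_stack(
    path: str | Path,
    mask: VolumeImage,
    subject_ids: Sequence[str] | None = None,
    contrast: str = "faces>shapes",
) -> ActivationDataset:
    """Load a 4-D NIfTI stack (one volume per subject) against a mask."""
    img = nib.load(str(path))
    if len(img.shape) != 4:
        raise ValueError(f"{path}: expected a 4-D stack, got shape {img.shape}")
    _check_geometry(img.shape[:3], img.affine, mask, str(path))
    data4d = np.asarray(img.dataobj, dtype=float)
    n = data4d.shape[3]
    if subject_ids is None:
        subject_ids = [f"sub-{i:04d}" for i in range(n)]
    if len(subject_ids) != n:
        raise ValueError("subject_ids must match the 4th dimension")
    idx = mask_index(mask.data)
    flat = data4d.reshape(-1, n, order="F")[idx]  # (V, n)
    mat = flat.T
    bad_per_subj = (~np.isfinite(mat)).sum(axis=1)
    if bad_per_subj.any():
        j = int(np.argmax(bad_per_subj))
        raise ValueError(
            f"subject {subject_ids[j]!r}: {int(bad_per_subj[j])} non-finite "
            "values inside the mask"
        )
    return ActivationDataset(mat, mask, list(subject_ids), contrast)


def write_map(values: np.ndarray, mask: VolumeImage, path: str | Path) -> None:
    """Write a length-V vector as a 3-D NIfTI map (float32, zeros off-mask)."""
    grid = embed_masked(np.asarray(values, dtype=np.float32), mask.data)
    nib.save(nib.Nifti1Image(grid.astype(np.float32), mask.affine), str(path))


def write_stack(matrix: np.ndarray, mask: VolumeImage, path: str | Path) -> None:
    """Write an (n, V) matrix as a 4-D NIfTI stack (float32)."""
    matrix = np.asarray(matrix, dtype=np.float32)
    idx = mask_index(mask.data)
    if matrix.ndim != 2 or matrix.shape[1] != idx.size:
        raise ValueError(f"expected (n, {idx.size}) matrix, got {matrix.shape}")
    flat = np.zeros((int(np.prod(mask.shape)), matrix.shape[0]), dtype=np.float32)
    flat[idx] = matrix.T
    grid = flat.reshape(mask.shape + (matrix.shape[0],), order="F")
    nib.save(nib.Nifti1Image(grid, mask.affine), str(path))


def write_mask(mask: VolumeImage, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path)
    )


# ---------------------------------------------------------------------------
# tables and QC
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    """Read a UTF-8 TSV with a header row."""
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def qc_filter_motion(
    records: Sequence[SubjectRecord], threshold: float = 0.5
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Partition sessions by head motion.

    A record is excluded when its mean relative RMS displacement is *strictly*
    greater than ``threshold`` (default 0.5 mm); records at exactly the
    threshold are kept.  Order is preserved and the two lists partition the
    input.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    for rec in records:
        if rec.mean_rel_rms < 0:
            raise ValueError(
                f"negative mean_rel_rms for subject {rec.subject_id!r}"
            )
    kept = [r for r in records if r.mean_rel_rms <= threshold]
    excluded = [r for r in records if r.mean_rel_rms > threshold]
    return kept, excluded
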