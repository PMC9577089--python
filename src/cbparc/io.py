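"""Volume and table I/O with the package's shared spatial conventions.

All volumes live on a :class:`VolumeGrid`; voxel indexing is 0-based and world
coordinates exist only through the affine. Operations that compare two volumes
require identical grids (shape equal, affines within ``GRID_ATOL`` mm) —
registration is upstream of this package and never performed implicitly.

Formats: NIfTI-1 (``.nii``/``.nii.gz``) for volumes, tab-separated UTF-8 text
for matrices (row ids in the first column, column names in the header).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GRID_ATOL",
    "VolumeGrid",
    "LabelVolume",
    "RegionSet",
    "GridMismatchError",
    "read_label_volume",
    "write_label_volume",
    "read_matrix_table",
    "write_matrix_table",
]

#: Absolute tolerance (mm) for affine agreement between comparable grids.
GRID_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D sampling grid: shape in voxels plus a voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel index -> world mm

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of one voxel along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def matches(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=GRID_ATOL
        )

    def require_match(self, other: "VolumeGrid", context: str = "operation") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{context} requires identical grids: "
                f"{self.shape} vs {other.shape} (affines within {GRID_ATOL} mm); "
                "resample/register upstream"
            )


@dataclass
class LabelVolume:
    """Integer labels on a grid; 0 is background, 1..K are regions/clusters."""

    grid: VolumeGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ValueError(
                f"label array shape {labels.shape} != grid shape {self.grid.shape}"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels.astype(np.int32, copy=False)

    @property
    def label_set(self) -> set[int]:
        return set(np.unique(self.labels).tolist())

    def mask(self) -> np.ndarray:
        """Boolean array of in-mask (label > 0) voxels."""
        return self.labels > 0

    def n_voxels(self, label: int | None = None) -> int:
        if label is None:
            return int((self.labels > 0).sum())
        return int((self.labels == label).sum())


@dataclass
class RegionSet:
    """An ordered, named collection of target regions.

    The order of ``names`` is the coordinate system every fingerprint is
    expressed in and is preserved by all downstream operations.
    """

    names: list[str]
    masks: dict[str, LabelVolume] | None = field(default=None)

    def __post_init__(self) -> None:
        self.names = list(self.names)
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a 3-D integer-valued NIfTI image as a :class:`LabelVolume`.

    Float-typed images are accepted only when every voxel is within 1e-6 of
    an integer (files written by tools that store labels as float32).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label image, got {data.ndim}-D")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: non-integer label data")
        data = rounded
    grid = VolumeGrid(shape=data.shape, affine=np.asarray(img.affine))
    return LabelVolume(grid=grid, labels=data.astype(np.int32))


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a :class:`LabelVolume` to NIfTI-1, int32 on disk."""
    img = nib.Nifti1Image(vol.labels.astype(np.int32), vol.grid.affine)
    nib.save(img, str(path))


def read_matrix_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix: header of column names, first column of row ids.

    Row and column order are preserved exactly as in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column ids {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cells in matrix table") from exc
    if not np.all(np.isfinite(values) | np.isnan(values)):
        raise ValueError(f"{path}: non-finite values in matrix table")
    return df.astype(float)


def write_matrix_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a named matrix as TSV ('.' decimal, UTF-8, full precision)."""
    df.to_csv(path, sep="\t", float_format="%.17g", encoding="utf-8")
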