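"""From streamline-count matrices to the voxelwise similarity matrix.

A subject's tractography product is a seed-voxel x target count matrix: row v
holds the number of streamlines seeded at voxel v that reached each target.
Voxels belonging to the same subregion are assumed to share a connectivity
profile, so the quantity that is clustered is the Pearson correlation between
the profiles of every voxel pair.

Seed voxels are kept in a fixed scan order — x fastest, then y, then z — so
that rows of every per-subject matrix line up across subjects and with the
seed-mask geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LabelVolume

__all__ = [
    "ConnectivityMatrix",
    "SimilarityMatrix",
    "scan_order_voxels",
    "voxel_linear_index",
    "build_connectivity_matrix",
    "build_similarity",
]

logger = logging.getLogger(__name__)


def scan_order_voxels(mask: LabelVolume) -> np.ndarray:
    """(n, 3) voxel coordinates of the in-mask voxels in scan order.

    Scan order iterates x fastest, then y, then z; it is the row order of
    every :class:`ConnectivityMatrix` on this mask.
    """
    coords = np.argwhere(mask.labels > 0)  # sorted by (x, y, z), z fastest
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    return coords[order]


def voxel_linear_index(coords: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Linear ids (x fastest) for (n, 3) voxel coordinates."""
    return np.ravel_multi_index(coords.T, shape, order="F")


@dataclass
class ConnectivityMatrix:
    """Seed-voxel x target streamline counts for one subject."""

    seed_voxel_ids: np.ndarray  # linear indices into the seed grid, scan order
    target_ids: list[str]
    counts: np.ndarray  # (n_voxels, n_targets) non-negative

    def __post_init__(self) -> None:
        self.seed_voxel_ids = np.asarray(self.seed_voxel_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        self.target_ids = [str(t) for t in self.target_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (voxels x targets)")
        if self.counts.shape != (len(self.seed_voxel_ids), len(self.target_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.seed_voxel_ids)} voxels x {len(self.target_ids)} targets"
            )
        if self.counts.min(initial=0.0) < 0:
            raise ValueError("negative streamline counts")

    @property
    def n_voxels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_targets(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.seed_voxel_ids, name="voxel"),
            columns=self.target_ids,
        )


@dataclass
class SimilarityMatrix:
    """Symmetric voxel x voxel Pearson-correlation matrix, unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric (1e-10)")
        if v.min() < -1 - 1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("similarity entries must lie in [-1, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1")
        self.values = v

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def build_connectivity_matrix(
    count_table: pd.DataFrame, seed_mask: LabelVolume
) -> ConnectivityMatrix:
    """Order a named count table to the seed mask's scan order.

    ``count_table`` rows are keyed by the linear voxel id (x fastest) of each
    in-mask voxel; they may arrive in any order and are re-sorted. Counts are
    never altered.
    """
    coords = scan_order_voxels(seed_mask)
    wanted = voxel_linear_index(coords, seed_mask.grid.shape)
    have = count_table.index.astype(int)
    have_set = set(have.tolist())
    missing = [int(i) for i in wanted if int(i) not in have_set]
    if missing:
        raise ValueError(
            f"count table is missing {len(missing)} seed-mask voxel(s); "
            f"first missing linear ids: {missing[:5]}"
        )
    extra = sorted(have_set - set(int(i) for i in wanted))
    if extra:
        raise ValueError(
            f"count table has {len(extra)} row(s) outside the seed mask; "
            f"first extra linear ids: {extra[:5]}"
        )
    table = count_table.set_axis(have, axis=0).loc[wanted]
    return ConnectivityMatrix(
        seed_voxel_ids=wanted,
        target_ids=list(count_table.columns),
        counts=table.to_numpy(dtype=float),
    )


def build_similarity(conn: ConnectivityMatrix) -> SimilarityMatrix:
    """Pearson correlation between the connectivity profiles of voxel pairs.

    Voxels with a flat (zero-variance) profile — typically voxels no
    streamline left — are retained with similarity 0 to every other voxel and
    1 on the diagonal, so the matrix keeps the seed mask's geometry.
    """
    if conn.n_voxels < 2:
        raise ValueError("need at least 2 seed voxels")
    if conn.n_targets < 2:
        raise ValueError("need at least 2 targets to correlate profiles")
    X = conn.counts
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "%d seed voxel(s) have zero-variance connectivity profiles; "
            "their similarity to all other voxels is set to 0",
            int(flat.sum()),
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(flat, 1.0, sd * np.sqrt(X.shape[1]))
    Z = Xc / denom[:, None]
    R = Z @ Z.T
    R[flat, :] = 0.0
    R[:, flat] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(values=R)
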