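"""Subject-level clustering and the group maximum probability map (MPM).

The parcellation stage turns each subject's voxelwise similarity matrix into
integer cluster labels (spectral clustering), reconciles the arbitrary label
identities across subjects (optimal assignment against a reference), and
summarizes the cohort as per-cluster probability maps whose voxelwise argmax
is the MPM. Exact argmax ties are broken by the higher mean probability over
the 26-neighborhood (the 3x3x3 cube minus the center, clipped at grid
borders); a residual exact tie falls back to the lower cluster index with a
logged warning. A modal ("median") filter over the same neighborhood is
available to smooth single-voxel islands out of categorical label maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .io import LabelVolume, VolumeGrid
from .similarity import SimilarityMatrix, scan_order_voxels

__all__ = [
    "SubjectParcellation",
    "GroupProbabilityMaps",
    "MPMVolume",
    "spectral_cluster",
    "spectral_labels",
    "align_labels",
    "median_filter_labels",
    "group_probability_maps",
    "build_mpm",
]

logger = logging.getLogger(__name__)

_NEIGHBOR_KERNEL = np.ones((3, 3, 3))
_NEIGHBOR_KERNEL[1, 1, 1] = 0.0  # 26-neighborhood: cube minus center


@dataclass
class SubjectParcellation:
    """One subject's cluster labels (1..k in-mask, 0 outside)."""

    subject_id: str
    k: int
    labels: LabelVolume

    def __post_init__(self) -> None:
        found = self.labels.label_set - {0}
        if not found <= set(range(1, self.k + 1)):
            raise ValueError(
                f"labels {sorted(found)} exceed k={self.k} for subject "
                f"{self.subject_id}"
            )

    @property
    def grid(self) -> VolumeGrid:
        return self.labels.grid


@dataclass
class GroupProbabilityMaps:
    """Per-cluster voxelwise labeling frequencies across aligned subjects."""

    k: int
    maps: np.ndarray  # (k, *grid.shape), values in [0, 1]
    grid: VolumeGrid
    n_subjects: int

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        if maps.shape != (self.k, *self.grid.shape):
            raise ValueError(
                f"maps shape {maps.shape} != (k={self.k}, grid {self.grid.shape})"
            )
        if maps.min() < -1e-12 or maps.max() > 1 + 1e-12:
            raise ValueError("probabilities must lie in [0, 1]")
        if maps.sum(axis=0).max() > 1 + 1e-9:
            raise ValueError("per-voxel probabilities must sum to at most 1")
        self.maps = np.clip(maps, 0.0, 1.0)


@dataclass
class MPMVolume:
    """Group maximum probability map: the modal cluster per voxel."""

    labels: LabelVolume
    k: int


def _embed_and_kmeans(
    affinity: np.ndarray, k: int, rng_seed: int
) -> np.ndarray:
    """Symmetric normalized spectral embedding + row-normalized k-means."""
    degree = affinity.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(degree, 1e-300))
    M = affinity * inv_sqrt[:, None] * inv_sqrt[None, :]
    M = (M + M.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(M)
    embedding = eigvecs[:, -k:]  # top-k eigenvectors
    norms = np.linalg.norm(embedding, axis=1, keepdims=True)
    embedding = embedding / np.maximum(norms, 1e-300)
    km = KMeans(n_clusters=k, n_init=10, random_state=rng_seed)
    return km.fit_predict(embedding)


def spectral_labels(sim: SimilarityMatrix, k: int, rng_seed: int) -> np.ndarray:
    """Cluster a similarity matrix into labels 1..k (one per row).

    The affinity is the similarity with negatives clipped to 0 and a unit
    diagonal; the embedding uses the symmetric normalized graph operator. If
    the affinity graph is disconnected the clustering proceeds per component
    (clusters shared out proportionally to component size); components too
    small to receive a cluster are merged into the cluster with the highest
    mean affinity.
    """
    n = sim.n_voxels
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    affinity = np.clip(sim.values, 0.0, None)
    np.fill_diagonal(affinity, 1.0)

    n_comp, comp_of = connected_components(affinity > 0, directed=False)
    labels = np.zeros(n, dtype=np.int32)
    if n_comp == 1:
        labels = _embed_and_kmeans(affinity, k, rng_seed).astype(np.int32) + 1
        return labels

    logger.warning(
        "affinity graph has %d disconnected components; clustering per component",
        n_comp,
    )
    sizes = np.bincount(comp_of, minlength=n_comp)
    order = np.argsort(sizes)[::-1]
    n_major = min(n_comp, k)
    major = order[:n_major]
    # largest-remainder share of k clusters over the major components
    share = np.ones(n_major, dtype=int)
    remaining = k - n_major
    if remaining > 0:
        quota = sizes[major] / sizes[major].sum() * remaining
        share += np.floor(quota).astype(int)
        frac_order = np.argsort(quota - np.floor(quota))[::-1]
        for i in frac_order[: remaining - int(np.floor(quota).sum())]:
            share[i] += 1
    next_label = 1
    for comp, k_c in zip(major, share):
        rows = np.flatnonzero(comp_of == comp)
        k_eff = int(min(k_c, len(rows)))
        if k_eff < k_c:
            logger.warning(
                "component of size %d cannot host %d clusters", len(rows), k_c
            )
        if k_eff <= 1:
            labels[rows] = next_label
            next_label += 1
        else:
            sub = SimilarityMatrix(values=sim.values[np.ix_(rows, rows)])
            labels[rows] = spectral_labels(sub, k_eff, rng_seed) + (next_label - 1)
            next_label += k_eff
    # small leftover components: merge into the cluster with max mean affinity
    for comp in order[n_major:]:
        rows = np.flatnonzero(comp_of == comp)
        best, best_aff = 1, -np.inf
        for c in range(1, labels.max() + 1):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            aff = affinity[np.ix_(rows, members)].mean()
            if aff > best_aff:
                best, best_aff = c, aff
        labels[rows] = best
    return labels


def spectral_cluster(
    sim: SimilarityMatrix,
    seed_mask: LabelVolume,
    k: int,
    rng_seed: int,
    subject_id: str = "subject",
) -> SubjectParcellation:
    """Spectral-cluster a subject's similarity matrix onto its seed mask.

    Rows of ``sim`` correspond to the in-mask voxels of ``seed_mask`` in scan
    order (x fastest, then y, then z).
    """
    coords = scan_order_voxels(seed_mask)
    if len(coords) != sim.n_voxels:
        raise ValueError(
            f"similarity has {sim.n_voxels} rows but seed mask has "
            f"{len(coords)} voxels"
        )
    flat = spectral_labels(sim, k, rng_seed)
    labels = np.zeros(seed_mask.grid.shape, dtype=np.int32)
    labels[tuple(coords.T)] = flat
    return SubjectParcellation(
        subject_id=subject_id,
        k=k,
        labels=LabelVolume(grid=seed_mask.grid, labels=labels),
    )


def _overlap_matrix(a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    """(k, k) voxel-overlap counts between two 1..k label arrays."""
    joint = (a > 0) & (b > 0)
    idx = (a[joint] - 1) * k + (b[joint] - 1)
    return np.bincount(idx, minlength=k * k).reshape(k, k)


def align_labels(
    parc: SubjectParcellation, reference: SubjectParcellation
) -> SubjectParcellation:
    """Permute cluster labels to best match a reference parcellation.

    The permutation maximizes total voxel overlap with the reference (optimal
    bipartite assignment); the partition itself is unchanged.
    """
    parc.grid.require_match(reference.grid, "label alignment")
    if parc.k != reference.k:
        raise ValueError(f"k mismatch: {parc.k} vs {reference.k}")
    overlap = _overlap_matrix(parc.labels.labels, reference.labels.labels, parc.k)
    rows, cols = linear_sum_assignment(-overlap)
    perm = np.zeros(parc.k + 1, dtype=np.int32)
    perm[rows + 1] = cols + 1
    return SubjectParcellation(
        subject_id=parc.subject_id,
        k=parc.k,
        labels=LabelVolume(grid=parc.grid, labels=perm[parc.labels.labels]),
    )


def _neighbor_label_counts(labels: np.ndarray, k: int) -> np.ndarray:
    """(k, *shape) counts of each in-mask label over the 26-neighborhood."""
    counts = np.empty((k, *labels.shape))
    for c in range(1, k + 1):
        counts[c - 1] = ndimage.convolve(
            (labels == c).astype(float), _NEIGHBOR_KERNEL, mode="constant", cval=0.0
        )
    return np.rint(counts).astype(np.int64)


def median_filter_labels(parc: SubjectParcellation) -> SubjectParcellation:
    """Single-pass modal filter of labels over the 26-neighborhood.

    Each in-mask voxel takes the most frequent label among its in-mask
    26-neighbors; a tie for the mode keeps the voxel's original label.
    Out-of-mask voxels are untouched. This is the order-free analogue of
    median filtering for categorical data.
    """
    labels = parc.labels.labels
    counts = _neighbor_label_counts(labels, parc.k)
    top = counts.max(axis=0)
    n_top = (counts == top[None]).sum(axis=0)
    modal = counts.argmax(axis=0).astype(np.int32) + 1
    out = labels.copy()
    inmask = labels > 0
    decided = inmask & (n_top == 1) & (top > 0)
    out[decided] = modal[decided]
    return SubjectParcellation(
        subject_id=parc.subject_id,
        k=parc.k,
        labels=LabelVolume(grid=parc.grid, labels=out),
    )


def group_probability_maps(
    parcs: list[SubjectParcellation],
) -> GroupProbabilityMaps:
    """Voxelwise labeling frequency per cluster across aligned subjects."""
    if not parcs:
        raise ValueError("need at least one parcellation")
    ref = parcs[0]
    for p in parcs[1:]:
        p.grid.require_match(ref.grid, "group probability maps")
        if p.k != ref.k:
            raise ValueError(f"k mismatch across subjects: {p.k} vs {ref.k}")
    maps = np.zeros((ref.k, *ref.grid.shape))
    for p in parcs:
        for c in range(1, ref.k + 1):
            maps[c - 1] += p.labels.labels == c
    maps /= len(parcs)
    return GroupProbabilityMaps(
        k=ref.k, maps=maps, grid=ref.grid, n_subjects=len(parcs)
    )


def build_mpm(maps: GroupProbabilityMaps) -> MPMVolume:
    """Assign each voxel to its most probable cluster.

    Exact probability ties are broken by the higher mean probability over the
    26-neighborhood (in-grid neighbors only); a residual exact tie goes to
    the lower cluster index and is logged. Voxels with zero probability for
    every cluster stay background.
    """
    P = maps.maps
    top = P.max(axis=0)
    support = top > 0
    winners = P.argmax(axis=0).astype(np.int32) + 1
    tied = support & ((P == top[None]).sum(axis=0) > 1)

    if tied.any():
        n_neighbors = ndimage.convolve(
            np.ones(maps.grid.shape), _NEIGHBOR_KERNEL, mode="constant", cval=0.0
        )
        neigh_mean = np.stack(
            [
                ndimage.convolve(P[c], _NEIGHBOR_KERNEL, mode="constant", cval=0.0)
                / n_neighbors
                for c in range(maps.k)
            ]
        )
        residual: list[tuple[int, ...]] = []
        for vox in np.argwhere(tied):
            vox = tuple(vox)
            contenders = np.flatnonzero(P[(slice(None), *vox)] == top[vox])
            means = neigh_mean[(contenders, *vox)]
            best = contenders[np.flatnonzero(means == means.max())]
            if len(best) > 1:
                residual.append(vox)
            winners[vox] = best[0] + 1
        if residual:
            logger.warning(
                "%d voxel(s) with a residual neighborhood-mean tie assigned "
                "to the lowest cluster index (first: %s)",
                len(residual),
                residual[0],
            )

    winners[~support] = 0
    return MPMVolume(
        labels=LabelVolume(grid=maps.grid, labels=winners), k=maps.k
    )
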