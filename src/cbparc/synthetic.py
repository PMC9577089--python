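"""Synthetic multi-subject cohorts with known ground truth.

Real inputs to connectivity-based parcellation are per-voxel streamline
counts from probabilistic tractography and region time series from
resting-state fMRI. This module generates stand-ins with planted structure so
every downstream stage (similarity, clustering, group maps, evaluation,
fingerprint matching) can be verified against a known answer:

* ``generate_cohort`` — a seed box partitioned into spatially contiguous
  clusters; each cluster has a target-connection propensity vector, each
  subject perturbs it multiplicatively, and each voxel draws a multinomial
  count vector with a fixed number of streamlines (preserving the per-voxel
  sum constraint real tractography output has).
* ``generate_timeseries`` — multivariate-normal region time series whose
  population correlation matrix is specified exactly (the functional pipeline
  only consumes Pearson r, so no hemodynamic model is simulated).
* ``generate_fingerprint_sets`` — two fingerprint sets with planted homolog
  pairs that share a base profile plus independent noise.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LabelVolume, VolumeGrid
from .regions import default_target_names
from .similarity import ConnectivityMatrix, scan_order_voxels, voxel_linear_index

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_timeseries",
    "generate_fingerprint_sets",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic tractography cohort.

    Defaults mirror the study conditions this package is exercised under:
    a dozen subjects, a 10 x 10 x 3 seed box (300 voxels, the scale of a
    small cortical area at ~1.4 mm resolution), two planted subregions,
    19 named targets, 2,000 streamlines seeded per voxel, and moderate
    between-subject variability.
    """

    n_subjects: int = 12
    seed_shape: tuple[int, int, int] = (10, 10, 3)
    k_true: int = 2
    n_targets: int = 19
    n_streamlines: int = 2000
    #: in [0, 1]; distance between cluster connection profiles (0 = identical)
    separation: float = 0.5
    #: log-normal sigma of per-subject multiplicative propensity jitter
    subject_jitter: float = 0.1
    #: in [0, 1); fraction of streamlines scattered uniformly over targets
    noise_floor: float = 0.05
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.seed_shape) != 3 or any(s < 1 for s in self.seed_shape):
            raise ValueError("seed_shape must be 3 positive integers")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.k_true > int(np.prod(self.seed_shape)):
            raise ValueError(
                f"k_true={self.k_true} exceeds the {int(np.prod(self.seed_shape))} "
                "seed voxels"
            )
        if self.n_targets < 2:
            raise ValueError("n_targets must be >= 2")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")
        if self.subject_jitter < 0:
            raise ValueError("subject_jitter must be >= 0")
        if not 0.0 <= self.noise_floor < 1.0:
            raise ValueError("noise_floor must lie in [0, 1)")
        if self.separation + self.noise_floor > 1.0 + 1e-12:
            raise ValueError("separation + noise_floor must be <= 1")


@dataclass
class SyntheticCohort:
    """Generated subjects plus the ground truth that produced them."""

    config: CohortConfig
    subjects: list[ConnectivityMatrix]
    ground_truth: LabelVolume
    #: (k_true, n_targets) cluster connection propensities (rows sum to 1)
    theta: np.ndarray
    target_names: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _planted_labels(shape: tuple[int, int, int], k: int) -> np.ndarray:
    """Partition a box into k contiguous slabs along its longest axis."""
    axis = int(np.argmax(shape))
    n = shape[axis]
    if n < k:
        raise ValueError(
            f"cannot plant {k} contiguous slabs along an axis of length {n}"
        )
    edges = np.linspace(0, n, k + 1).round().astype(int)
    labels = np.zeros(shape, dtype=np.int32)
    index = [slice(None)] * 3
    for c in range(k):
        index[axis] = slice(edges[c], edges[c + 1])
        labels[tuple(index)] = c + 1
    return labels


def _cluster_propensities(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """theta_c = (1 - separation) * base + separation * delta_c.

    ``base`` is a shared positive simplex vector; ``delta_c`` are
    cluster-specific simplex vectors with disjoint support (targets dealt
    round-robin to clusters), so separation=1 gives clusters disjoint
    high-mass targets.
    """
    k, m = config.k_true, config.n_targets
    base = rng.dirichlet(np.full(m, 5.0))
    delta = np.zeros((k, m))
    owner = np.arange(m) % k
    for c in range(k):
        support = owner == c
        weights = rng.random(int(support.sum())) + 0.5
        delta[c, support] = weights / weights.sum()
    return (1.0 - config.separation) * base[None, :] + config.separation * delta


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a cohort of per-subject streamline-count matrices.

    Voxel v of subject s in planted cluster c draws
    ``Multinomial(n_streamlines, (1 - noise_floor) * perturb_s(theta_c)
    + noise_floor * uniform)`` where ``perturb_s`` multiplies the propensity
    vector by per-subject log-normal factors (sigma = ``subject_jitter``)
    and renormalizes. Bit-identical under a fixed ``rng_seed``.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.rng_seed)

    shape = tuple(config.seed_shape)
    labels = _planted_labels(shape, config.k_true)
    grid = VolumeGrid(shape=shape, affine=np.eye(4))
    truth = LabelVolume(grid=grid, labels=labels)

    theta = _cluster_propensities(config, rng)
    coords = scan_order_voxels(truth)
    voxel_ids = voxel_linear_index(coords, shape)
    voxel_cluster = labels[tuple(coords.T)] - 1  # 0-based cluster per row
    target_names = default_target_names(config.n_targets)
    uniform = np.full(config.n_targets, 1.0 / config.n_targets)

    subjects: list[ConnectivityMatrix] = []
    for _ in range(config.n_subjects):
        jitter = rng.lognormal(
            mean=0.0, sigma=config.subject_jitter, size=theta.shape
        )
        theta_s = theta * jitter
        theta_s /= theta_s.sum(axis=1, keepdims=True)
        probs = (1.0 - config.noise_floor) * theta_s + config.noise_floor * uniform
        counts = np.empty((len(voxel_ids), config.n_targets), dtype=np.int64)
        for row, c in enumerate(voxel_cluster):
            counts[row] = rng.multinomial(config.n_streamlines, probs[c])
        subjects.append(
            ConnectivityMatrix(
                seed_voxel_ids=voxel_ids,
                target_ids=target_names,
                counts=counts,
            )
        )
    return SyntheticCohort(
        config=config,
        subjects=subjects,
        ground_truth=truth,
        theta=theta,
        target_names=target_names,
    )


def generate_timeseries(
    region_names: list[str],
    target_corr: np.ndarray,
    length: int,
    rng_seed: int,
) -> pd.DataFrame:
    """Region x time table with population correlation ``target_corr``.

    Draws i.i.d. multivariate-normal time points with covariance equal to the
    requested correlation matrix; sample correlations converge to the target
    at the usual 1/sqrt(length) rate.
    """
    names = list(region_names)
    C = np.asarray(target_corr, dtype=float)
    n = len(names)
    if C.shape != (n, n):
        raise ValueError(f"target_corr must be {n}x{n}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("target_corr must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("target_corr must have unit diagonal")
    eigvals, eigvecs = np.linalg.eigh((C + C.T) / 2.0)
    if eigvals.min() < -1e-8:
        raise ValueError(
            f"target_corr is not positive semi-definite (min eigenvalue "
            f"{eigvals.min():.3g})"
        )
    if length < 2:
        raise ValueError("length must be >= 2")
    # eigen factorization handles exactly singular targets (e.g. r = 1)
    L = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    rng = np.random.default_rng(rng_seed)
    X = rng.standard_normal((length, n)) @ L.T
    return pd.DataFrame(X.T, index=pd.Index(names, name="region"))


def generate_fingerprint_sets(
    n_regions_a: int,
    n_regions_b: int,
    n_targets: int,
    planted_pairs: list[tuple[int, int]],
    noise: float,
    rng_seed: int,
):
    """Two cross-species fingerprint sets with planted homolog pairs.

    Planted pairs share a base profile plus independent Gaussian noise of
    scale ``noise``; all other regions get independent profiles. Returns
    ``(set_a, set_b, planted_pairs)`` where the sets are
    :class:`~cbparc.fingerprints.FingerprintSet` instances.
    """
    from .fingerprints import Fingerprint, FingerprintSet

    for a, b in planted_pairs:
        if not (0 <= a < n_regions_a and 0 <= b < n_regions_b):
            raise ValueError(f"planted pair ({a}, {b}) out of range")
    if len({a for a, _ in planted_pairs}) != len(planted_pairs) or len(
        {b for _, b in planted_pairs}
    ) != len(planted_pairs):
        raise ValueError("planted pairs must be one-to-one")
    if noise < 0:
        raise ValueError("noise must be >= 0")

    rng = np.random.default_rng(rng_seed)
    targets = default_target_names(n_targets)
    values_a = rng.random((n_regions_a, n_targets))
    values_b = rng.random((n_regions_b, n_targets))
    for a, b in planted_pairs:
        base = rng.random(n_targets)
        values_a[a] = base + noise * rng.standard_normal(n_targets)
        values_b[b] = base + noise * rng.standard_normal(n_targets)

    def _make_set(species: str, values: np.ndarray) -> FingerprintSet:
        fps = [
            Fingerprint(
                region_id=f"{species}_{i + 1:02d}",
                target_names=list(targets),
                values=values[i],
                kind="structural",
            )
            for i in range(values.shape[0])
        ]
        return FingerprintSet(species=species, fingerprints=fps)

    return _make_set("A", values_a), _make_set("B", values_b), list(planted_pairs)
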