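"""Connectivity fingerprints and cross-species homolog matching.

A fingerprint is one seed region's vector of connection values over a fixed,
ordered set of target regions — streamline-derived connection probabilities
(structural) or resting-state Pearson correlations (functional). Because the
targets are chosen to be homologous across species, two species' fingerprint
sets live in a common coordinate system and regions can be compared
directly:

* min-max normalization maps each fingerprint's strongest target to 1 and
  weakest to 0, removing per-region scale;
* cosine similarity CS = sum(p_i q_i) / (||p|| ||q||), in [-1, 1], higher =
  more similar connection pattern;
* Manhattan distance MD = sum |p_i - q_i|, lower = more similar.

``match_homologs`` proposes, for every region of one set, the region of the
other set with the highest CS; MD is reported alongside and any disagreement
between the CS-best and MD-best candidate is flagged, never silently
resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import RegionSet
from .similarity import ConnectivityMatrix

__all__ = [
    "Fingerprint",
    "FingerprintSet",
    "HomologMatch",
    "extract_structural_fingerprint",
    "normalize_fingerprint",
    "cosine_similarity",
    "manhattan_distance",
    "fc_fingerprint",
    "threshold_targets",
    "match_homologs",
    "group_fingerprint",
]

logger = logging.getLogger(__name__)


@dataclass
class Fingerprint:
    """One region's connection values over an ordered target set."""

    region_id: str
    target_names: list[str]
    values: np.ndarray
    kind: str  # "structural" | "functional"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.target_names = list(self.target_names)
        if self.values.shape != (len(self.target_names),):
            raise ValueError("one value per target required")
        if self.kind not in ("structural", "functional"):
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprint values must be finite")
        if self.kind == "functional" and not self.normalized:
            if self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9:
                raise ValueError("functional fingerprint values must lie in [-1, 1]")
        if self.normalized:
            if abs(self.values.min()) > 1e-12 or abs(self.values.max() - 1) > 1e-12:
                raise ValueError("normalized fingerprint must span [0, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.target_names, name=self.region_id)


@dataclass
class FingerprintSet:
    """Fingerprints of one species, all on the same ordered target set."""

    species: str
    fingerprints: list[Fingerprint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fingerprints:
            raise ValueError("fingerprint set cannot be empty")
        ref = self.fingerprints[0].target_names
        for fp in self.fingerprints[1:]:
            if fp.target_names != ref:
                raise ValueError(
                    f"region {fp.region_id}: target order differs within set"
                )
        ids = [fp.region_id for fp in self.fingerprints]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids in fingerprint set")

    @property
    def target_names(self) -> list[str]:
        return self.fingerprints[0].target_names

    @property
    def region_ids(self) -> list[str]:
        return [fp.region_id for fp in self.fingerprints]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [fp.values for fp in self.fingerprints],
            index=pd.Index(self.region_ids, name="region"),
            columns=self.target_names,
        )


def extract_structural_fingerprint(
    conn: ConnectivityMatrix,
    seed_region: set[int] | np.ndarray,
    targets: RegionSet,
    samples_per_voxel: int,
    region_id: str = "seed",
) -> Fingerprint:
    """Connection probability from a seed region to each named target.

    value_j = (streamlines from the seed region reaching target j) /
    (region size x streamlines seeded per voxel) — i.e. the fraction of all
    seeded streamlines that reached the target.
    """
    if samples_per_voxel <= 0:
        raise ValueError("samples_per_voxel must be positive")
    seed_ids = np.asarray(sorted(set(int(v) for v in seed_region)))
    if seed_ids.size == 0:
        raise ValueError("empty seed region")
    unknown = [t for t in targets.names if t not in conn.target_ids]
    if unknown:
        raise ValueError(f"unknown target region(s): {unknown}")
    id_to_row = {int(v): i for i, v in enumerate(conn.seed_voxel_ids)}
    missing = [int(v) for v in seed_ids if int(v) not in id_to_row]
    if missing:
        raise ValueError(f"seed voxel(s) not in connectivity matrix: {missing[:5]}")
    rows = [id_to_row[int(v)] for v in seed_ids]
    cols = [conn.target_ids.index(t) for t in targets.names]
    totals = conn.counts[np.ix_(rows, cols)].sum(axis=0)
    values = totals / (len(seed_ids) * samples_per_voxel)
    return Fingerprint(
        region_id=region_id,
        target_names=list(targets.names),
        values=values,
        kind="structural",
    )


def normalize_fingerprint(fp: Fingerprint) -> Fingerprint:
    """Min-max normalize: strongest target -> 1, weakest -> 0. Idempotent."""
    lo = fp.values.min()
    hi = fp.values.max()
    if hi == lo:
        raise ValueError(f"degenerate fingerprint {fp.region_id!r}: all values equal")
    return replace(fp, values=(fp.values - lo) / (hi - lo), normalized=True)


def _check_comparable(p: Fingerprint, q: Fingerprint) -> None:
    if p.target_names != q.target_names:
        raise ValueError(
            f"target-order mismatch between {p.region_id!r} and {q.region_id!r}"
        )


def cosine_similarity(p: Fingerprint, q: Fingerprint) -> float:
    """CS = sum(p_i q_i) / (||p|| ||q||), in [-1, 1]."""
    _check_comparable(p, q)
    np_norm = np.linalg.norm(p.values)
    nq_norm = np.linalg.norm(q.values)
    if np_norm == 0 or nq_norm == 0:
        raise ValueError("cosine similarity undefined for an all-zero fingerprint")
    if np.array_equal(p.values, q.values):
        return 1.0  # exact on identical profiles (no sqrt round-trip error)
    return float(np.clip(p.values @ q.values / (np_norm * nq_norm), -1.0, 1.0))


def manhattan_distance(p: Fingerprint, q: Fingerprint) -> float:
    """MD = sum |p_i - q_i| >= 0."""
    _check_comparable(p, q)
    return float(np.abs(p.values - q.values).sum())


def fc_fingerprint(
    timeseries: pd.DataFrame,
    seed_region: str,
    targets: RegionSet,
) -> Fingerprint:
    """Functional fingerprint: Pearson r of the seed series with each target.

    ``timeseries`` is a region x time table (regions as rows).
    """
    for name in [seed_region, *targets.names]:
        if name not in timeseries.index:
            raise ValueError(f"region {name!r} missing from time-series table")
    if timeseries.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    seed = timeseries.loc[seed_region].to_numpy(dtype=float)
    if seed.std() == 0:
        raise ValueError(f"constant time series for region {seed_region!r}")
    values = np.empty(len(targets))
    for j, name in enumerate(targets.names):
        y = timeseries.loc[name].to_numpy(dtype=float)
        if y.std() == 0:
            raise ValueError(f"constant time series for region {name!r}")
        values[j] = np.corrcoef(seed, y)[0, 1]
    return Fingerprint(
        region_id=seed_region,
        target_names=list(targets.names),
        values=values,
        kind="functional",
    )


def threshold_targets(fp: Fingerprint, r_min: float) -> pd.Series:
    """Targets with value strictly above ``r_min``, sorted descending.

    Mirrors the connection-point selection used for functional fingerprints
    (e.g. r > 0.4 for region bar charts, r > 0.5 for fingerprint wheels);
    the inequality is strict, and an empty result is allowed.
    """
    if fp.kind != "functional":
        raise ValueError("threshold_targets applies to functional fingerprints")
    s = fp.to_series()
    s = s[s > r_min]
    return s.sort_values(ascending=False, kind="stable")


@dataclass
class HomologMatch:
    """Cross-set CS/MD matrices and the proposed per-region matches."""

    cs: pd.DataFrame  # regions of set_a x regions of set_b
    md: pd.DataFrame
    #: per region of set_a: CS-best region of set_b
    best_by_cs: pd.Series
    best_by_md: pd.Series
    #: regions of set_a whose CS-best and MD-best candidates differ
    disagreements: list[str]
    #: regions of set_a with an exact tie for the CS-best candidate
    ties: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Long-form pairing table: one row per (a, b) candidate pair."""
        rows = []
        for a in self.cs.index:
            for b in self.cs.columns:
                rows.append(
                    {
                        "region_a": a,
                        "region_b": b,
                        "cs": self.cs.at[a, b],
                        "md": self.md.at[a, b],
                        "cs_best": self.best_by_cs[a] == b,
                        "md_best": self.best_by_md[a] == b,
                    }
                )
        return pd.DataFrame(rows)


def match_homologs(set_a: FingerprintSet, set_b: FingerprintSet) -> HomologMatch:
    """Propose homolog matches from set_a regions to set_b regions.

    Requires both sets on the same ordered targets and consistently
    normalized (both raw or both min-max normalized). The proposed match per
    region is the CS argmax; the MD argmin is reported alongside, and
    regions where the two criteria disagree are flagged.
    """
    if set_a.target_names != set_b.target_names:
        raise ValueError("fingerprint sets have different target orders")
    norms = {fp.normalized for fp in set_a.fingerprints + set_b.fingerprints}
    if len(norms) > 1:
        raise ValueError(
            "sets mix normalized and raw fingerprints; normalize consistently"
        )
    ids_a, ids_b = set_a.region_ids, set_b.region_ids
    cs = pd.DataFrame(index=ids_a, columns=ids_b, dtype=float)
    md = pd.DataFrame(index=ids_a, columns=ids_b, dtype=float)
    for fa in set_a.fingerprints:
        for fb in set_b.fingerprints:
            cs.at[fa.region_id, fb.region_id] = cosine_similarity(fa, fb)
            md.at[fa.region_id, fb.region_id] = manhattan_distance(fa, fb)

    best_by_cs = cs.idxmax(axis=1)
    best_by_md = md.idxmin(axis=1)
    ties = [
        a
        for a in ids_a
        if int((cs.loc[a] == cs.loc[a].max()).sum()) > 1
    ]
    for a in ties:
        tied = cs.columns[cs.loc[a] == cs.loc[a].max()].tolist()
        logger.warning("region %s: CS tie between candidates %s", a, tied)
    disagreements = [a for a in ids_a if best_by_cs[a] != best_by_md[a]]
    for a in disagreements:
        logger.warning(
            "region %s: CS-best %s but MD-best %s (reported, not resolved)",
            a,
            best_by_cs[a],
            best_by_md[a],
        )
    return HomologMatch(
        cs=cs,
        md=md,
        best_by_cs=best_by_cs,
        best_by_md=best_by_md,
        disagreements=disagreements,
        ties=ties,
    )


def group_fingerprint(fps: list[Fingerprint], region_id: str | None = None) -> Fingerprint:
    """Average per-subject fingerprints into one group fingerprint.

    Structural fingerprints are min-max normalized per subject before
    averaging (so every subject contributes on the same scale); functional
    fingerprints are averaged on the Fisher-z scale and transformed back
    (the variance-stabilizing default for correlations).
    """
    if not fps:
        raise ValueError("no fingerprints to combine")
    kinds = {fp.kind for fp in fps}
    if len(kinds) > 1:
        raise ValueError("cannot mix structural and functional fingerprints")
    ref = fps[0]
    for fp in fps[1:]:
        _check_comparable(ref, fp)
    kind = kinds.pop()
    if kind == "structural":
        stack = np.stack([normalize_fingerprint(fp).values for fp in fps])
        values = stack.mean(axis=0)
        normalized = False  # mean of normalized profiles need not span [0, 1]
    else:
        z = np.arctanh(np.clip(np.stack([fp.values for fp in fps]), -1 + 1e-12, 1 - 1e-12))
        values = np.tanh(z.mean(axis=0))
        normalized = False
    return Fingerprint(
        region_id=region_id or ref.region_id,
        target_names=ref.target_names,
        values=values,
        kind=kind,
        normalized=normalized,
    )
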