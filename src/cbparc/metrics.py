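"""Partition-agreement metrics and the optimal-cluster-number rule.

Agreement between two label volumes is measured on the voxels labeled in
both (background excluded) through their contingency table:

* Cramér's V — sqrt(chi2 / (N * (min(r, c) - 1))), association in [0, 1];
* NMI — 2 I(X;Y) / (H(X) + H(Y)), normalized mutual information in [0, 1];
* VI — H(X) + H(Y) - 2 I(X;Y), the variation of information, a metric on
  partitions (natural logarithms throughout, so VI is in nats);
* multi-label and binary Dice, plus a sensitivity/specificity/IoU report.

Reproducibility of a cohort parcellation is scored by split-half
resampling: subjects are repeatedly divided into two halves, a maximum
probability map is built per half, and a chosen metric compares the two
maps. Averaged over repetitions and computed for each candidate K, these
scores feed ``select_optimal_k``, which ranks K per index (higher better for
CV/Dice/NMI, lower for VI) and returns the K with the best total rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import LabelVolume
from .parcellation import SubjectParcellation, build_mpm, group_probability_maps

__all__ = [
    "ContingencyTable",
    "EvaluationReport",
    "contingency",
    "dice_multilabel",
    "cramers_v",
    "nmi",
    "variation_of_information",
    "overlap_report",
    "split_half_consistency",
    "split_half_table",
    "select_optimal_k",
    "METRICS",
]

logger = logging.getLogger(__name__)

#: Metric name -> (higher_is_better,)
METRICS = {"cv": True, "dice": True, "nmi": True, "vi": False}


@dataclass
class ContingencyTable:
    """Joint label counts of two partitions over their common support."""

    counts: np.ndarray  # (r, c) non-negative integers
    row_labels: list[int]
    col_labels: list[int]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("contingency counts must be 2-D")
        if counts.min(initial=0) < 0:
            raise ValueError("contingency counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """Per-K table of split-half consistency scores.

    ``means``/``sds`` are DataFrames indexed by K with one column per metric
    (cv, dice, nmi, vi).
    """

    means: pd.DataFrame
    sds: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in METRICS if m not in self.means.columns]
        if missing:
            raise ValueError(f"report is missing metrics: {missing}")
        if not np.all(np.isfinite(self.means[list(METRICS)].to_numpy())):
            raise ValueError("report contains non-finite values")

    @classmethod
    def from_values(
        cls,
        ks: list[int],
        cv: list[float],
        dice: list[float],
        nmi: list[float],
        vi: list[float],
        **metadata,
    ) -> "EvaluationReport":
        means = pd.DataFrame(
            {"cv": cv, "dice": dice, "nmi": nmi, "vi": vi},
            index=pd.Index(ks, name="k"),
        )
        return cls(means=means, metadata=metadata)


def contingency(a: LabelVolume, b: LabelVolume) -> ContingencyTable:
    """Contingency table over voxels labeled > 0 in both volumes."""
    a.grid.require_match(b.grid, "contingency table")
    joint = (a.labels > 0) & (b.labels > 0)
    if not joint.any():
        raise ValueError("no voxels labeled in both volumes")
    x = a.labels[joint]
    y = b.labels[joint]
    row_labels = np.unique(x)
    col_labels = np.unique(y)
    ri = np.searchsorted(row_labels, x)
    ci = np.searchsorted(col_labels, y)
    counts = np.bincount(
        ri * len(col_labels) + ci, minlength=len(row_labels) * len(col_labels)
    ).reshape(len(row_labels), len(col_labels))
    return ContingencyTable(
        counts=counts,
        row_labels=row_labels.tolist(),
        col_labels=col_labels.tolist(),
    )


def dice_multilabel(
    a: LabelVolume, b: LabelVolume
) -> tuple[float, dict[int, float]]:
    """Mean and per-label Dice overlap of two aligned label volumes.

    Per label c: 2|A_c ∩ B_c| / (|A_c| + |B_c|) with A_c = (a == c). The mean
    runs over labels present in either volume; a label absent from both
    contributes nothing.
    """
    a.grid.require_match(b.grid, "Dice")
    labels = sorted((a.label_set | b.label_set) - {0})
    per_label: dict[int, float] = {}
    for c in labels:
        A = a.labels == c
        B = b.labels == c
        denom = int(A.sum()) + int(B.sum())
        if denom == 0:
            continue
        per_label[c] = 2.0 * int((A & B).sum()) / denom
    if not per_label:
        raise ValueError("no foreground labels in either volume")
    return float(np.mean(list(per_label.values()))), per_label


def _chi2(counts: np.ndarray) -> float:
    """Pearson chi-square statistic of a contingency table."""
    N = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / N
    mask = expected > 0
    return float(((counts - expected)[mask] ** 2 / expected[mask]).sum())


def cramers_v(table: ContingencyTable) -> float:
    """Cramér's V association of a contingency table, in [0, 1]."""
    r, c = table.counts.shape
    if r < 2 or c < 2:
        raise ValueError(f"Cramér's V undefined for a {r}x{c} table")
    if table.total < 1:
        raise ValueError("empty contingency table")
    nonzero_rows = int((table.counts.sum(axis=1) > 0).sum())
    nonzero_cols = int((table.counts.sum(axis=0) > 0).sum())
    if nonzero_rows < 2 or nonzero_cols < 2:
        logger.warning("degenerate marginal in contingency table; Cramér's V = 0")
        return 0.0
    v = np.sqrt(_chi2(table.counts) / (table.total * (min(r, c) - 1)))
    return float(min(v, 1.0))


def _entropies(counts: np.ndarray) -> tuple[float, float, float]:
    """(H(X), H(Y), I(X;Y)) in nats from a contingency table."""
    N = counts.sum()
    p = counts / N
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = float(-np.sum(px[px > 0] * np.log(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log(py[py > 0])))
    nz = p > 0
    outer = np.outer(px, py)
    mi = float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))
    return hx, hy, max(mi, 0.0)


def nmi(table: ContingencyTable) -> float:
    """Normalized mutual information 2I/(H(X)+H(Y)), in [0, 1]."""
    if table.total < 1:
        raise ValueError("empty contingency table")
    hx, hy, mi = _entropies(table.counts)
    if hx + hy == 0:
        logger.warning("both partitions are single-cluster; NMI = 0")
        return 0.0
    return float(np.clip(2.0 * mi / (hx + hy), 0.0, 1.0))


def variation_of_information(table: ContingencyTable) -> float:
    """VI = H(X) + H(Y) - 2 I(X;Y), in nats (0 iff identical partitions)."""
    if table.total < 1:
        raise ValueError("empty contingency table")
    hx, hy, mi = _entropies(table.counts)
    return float(max(hx + hy - 2.0 * mi, 0.0))


def overlap_report(
    a: LabelVolume, b: LabelVolume, label: int
) -> dict[str, float]:
    """Dice, sensitivity, specificity and IoU of one label, a = reference.

    Binary masks A = (a == label), B = (b == label) over the full grid:
    dice = 2|A∩B|/(|A|+|B|), sensitivity = |A∩B|/|A|,
    specificity = |¬A∩¬B|/|¬A|, iou = |A∩B|/|A∪B|.
    """
    a.grid.require_match(b.grid, "overlap report")
    A = a.labels == label
    if not A.any():
        raise ValueError(f"label {label} absent from the reference volume")
    B = b.labels == label
    inter = int((A & B).sum())
    union = int((A | B).sum())
    n_a, n_b = int(A.sum()), int(B.sum())
    n_not_a = A.size - n_a
    return {
        "dice": 2.0 * inter / (n_a + n_b) if n_a + n_b else 0.0,
        "sensitivity": inter / n_a,
        "specificity": int((~A & ~B).sum()) / n_not_a if n_not_a else 1.0,
        "iou": inter / union if union else 0.0,
    }


def _metric_between(a: LabelVolume, b: LabelVolume, metric: str) -> float:
    if metric == "dice":
        return dice_multilabel(a, b)[0]
    table = contingency(a, b)
    if metric == "cv":
        if min(table.counts.shape) < 2:
            logger.warning("single-label contingency; Cramér's V = 0")
            return 0.0
        return cramers_v(table)
    if metric == "nmi":
        return nmi(table)
    if metric == "vi":
        return variation_of_information(table)
    raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")


def split_half_consistency(
    parcs: list[SubjectParcellation],
    metric: str,
    n_reps: int,
    rng_seed: int,
) -> tuple[float, float]:
    """Mean and sd of a metric between MPMs of random half-cohorts.

    Each repetition splits the subjects into two equal halves (sizes differ
    by one for odd cohorts), builds a maximum probability map per half, and
    scores the two maps with ``metric``. Deterministic given ``rng_seed``.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if len(parcs) < 4:
        raise ValueError("split-half consistency needs at least 4 subjects")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    table = split_half_table(parcs, [metric], n_reps, rng_seed)
    return table[metric]


def split_half_table(
    parcs: list[SubjectParcellation],
    metrics: list[str],
    n_reps: int,
    rng_seed: int,
) -> dict[str, tuple[float, float]]:
    """Split-half means/sds for several metrics sharing the same splits.

    Equivalent to calling :func:`split_half_consistency` per metric with the
    same seed (the random splits depend only on the seed), but each half-MPM
    is built once per repetition instead of once per metric.
    """
    unknown = [m for m in metrics if m not in METRICS]
    if unknown:
        raise ValueError(f"unknown metric(s) {unknown}; choose from {sorted(METRICS)}")
    if len(parcs) < 4:
        raise ValueError("split-half consistency needs at least 4 subjects")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n = len(parcs)
    half = n // 2
    values = {m: np.empty(n_reps) for m in metrics}
    for rep in range(n_reps):
        order = rng.permutation(n)
        mpm_a = build_mpm(group_probability_maps([parcs[i] for i in order[:half]]))
        mpm_b = build_mpm(group_probability_maps([parcs[i] for i in order[half:]]))
        for m in metrics:
            values[m][rep] = _metric_between(mpm_a.labels, mpm_b.labels, m)
    return {m: (float(v.mean()), float(v.std())) for m, v in values.items()}


def select_optimal_k(report: EvaluationReport | pd.DataFrame) -> int:
    """Choose the cluster number with the best total rank across indices.

    CV, Dice and NMI are ranked higher-is-better, VI lower-is-better; ranks
    are summed per K and the K with the lowest total wins. An exact tie in
    the total goes to the smaller K (logged).
    """
    means = report.means if isinstance(report, EvaluationReport) else report
    if len(means) < 2:
        raise ValueError("report must cover at least 2 values of K")
    missing = [m for m in METRICS if m not in means.columns]
    if missing:
        raise ValueError(f"report is missing metrics: {missing}")
    totals = np.zeros(len(means))
    for metric, higher_better in METRICS.items():
        col = means[metric].to_numpy(dtype=float)
        totals += rankdata(-col if higher_better else col, method="average")
    ks = np.asarray(means.index, dtype=int)
    best_total = totals.min()
    candidates = ks[totals == best_total]
    if len(candidates) > 1:
        logger.warning(
            "optimal-K rank tie between %s; choosing smallest K=%d",
            candidates.tolist(),
            int(candidates.min()),
        )
    return int(candidates.min())
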