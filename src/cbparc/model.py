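"""Model/results interface for connectivity-based parcellation.

:class:`ConnectivityParcellation` is built from a cohort of per-subject
seed-voxel x target streamline-count matrices on a shared seed mask;
``fit()`` runs the whole pipeline — voxelwise profile correlation, spectral
clustering per subject for every candidate K, cross-subject label alignment,
group probability maps and the maximum probability map (MPM), split-half
consistency scoring, and the optimal-K rank rule — and returns a
:class:`ParcellationResults` carrying every intermediate product plus a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LabelVolume
from .metrics import (
    METRICS,
    EvaluationReport,
    dice_multilabel,
    select_optimal_k,
    split_half_table,
)
from .parcellation import (
    GroupProbabilityMaps,
    MPMVolume,
    SubjectParcellation,
    align_labels,
    build_mpm,
    group_probability_maps,
    median_filter_labels,
    spectral_cluster,
)
from .similarity import ConnectivityMatrix, build_similarity

__all__ = ["ConnectivityParcellation", "ParcellationResults"]


class ConnectivityParcellation:
    """Connectivity-based parcellation of a seed region across a cohort.

    Parameters
    ----------
    connectivity
        One streamline-count matrix per subject, rows in the seed mask's
        scan order (x fastest, then y, then z).
    seed_mask
        Label volume whose positive voxels define the seed region.
    subject_ids
        Optional names; defaults to ``sub-01..``.

    Examples
    --------
    >>> from cbparc import generate_cohort, ConnectivityParcellation
    >>> cohort = generate_cohort()
    >>> res = ConnectivityParcellation.from_cohort(cohort).fit(n_reps=50)
    >>> res.k_opt
    2
    """

    def __init__(
        self,
        connectivity: list[ConnectivityMatrix],
        seed_mask: LabelVolume,
        subject_ids: list[str] | None = None,
    ) -> None:
        if not connectivity:
            raise ValueError("need at least one subject")
        n_vox = seed_mask.n_voxels()
        for i, conn in enumerate(connectivity):
            if conn.n_voxels != n_vox:
                raise ValueError(
                    f"subject {i}: {conn.n_voxels} rows but seed mask has "
                    f"{n_vox} voxels"
                )
        if subject_ids is None:
            subject_ids = [f"sub-{i + 1:02d}" for i in range(len(connectivity))]
        if len(subject_ids) != len(connectivity):
            raise ValueError("one subject id per connectivity matrix required")
        self.connectivity = list(connectivity)
        self.seed_mask = seed_mask
        self.subject_ids = list(subject_ids)

    @classmethod
    def from_cohort(cls, cohort) -> "ConnectivityParcellation":
        """Build the model from a :class:`~cbparc.synthetic.SyntheticCohort`.

        The cohort's ground-truth volume supplies the seed-mask geometry
        (every in-mask voxel), not the cluster assignment.
        """
        mask = LabelVolume(
            grid=cohort.ground_truth.grid,
            labels=(cohort.ground_truth.labels > 0).astype(np.int32),
        )
        return cls(connectivity=cohort.subjects, seed_mask=mask)

    @property
    def n_subjects(self) -> int:
        return len(self.connectivity)

    def fit(
        self,
        k_range: tuple[int, int] = (2, 5),
        rng_seed: int = 0,
        n_reps: int = 100,
        median_filter: str = "mpm",
    ) -> "ParcellationResults":
        """Run the parcellation pipeline over a range of cluster numbers.

        Parameters
        ----------
        k_range
            Inclusive (k_min, k_max) of candidate subregion counts.
        rng_seed
            Seed for k-means restarts and the split-half resampling.
        n_reps
            Split-half repetitions per K and metric.
        median_filter
            Where to apply the modal 26-neighborhood filter: ``"mpm"``
            (default, smooths the group map), ``"subject"`` (each aligned
            subject map) or ``"none"``.
        """
        k_min, k_max = int(k_range[0]), int(k_range[1])
        if not 2 <= k_min <= k_max:
            raise ValueError(f"invalid k_range {k_range}")
        if median_filter not in ("mpm", "subject", "none"):
            raise ValueError("median_filter must be 'mpm', 'subject' or 'none'")

        sims = [build_similarity(conn) for conn in self.connectivity]
        ks = list(range(k_min, k_max + 1))
        parcs: dict[int, list[SubjectParcellation]] = {}
        prob_maps: dict[int, GroupProbabilityMaps] = {}
        mpms: dict[int, MPMVolume] = {}
        for k in ks:
            subject_parcs = [
                spectral_cluster(sim, self.seed_mask, k, rng_seed, subject_id=sid)
                for sim, sid in zip(sims, self.subject_ids)
            ]
            aligned = [subject_parcs[0]] + [
                align_labels(p, subject_parcs[0]) for p in subject_parcs[1:]
            ]
            if median_filter == "subject":
                aligned = [median_filter_labels(p) for p in aligned]
            parcs[k] = aligned
            prob_maps[k] = group_probability_maps(aligned)
            mpm = build_mpm(prob_maps[k])
            if median_filter == "mpm":
                mpm = MPMVolume(
                    labels=median_filter_labels(
                        SubjectParcellation("mpm", mpm.k, mpm.labels)
                    ).labels,
                    k=mpm.k,
                )
            mpms[k] = mpm

        means = {m: [] for m in METRICS}
        sds = {m: [] for m in METRICS}
        can_resample = self.n_subjects >= 4 and n_reps > 0
        for k in ks:
            if can_resample:
                table = split_half_table(parcs[k], list(METRICS), n_reps, rng_seed)
            else:
                table = {m: (float("nan"), float("nan")) for m in METRICS}
            for metric in METRICS:
                means[metric].append(table[metric][0])
                sds[metric].append(table[metric][1])

        index = pd.Index(ks, name="k")
        report = None
        k_opt = None
        if can_resample:
            report = EvaluationReport(
                means=pd.DataFrame(means, index=index),
                sds=pd.DataFrame(sds, index=index),
                metadata={"n_reps": n_reps, "rng_seed": rng_seed},
            )
            k_opt = select_optimal_k(report)
        return ParcellationResults(
            model=self,
            k_range=(k_min, k_max),
            rng_seed=rng_seed,
            n_reps=n_reps if can_resample else 0,
            subject_parcellations=parcs,
            prob_maps=prob_maps,
            mpms=mpms,
            report=report,
            k_opt=k_opt,
        )


@dataclass
class ParcellationResults:
    """Everything the parcellation pipeline produced, per candidate K."""

    model: ConnectivityParcellation
    k_range: tuple[int, int]
    rng_seed: int
    n_reps: int
    subject_parcellations: dict[int, list[SubjectParcellation]]
    prob_maps: dict[int, GroupProbabilityMaps]
    mpms: dict[int, MPMVolume]
    report: EvaluationReport | None = None
    k_opt: int | None = None
    _truth_cache: dict = field(default_factory=dict, repr=False)

    @property
    def ks(self) -> list[int]:
        return sorted(self.mpms)

    def mpm(self, k: int | None = None) -> MPMVolume:
        """The group maximum probability map at K (default: selected K)."""
        if k is None:
            if self.k_opt is None:
                raise ValueError("no optimal K available; pass k explicitly")
            k = self.k_opt
        return self.mpms[k]

    def dice_vs(self, truth: LabelVolume, k: int | None = None) -> float:
        """Mean per-cluster Dice of the MPM against a reference labeling.

        Labels are aligned to the reference by optimal assignment first, so
        the score is invariant to cluster numbering.
        """
        mpm = self.mpm(k)
        ref = SubjectParcellation("truth", mpm.k, truth)
        test = SubjectParcellation("mpm", mpm.k, mpm.labels)
        aligned = align_labels(test, ref)
        return dice_multilabel(aligned.labels, truth)[0]

    def subject_dice_vs(self, truth: LabelVolume, k: int | None = None) -> list[float]:
        """Per-subject aligned mean Dice against a reference labeling."""
        if k is None:
            if self.k_opt is None:
                raise ValueError("no optimal K available; pass k explicitly")
            k = self.k_opt
        out = []
        for p in self.subject_parcellations[k]:
            ref = SubjectParcellation("truth", p.k, truth)
            aligned = align_labels(p, ref)
            out.append(dice_multilabel(aligned.labels, truth)[0])
        return out

    def summary(self) -> str:
        """Statsmodels-style text summary of the fit."""
        m = self.model
        lines = []
        width = 58
        lines.append("Connectivity-Based Parcellation Results".center(width))
        lines.append("=" * width)
        lines.append(
            f"Subjects: {m.n_subjects:<6d} Seed voxels: "
            f"{m.seed_mask.n_voxels():<8d} Targets: {m.connectivity[0].n_targets}"
        )
        lines.append(
            f"K range: {self.k_range[0]}-{self.k_range[1]:<7d} Split-half reps: "
            f"{self.n_reps:<6d} Seed: {self.rng_seed}"
        )
        lines.append("-" * width)
        if self.report is not None:
            lines.append(f"{'K':>4} {'CV':>10} {'Dice':>10} {'NMI':>10} {'VI':>10}")
            for k in self.ks:
                row = self.report.means.loc[k]
                lines.append(
                    f"{k:>4} {row['cv']:>10.4f} {row['dice']:>10.4f} "
                    f"{row['nmi']:>10.4f} {row['vi']:>10.4f}"
                )
            lines.append("-" * width)
            lines.append(
                f"Selected number of subregions (rank rule): K = {self.k_opt}"
            )
        else:
            lines.append("Split-half evaluation not run (fewer than 4 subjects).")
        lines.append("=" * width)
        return "\n".join(lines)

    def plot_evaluation(self, ax=None):
        """Line plot of the split-half indices over K (one line per metric)."""
        from .plotting import plot_evaluation_report

        if self.report is None:
            raise ValueError("no evaluation report to plot")
        return plot_evaluation_report(self.report, ax=ax)
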