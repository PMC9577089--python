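"""Basic plots: fingerprint radar charts and evaluation-index trends."""

from __future__ import annotations

import numpy as np

from .fingerprints import Fingerprint
from .metrics import METRICS, EvaluationReport

__all__ = ["plot_fingerprint", "plot_evaluation_report"]


def plot_fingerprint(fps: Fingerprint | list[Fingerprint], ax=None):
    """Radar plot of one or more fingerprints sharing a target order."""
    import matplotlib.pyplot as plt

    if isinstance(fps, Fingerprint):
        fps = [fps]
    if not fps:
        raise ValueError("nothing to plot")
    targets = fps[0].target_names
    for fp in fps[1:]:
        if fp.target_names != targets:
            raise ValueError("fingerprints must share the same target order")
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    angles = np.linspace(0, 2 * np.pi, len(targets), endpoint=False)
    closed = np.concatenate([angles, angles[:1]])
    for fp in fps:
        values = np.concatenate([fp.values, fp.values[:1]])
        ax.plot(closed, values, label=fp.region_id)
        ax.fill(closed, values, alpha=0.1)
    ax.set_xticks(angles)
    ax.set_xticklabels(targets, fontsize=7)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=7)
    return ax


def plot_evaluation_report(report: EvaluationReport, ax=None):
    """The per-K trend of each split-half index, one line per metric."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ks = report.means.index.to_numpy()
    for metric in METRICS:
        ax.plot(ks, report.means[metric], marker="o", label=metric.upper())
        if report.sds is not None:
            sd = report.sds[metric].to_numpy()
            ax.fill_between(
                ks,
                report.means[metric] - sd,
                report.means[metric] + sd,
                alpha=0.15,
            )
    ax.set_xlabel("number of subregions K")
    ax.set_ylabel("split-half index")
    ax.set_xticks(ks)
    ax.legend()
    return ax
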