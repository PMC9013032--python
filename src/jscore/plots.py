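"""Matplotlib figures for evaluation reports and score analytics."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from jscore.evaluation import EvalReport

__all__ = [
    "plot_roc_pr",
    "plot_score_distribution",
    "plot_trend",
    "plot_group_comparison",
]


def plot_roc_pr(reports: Sequence[EvalReport], path: str | Path) -> Path:
    """ROC (left) and PR (right) panels, one line per model variant."""
    fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(10, 4.5))
    for rep in reports:
        xs, ys = zip(*rep.roc_points)
        ax_roc.plot(xs, ys, label=f"{rep.variant} (AUC {rep.roc_auc:.3f})")
        xs, ys = zip(*rep.pr_points)
        ax_pr.plot(xs, ys, label=f"{rep.variant} (AUC {rep.pr_auc:.3f})")
    ax_roc.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax_roc.set_xlabel("False positive rate")
    ax_roc.set_ylabel("True positive rate")
    ax_roc.set_title(f"ROC ({reports[0].phase})")
    ax_roc.legend(loc="lower right", fontsize=8)
    ax_pr.set_xlabel("Recall")
    ax_pr.set_ylabel("Precision")
    ax_pr.set_title(f"Precision-Recall ({reports[0].phase})")
    ax_pr.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_score_distribution(dist: dict, path: str | Path) -> Path:
    """Histograms of J_Score_POA and J_Score from a distribution summary."""
    edges = dist["bin_edges"]
    centers = [(a + b) / 2 for a, b in zip(edges[:-1], edges[1:])]
    width = edges[1] - edges[0]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, key, title in zip(axes, ("j_score_poa", "j_score"), ("J_Score_POA", "J_Score")):
        ax.bar(centers, dist[key]["counts"], width=width)
        ax.set_xlabel(title)
        ax.set_title(
            f"{title}: {100 * dist[key]['proportion_at_one']:.1f}% at 1"
        )
    axes[0].set_ylabel("Encounters")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_trend(trend: dict, path: str | Path) -> Path:
    """Monthly mean J_Score and J_Score_POA with the non-POA gap."""
    months = list(trend)
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(months, [trend[m]["mean_j_score"] for m in months], "-o", label="J_Score")
    ax.plot(
        months,
        [trend[m]["mean_j_score_poa"] for m in months],
        "-s",
        label="J_Score_POA",
    )
    ax.set_ylabel("Mean score")
    ax.set_xlabel("Discharge month")
    ax.tick_params(axis="x", rotation=60, labelsize=7)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_group_comparison(groups: dict, path: str | Path, *, label: str = "CDS reviewed") -> Path:
    """Mean scores by CDI review/query group."""
    names = list(groups)
    x = range(len(names))
    fig, ax = plt.subplots(figsize=(6, 4))
    w = 0.35
    ax.bar(
        [i - w / 2 for i in x],
        [groups[g]["mean_j_score_poa"] for g in names],
        w,
        label="J_Score_POA",
    )
    ax.bar(
        [i + w / 2 for i in x],
        [groups[g]["mean_j_score"] for g in names],
        w,
        label="J_Score",
    )
    ax.set_xticks(list(x), [f"{label}: {g}" for g in names])
    ax.set_ylabel("Mean score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
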