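"""Optional figure exports (requires matplotlib, the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .bench import LearningCurve
from .cluster import Dendrogram, PCoAResult


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_learning_curve(curve: LearningCurve, path, metric: str = "weighted_f1") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    k = np.asarray(curve.k_values)
    mean, sd = curve.means[metric], curve.sds[metric]
    ax.errorbar(k, mean, yerr=sd, fmt="-o", capsize=3)
    best = int(np.flatnonzero(mean == mean.max())[0])
    ax.plot(k[best], mean[best], "r*", markersize=14)
    ax.set_xlabel("markers incorporated")
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_confusion(matrix: np.ndarray, classes, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, cmap="Blues")
    ax.set_xticks(range(len(classes)), classes)
    ax.set_yticks(range(len(classes)), classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(classes)):
        for j in range(len(classes)):
            ax.text(j, i, f"{matrix[i, j]:.1f}", ha="center", va="center")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pcoa(result: PCoAResult, groups, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 5))
    coords = result.coordinates
    labels = [groups[s] for s in result.ids]
    for g in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == g]
        y = coords[idx, 1] if coords.shape[1] > 1 else np.zeros(len(idx))
        ax.scatter(coords[idx, 0], y, label=g)
    p = 100 * result.proportion_explained
    ax.set_xlabel(f"PC1 ({p[0]:.2f}%)")
    if coords.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({p[1]:.2f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(tree: Dendrogram, path) -> None:
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    plt = _plt()
    fig, ax = plt.subplots(figsize=(8, 4))
    scipy_dendrogram(tree.to_linkage(), labels=tree.leaf_names, ax=ax, leaf_rotation=90)
    ax.set_ylabel("Jaccard merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
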