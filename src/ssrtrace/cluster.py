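"""Jaccard distances on marker panels, principal coordinates, UPGMA trees.

Samples are compared as sets of present markers: d(a, b) = 1 - |A n B|/|A u B|
(two samples with no selected markers at all are identical under the panel,
distance 0). PCoA follows the classical Gower construction — double-centre
-d^2/2, eigendecompose, scale eigenvectors by sqrt(eigenvalue) — keeping only
positive-eigenvalue axes and reporting negative eigenvalues without
correction. UPGMA merges the closest cluster pair under unweighted average
linkage (size-weighted average of member distances), ties resolved toward the
smallest (i, j) index pair, producing an ultrametric dendrogram whose
cophenetic distance between two leaves is the height of their lowest common
merge.

Newick export writes edge lengths as half the height difference between a
node and its child, so the leaf-to-root path length equals half the root
merge height (stated in the file header comment written alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .extract import FeatureMatrix

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "Dendrogram",
    "NewickParseError",
    "jaccard_matrix",
    "pcoa",
    "upgma",
    "write_newick",
    "read_newick",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # n x p, axes ordered by descending eigenvalue
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray  # reported, not corrected
    ids: list[str] = field(default_factory=list)


def jaccard_matrix(matrix: FeatureMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances between samples' present-marker sets."""
    X = matrix.values.astype(bool)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    inter = (X[:, None, :] & X[None, :, :]).sum(axis=2).astype(float)
    union = (X[:, None, :] | X[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(matrix.sample_ids), d)


def pcoa(d: DistanceMatrix) -> PCoAResult:
    """Classical metric multidimensional scaling of a distance matrix."""
    D = d.values
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    vals, vecs = eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(vals).max()))
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    total = vals[pos].sum()
    props = vals[pos] / total if total > 0 else np.zeros(int(pos.sum()))
    return PCoAResult(
        coordinates=coords,
        eigenvalues=vals[pos],
        proportion_explained=props,
        negative_eigenvalues=vals[vals < -tol],
        ids=list(d.ids),
    )


@dataclass
class _Node:
    height: float
    leaf: str | None = None
    children: tuple["_Node", "_Node"] | None = None

    def leaves(self) -> list[str]:
        if self.leaf is not None:
            return [self.leaf]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class Dendrogram:
    """Binary merge tree with heights; supports cophenetic lookup and Newick IO."""

    root: _Node
    leaf_names: list[str]
    merge_heights: list[float]

    def cophenetic(self) -> DistanceMatrix:
        """Leaf-pair distances = height of the lowest common merge."""
        names = self.leaf_names
        idx = {s: i for i, s in enumerate(names)}
        n = len(names)
        out = np.zeros((n, n))

        def walk(node: _Node) -> list[str]:
            if node.leaf is not None:
                return [node.leaf]
            left = walk(node.children[0])
            right = walk(node.children[1])
            for a in left:
                for b in right:
                    out[idx[a], idx[b]] = out[idx[b], idx[a]] = node.height
            return left + right

        walk(self.root)
        return DistanceMatrix(names, out)

    def to_linkage(self) -> np.ndarray:
        """scipy-style linkage array (for plotting via scipy.cluster.hierarchy)."""
        idx = {s: i for i, s in enumerate(self.leaf_names)}
        n = len(self.leaf_names)
        rows = []
        next_id = n

        def walk(node: _Node) -> tuple[int, int]:
            nonlocal next_id
            if node.leaf is not None:
                return idx[node.leaf], 1
            (a, na) = walk(node.children[0])
            (b, nb) = walk(node.children[1])
            rows.append([min(a, b), max(a, b), node.height, na + nb])
            me = next_id
            next_id += 1
            return me, na + nb

        walk(self.root)
        rows.sort(key=lambda r: r[2])
        return np.array(rows, dtype=float)


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage agglomeration of a distance matrix."""
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least two samples")
    nodes: dict[int, _Node] = {i: _Node(0.0, leaf=d.ids[i]) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    heights: list[float] = []
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))  # ties: smallest (i, j)
        (i, j), h = best
        node = _Node(h, children=(nodes[i], nodes[j]))
        heights.append(h)
        new_dist: dict[tuple[int, int], float] = {}
        for (a, b), v in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = v
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            v = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            new_dist[(min(k, next_id), max(k, next_id))] = v
        nodes[next_id] = node
        sizes[next_id] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [next_id]
        dist = new_dist
        next_id += 1
    return Dendrogram(root=nodes[active[0]], leaf_names=list(d.ids), merge_heights=heights)


class NewickParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


def write_newick(dendrogram: Dendrogram) -> str:
    """Serialize with edge length = (parent height - child height) / 2."""

    def fmt(node: _Node, parent_height: float | None) -> str:
        if node.leaf is not None:
            body = node.leaf
        else:
            a = fmt(node.children[0], node.height)
            b = fmt(node.children[1], node.height)
            body = f"({a},{b})"
        if parent_height is None:
            return body
        return f"{body}:{(parent_height - node.height) / 2:.10g}"

    return fmt(dendrogram.root, None) + ";"


def read_newick(text: str) -> Dendrogram:
    """Parse a Newick string written by :func:`write_newick` back into a tree.

    Heights are reconstructed bottom-up (leaf height 0, parent = child height
    + 2 * edge length), which is exact for the ultrametric trees UPGMA emits.
    """
    pos = 0
    s = text.strip()

    def error(msg: str):
        raise NewickParseError(msg, pos)

    def parse_node() -> tuple[_Node, float]:
        nonlocal pos
        if pos >= len(s):
            error("unexpected end of input")
        if s[pos] == "(":
            pos += 1
            left, el = parse_node()
            if pos >= len(s) or s[pos] != ",":
                error("expected ','")
            pos += 1
            right, er = parse_node()
            if pos >= len(s) or s[pos] != ")":
                error("expected ')'")
            pos += 1
            hl = left.height + 2 * el
            hr = right.height + 2 * er
            if not np.isclose(hl, hr, atol=1e-9):
                error(f"non-ultrametric child heights {hl:g} vs {hr:g}")
            node = _Node((hl + hr) / 2, children=(left, right))
        else:
            start = pos
            while pos < len(s) and s[pos] not in ":,();":
                pos += 1
            name = s[start:pos]
            if not name:
                error("expected leaf name")
            node = _Node(0.0, leaf=name)
        edge = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            try:
                edge = float(s[start:pos])
            except ValueError:
                error("invalid branch length")
        return node, edge

    root, _ = parse_node()
    if pos >= len(s) or s[pos] != ";":
        error("expected ';'")
    heights: list[float] = []

    def collect(node: _Node) -> None:
        if node.children is not None:
            collect(node.children[0])
            collect(node.children[1])
            heights.append(node.height)

    collect(root)
    heights.sort()
    return Dendrogram(root=root, leaf_names=root.leaves(), merge_heights=heights)
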