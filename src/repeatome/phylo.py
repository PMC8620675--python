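"""Distance-based phylogeny over samples from repeat abundance profiles.

The neighbor-joining algorithm (Saitou & Nei 1987, with the Studier-Keppler
Q criterion) is implemented here directly and is exact on additive distance
matrices; dendropy supplies the tree container and Newick serialization.
Negative branch-length estimates, which NJ can produce on noisy
non-additive input, are clamped to zero with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .quantify import AbundanceMatrix

__all__ = [
    "DistanceMatrix",
    "abundance_distance",
    "neighbor_joining",
    "write_newick",
    "read_newick",
    "is_monophyletic",
    "tree_distance_matrix",
]

logger = logging.getLogger(__name__)

_METRICS = {"euclidean", "manhattan", "correlation"}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances over labeled samples."""

    labels: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if D.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (D < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "D", D)


def abundance_distance(matrix: AbundanceMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between sample columns of the abundance matrix."""
    if matrix.state not in ("log", "quantile_normalized"):
        raise ValueError("abundance_distance expects a log or quantile-normalized matrix")
    if len(matrix.col_ids) < 2:
        raise ValueError("need at least 2 samples")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    X = matrix.values.T  # samples x repeats
    scipy_metric = {"euclidean": "euclidean", "manhattan": "cityblock", "correlation": "correlation"}[metric]
    D = squareform(pdist(X, metric=scipy_metric))
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    D = (D + D.T) / 2.0
    return DistanceMatrix(tuple(matrix.col_ids), D)


def _new_tree(labels: Sequence[str]) -> tuple[dendropy.Tree, dict[str, dendropy.Node]]:
    taxa = dendropy.TaxonNamespace([str(x) for x in labels])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = {}
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(str(label)))
        nodes[label] = node
    return tree, nodes


def _clamp(length: float, clamped: list[int]) -> float:
    if length < 0:
        clamped[0] += 1
        return 0.0
    return float(length)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining on a distance matrix; deterministic (ties broken by
    label order) and exact on additive inputs."""
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    tree, leaf_nodes = _new_tree(labels)
    clamped = [0]

    if n == 2:
        root = dendropy.Node()
        half = dm.D[0, 1] / 2.0
        for label in labels:
            leaf_nodes[label].edge.length = _clamp(half, clamped)
            root.add_child(leaf_nodes[label])
        tree.seed_node = root
        tree.is_rooted = False
        return tree

    # active cluster bookkeeping: index -> (sort key, node)
    D = dm.D.astype(float).copy()
    active = list(range(n))
    nodes = {i: leaf_nodes[labels[i]] for i in range(n)}
    # a cluster's tie-break key is the smallest leaf label it contains
    keys = {i: str(labels[i]) for i in range(n)}

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-9 * (1.0 + abs(qmin))
        pairs = np.argwhere(Q <= qmin + tol)
        best = None
        for a, b in pairs:
            if a >= b:
                continue
            i, j = idx[a], idx[b]
            key = tuple(sorted((keys[i], keys[j])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        i, j = int(idx[a]), int(idx[b])
        dij = D[i, j]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = _clamp(li, clamped)
        nodes[j].edge.length = _clamp(lj, clamped)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # reduction: d(u, k) = (d(i,k) + d(j,k) - d(i,j)) / 2
        newrow = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newrow) - 1] = newrow[:-1]
        D[: len(newrow) - 1, -1] = newrow[:-1]
        new = D.shape[0] - 1
        nodes[new] = parent
        keys[new] = min(keys[i], keys[j])
        active = [k for k in active if k not in (i, j)] + [new]

    # join the final three clusters at an unrooted degree-3 node
    i, j, k = active
    root = dendropy.Node()
    li = (D[i, j] + D[i, k] - D[j, k]) / 2.0
    lj = (D[i, j] + D[j, k] - D[i, k]) / 2.0
    lk = (D[i, k] + D[j, k] - D[i, j]) / 2.0
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.edge.length = _clamp(length, clamped)
        root.add_child(node)
    tree.seed_node = root
    tree.is_rooted = False
    if clamped[0]:
        logger.warning("neighbor joining clamped %d negative branch length(s) to 0", clamped[0])
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize a tree as Newick with branch lengths; labels containing
    spaces are quoted by the writer."""
    text = tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(text_or_path: str) -> dendropy.Tree:
    if "(" in text_or_path:
        return dendropy.Tree.get(data=text_or_path, schema="newick")
    return dendropy.Tree.get(path=text_or_path, schema="newick")


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = tuple(t.label for t in taxa)
    n = len(labels)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            D[a, b] = D[b, a] = pdm.patristic_distance(taxa[a], taxa[b])
    return DistanceMatrix(labels, D)


def is_monophyletic(tree: dendropy.Tree, labels: Sequence[str]) -> bool:
    """True if some edge of the unrooted tree splits exactly ``labels`` from
    the remaining leaves."""
    want = frozenset(str(x) for x in labels)
    all_leaves = frozenset(t.label for t in tree.taxon_namespace)
    if not want or not want <= all_leaves:
        raise ValueError("labels must be a non-empty subset of the tree's leaves")
    if len(want) in (1, len(all_leaves)):
        return True
    tree.encode_bipartitions()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(
            t.label for t in edge.bipartition.leafset_taxa(tree.taxon_namespace)
        )
        if side == want or (all_leaves - side) == want:
            return True
    return False
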