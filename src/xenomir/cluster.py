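"""Sample-level hierarchical clustering: Pearson distance + average linkage.

Reproduces the classic expression-viewer analysis natively: features are
mean-centred, samples are compared by Pearson correlation distance
``d = 1 − r`` (pairwise-complete over mutually observed features), and the
sample dendrogram is built by UPGMA-style average linkage, where the
distance between two clusters is the unweighted mean of all cross-pair
leaf distances.  The tree can be exported as an ultrametric newick string.

Tie-breaks are fully deterministic (lowest cluster-id pair first), so
identical input always yields an identical merge sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .qpcr import CrtMatrix

__all__ = [
    "Dendrogram",
    "mean_center",
    "pearson_distance_matrix",
    "average_linkage",
    "write_newick",
    "sibling_pairs",
]


def mean_center(matrix: CrtMatrix) -> CrtMatrix:
    """Centre each feature on its across-sample mean (observed values only).

    Missing cells are left missing.  The result is no longer on the raw
    cycle scale, so range checking is relaxed on the returned matrix.
    """
    vals = matrix.values
    if (vals.notna().sum(axis=1) < 1).any():
        raise InputError("every feature needs at least one observed value")
    centered = vals.sub(vals.mean(axis=1, skipna=True), axis=0)
    return matrix.with_values(centered, check_range=False)


def pearson_distance_matrix(matrix: CrtMatrix, absolute: bool = False, min_shared: int = 3) -> pd.DataFrame:
    """Sample x sample Pearson correlation distances, d = 1 − r.

    Correlations use pairwise-complete observations.  ``absolute=True``
    switches to ``1 − |r|`` for callers that consider anti-correlated
    samples similar; the default treats them as maximally distant (d = 2).
    """
    vals = matrix.values
    samples = list(vals.columns)
    n = len(samples)
    dist = pd.DataFrame(np.zeros((n, n)), index=samples, columns=samples)
    arr = vals.to_numpy(dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        x, y = arr[:, i], arr[:, j]
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < min_shared:
            raise InputError(
                f"samples {samples[i]!r} and {samples[j]!r} share only {int(mask.sum())} observed features"
            )
        xs, ys = x[mask], y[mask]
        if xs.std() == 0 or ys.std() == 0:
            raise InputError(
                f"zero variance over shared features for pair ({samples[i]!r}, {samples[j]!r})"
            )
        r = float(np.corrcoef(xs, ys)[0, 1])
        d = 1.0 - (abs(r) if absolute else r)
        dist.iloc[i, j] = dist.iloc[j, i] = d
    return dist


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree over samples.

    ``merges`` follows the scipy convention: leaves are clusters
    ``0..n−1`` in the order of ``leaves``; merge k creates cluster
    ``n + k`` from ``(left, right, height, size)``.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise InputError(f"{n} leaves require exactly {n - 1} merges")

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def clusters(self) -> list[tuple[frozenset[str], float]]:
        """Each merged cluster as (leaf-name set, merge height)."""
        n = len(self.leaves)
        members: dict[int, frozenset[str]] = {i: frozenset([name]) for i, name in enumerate(self.leaves)}
        out = []
        for k, (a, b, h, _size) in enumerate(self.merges):
            members[n + k] = members[a] | members[b]
            out.append((members[n + k], h))
        return out

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the drawn tree (see write_newick)."""
        return _ordered_leaves(self, len(self.leaves) + len(self.merges) - 1)


def average_linkage(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance matrix.

    At each step the closest pair of active clusters is merged; the
    distance between clusters is recomputed as the unweighted mean of all
    cross-pair *leaf* distances, so merge heights do not depend on the
    merge history.  Ties on merge distance are broken by the lowest
    (cluster-id, cluster-id) pair.
    """
    labels = list(distances.index)
    n = len(labels)
    if n < 2:
        raise InputError("clustering needs at least 2 samples")
    D = distances.to_numpy(dtype=float)
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12) or not np.allclose(np.diag(D), 0.0):
        raise InputError("distances must be a symmetric matrix with zero diagonal")

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n

    def cluster_dist(a: int, b: int) -> float:
        ia, ib = members[a], members[b]
        return float(D[np.ix_(ia, ib)].mean())

    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            d = cluster_dist(a, b)
            key = (d, a, b)
            if best is None or key < best:
                best = key
        d, a, b = best
        members[next_id] = members[a] + members[b]
        active.discard(a)
        active.discard(b)
        active.add(next_id)
        merges.append((a, b, d, len(members[next_id])))
        next_id += 1
    return Dendrogram(tuple(labels), tuple(merges))


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.1f}" if x == int(x) else f"{x:.12g}"


def _node_height(tree: Dendrogram, node: int) -> float:
    n = len(tree.leaves)
    return 0.0 if node < n else tree.merges[node - n][2]


def _min_leaf(tree: Dendrogram, node: int) -> str:
    n = len(tree.leaves)
    if node < n:
        return tree.leaves[node]
    a, b, _, _ = tree.merges[node - n]
    return min(_min_leaf(tree, a), _min_leaf(tree, b))


def _ordered_leaves(tree: Dendrogram, node: int) -> list[str]:
    n = len(tree.leaves)
    if node < n:
        return [tree.leaves[node]]
    a, b, _, _ = tree.merges[node - n]
    a, b = sorted((a, b), key=lambda c: _min_leaf(tree, c))
    return _ordered_leaves(tree, a) + _ordered_leaves(tree, b)


def to_newick(tree: Dendrogram) -> str:
    """Ultrametric newick string: every leaf sits at depth root_height / 2.

    A child hanging from a merge at height H, itself merged at height h,
    gets branch length (H − h) / 2; leaves get H / 2.  Children are ordered
    by their lexicographically smallest leaf name.
    """
    n = len(tree.leaves)
    root = n + len(tree.merges) - 1

    def render(node: int, parent_height: float) -> str:
        h = _node_height(tree, node)
        length = (parent_height - h) / 2.0
        if node < n:
            return f"{tree.leaves[node]}:{_fmt(length)}"
        a, b, _, _ = tree.merges[node - n]
        a, b = sorted((a, b), key=lambda c: _min_leaf(tree, c))
        return f"({render(a, h)},{render(b, h)}):{_fmt(length)}"

    h = _node_height(tree, root)
    a, b, _, _ = tree.merges[root - n]
    a, b = sorted((a, b), key=lambda c: _min_leaf(tree, c))
    return f"({render(a, h)},{render(b, h)});"


def write_newick(tree: Dendrogram, path) -> str:
    """Write the newick rendering of *tree* to *path* and return it."""
    text = to_newick(tree)
    with open(path, "w") as fh:
        fh.write(text + "\n")
    return text


def sibling_pairs(tree: Dendrogram) -> set[frozenset[str]]:
    """Leaf pairs that are merged directly with each other (cherries)."""
    n = len(tree.leaves)
    out = set()
    for a, b, _, _ in tree.merges:
        if a < n and b < n:
            out.add(frozenset((tree.leaves[a], tree.leaves[b])))
    return out
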