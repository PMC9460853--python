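"""Neighbor-joining phenograms and topology utilities.

Reconstructs unrooted phenograms from population distance matrices by the
standard neighbor-joining agglomeration: at each step the pair (i, j)
minimizing

    Q(i, j) = (n - 2) * d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined, branch lengths follow the canonical closed forms, and the final
three nodes attach to a single internal (degree-3) node.  Negative estimated
branch lengths are clamped to zero with the deficit transferred to the sister
branch, so path lengths through the join are preserved.  Taxa are processed
in sorted-label order with lowest-index tie-breaking, making the result
deterministic and independent of input label order.

Trees are :class:`skbio.TreeNode` objects (Newick-serializable); helper
functions identify the tightest sister-leaf pair and the "outermost" leaf
(maximal mean path distance to all other leaves) used to read phenograms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "TreeError",
    "TightPair",
    "OutermostLeaf",
    "neighbor_joining",
    "to_newick",
    "read_newick",
    "tight_pair",
    "outermost_leaf",
    "robinson_foulds",
]


class TreeError(ValueError):
    """Invalid tree-construction input."""


@dataclass(frozen=True)
class TightPair:
    """The closest sister-leaf pair of a phenogram."""

    leaves: tuple[str, str]
    distance: float
    sister: bool  # True when the two leaves share an internal node
    tied: bool


@dataclass(frozen=True)
class OutermostLeaf:
    """The leaf with maximal mean path distance to all other leaves."""

    leaf: str
    mean_distance: float
    tied: bool


def _as_distance_matrix(dm) -> DistanceMatrix:
    if isinstance(dm, DistanceMatrix):
        return dm
    raise TreeError("expected a skbio DistanceMatrix")


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a symmetric, hollow distance matrix.

    Returns the unrooted tree in its conventional rooted representation:
    a degree-3 basal node with all other internal nodes binary.
    """
    dm = _as_distance_matrix(dm)
    n = len(dm.ids)
    if n < 3:
        raise TreeError(f"neighbor joining needs at least 3 taxa (got {n})")
    if np.any(dm.data < 0):
        raise TreeError("distance matrix has negative entries")

    order = sorted(dm.ids)
    d = dm.filter(order).data.copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in order]

    while len(nodes) > 3:
        m = d.shape[0]
        row_sums = d.sum(axis=1)
        q = (m - 2) * d - row_sums[:, None] - row_sums[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        best = int(np.argmin(flat))  # argmin returns the first minimum: lowest (i, j)
        i, j = int(iu[0][best]), int(iu[1][best])

        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        # clamp negatives, transferring the deficit to the sister branch
        if li < 0.0:
            li, lj = 0.0, d[i, j]
        elif lj < 0.0:
            li, lj = d[i, j], 0.0
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])

        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        new_row = np.clip(new_row, 0.0, None)
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_row[keep]
        d = d_next
        nodes = [nodes[k] for k in keep] + [parent]

    (d01, d02, d12) = d[0, 1], d[0, 2], d[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, length in zip(nodes, lengths):
        node.length = float(max(0.0, length))
    return TreeNode(children=list(nodes))


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string with branch lengths."""
    if tree.count(tips=True) < 2:
        raise TreeError("cannot serialize a tree with fewer than 2 leaves")
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string."""
    return TreeNode.read(io.StringIO(text), format="newick")


def _sister_leaf_pairs(tree: TreeNode):
    """Leaf pairs sharing a parent node (including the basal degree-3 node)."""
    for node in tree.non_tips(include_self=True):
        leaf_children = [c for c in node.children if c.is_tip()]
        for a, b in combinations(leaf_children, 2):
            yield a, b


def tight_pair(tree: TreeNode) -> TightPair:
    """The sister-leaf pair with the smallest path distance between its leaves.

    Ties are broken lexicographically and flagged.  Should no sister-leaf
    pair exist, the globally closest leaf pair is returned with
    ``sister=False``.
    """
    if tree.count(tips=True) < 4:
        raise TreeError("tight_pair needs at least 4 leaves")
    candidates = []
    for a, b in _sister_leaf_pairs(tree):
        dist = (a.length or 0.0) + (b.length or 0.0)
        candidates.append((dist, tuple(sorted((a.name, b.name))), True))
    if not candidates:
        tips = tree.tip_tip_distances()
        for x, y in combinations(tips.ids, 2):
            candidates.append((float(tips[x, y]), tuple(sorted((x, y))), False))
    candidates.sort(key=lambda c: (c[0], c[1]))
    best = candidates[0]
    tied = sum(1 for c in candidates if abs(c[0] - best[0]) <= 1e-12) > 1
    return TightPair(leaves=best[1], distance=best[0], sister=best[2], tied=tied)


def outermost_leaf(tree: TreeNode) -> OutermostLeaf:
    """Leaf with the largest mean path distance to every other leaf."""
    if tree.count(tips=True) < 3:
        raise TreeError("outermost_leaf needs at least 3 leaves")
    tips = tree.tip_tip_distances()
    means = tips.data.sum(axis=1) / (len(tips.ids) - 1)
    ranked = sorted(zip(-means, tips.ids))
    tied = len(ranked) > 1 and abs(ranked[0][0] - ranked[1][0]) <= 1e-12
    return OutermostLeaf(leaf=ranked[0][1], mean_distance=float(-ranked[0][0]), tied=tied)


def robinson_foulds(a: TreeNode, b: TreeNode) -> float:
    """Unweighted Robinson-Foulds distance between two trees."""
    return float(a.compare_rfd(b))
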