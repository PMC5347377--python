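"""Neighbor-joining tree construction, implemented from first principles.

The agglomerative algorithm of Saitou & Nei (1987): at each step join the
pair (i, j) minimizing

    Q(i, j) = (n - 2) d(i, j) - r_i - r_j        (r = row sums)

attach both to a new node with branch lengths

    l_i = d(i, j) / 2 + (r_i - r_j) / (2 (n - 2)),      l_j = d(i, j) - l_i

and reduce the matrix with d(u, k) = (d(i, k) + d(j, k) - d(i, j)) / 2.
When three nodes remain they are joined in a trifurcation with closed-form
lengths.  NJ makes no molecular-clock assumption and is exact on additive
matrices: if the input equals the path-length matrix of some tree, that
tree (topology and branch lengths) is recovered.

Ties in Q are broken toward the lexicographically smallest (row, column)
pair in the current working order, making the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .jaccard_core import DistanceMatrix


@dataclass
class ClusterTree:
    """Unrooted tree with branch lengths; leaves carry subject ids.

    ``adjacency`` maps node id -> {neighbor id: branch length};
    ``leaf_names`` maps leaf node ids to subject ids.
    """

    adjacency: dict[int, dict[int, float]]
    leaf_names: dict[int, str]

    def leaf_nodes(self) -> list[int]:
        return sorted(self.leaf_names)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.leaf_names[n] for n in self.leaf_nodes()]

    def node_of(self, label: str) -> int:
        for node, name in self.leaf_names.items():
            if name == label:
                return node
        raise KeyError(f"unknown subject id {label!r}")

    def edges(self) -> Iterator[tuple[int, int, float]]:
        for a, nbrs in self.adjacency.items():
            for b, length in nbrs.items():
                if a < b:
                    yield a, b, length

    def validate(self) -> None:
        n_nodes = len(self.adjacency)
        n_edges = sum(1 for _ in self.edges())
        if n_edges != n_nodes - 1:
            raise ValueError("tree is not acyclic/connected")
        for node in self.leaf_names:
            if len(self.adjacency[node]) != 1:
                raise ValueError(f"leaf node {node} has degree != 1")
        for _, _, length in self.edges():
            if not np.isfinite(length):
                raise ValueError("non-finite branch length")

    def bipartition(self, a: int, b: int) -> frozenset[str]:
        """Leaf labels on the ``a`` side of edge (a, b)."""
        seen = {b, a}
        stack = [a]
        side = []
        while stack:
            node = stack.pop()
            if node in self.leaf_names:
                side.append(self.leaf_names[node])
            for nbr in self.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(side)

    def bipartitions(self) -> Iterator[frozenset[str]]:
        """One side of every edge, as leaf-label sets."""
        for a, b, _ in self.edges():
            yield self.bipartition(a, b)

    def restrict(self, labels: set[str]) -> "ClusterTree":
        """Prune to the given leaves, suppressing degree-2 nodes (their two
        edges merge, lengths summed)."""
        keep = {n for n, name in self.leaf_names.items() if name in labels}
        missing = labels - set(self.leaf_names.values())
        if missing:
            raise KeyError(f"unknown subject id(s): {sorted(missing)}")
        adjacency = {a: dict(nbrs) for a, nbrs in self.adjacency.items()}
        leaf_names = {n: self.leaf_names[n] for n in keep}

        def remove_node(node: int) -> None:
            for nbr in list(adjacency[node]):
                del adjacency[nbr][node]
            del adjacency[node]

        pruned = [
            n for n in self.leaf_names if n not in keep
        ]
        for node in pruned:
            remove_node(node)
        changed = True
        while changed:
            changed = False
            for node in list(adjacency):
                if node in leaf_names:
                    continue
                degree = len(adjacency[node])
                if degree == 0 and len(adjacency) > 1:
                    remove_node(node)
                    changed = True
                elif degree == 1:
                    remove_node(node)
                    changed = True
                elif degree == 2:
                    (a, la), (b, lb) = adjacency[node].items()
                    remove_node(node)
                    adjacency[a][b] = adjacency[b][a] = la + lb
                    changed = True
        return ClusterTree(adjacency, leaf_names)


def neighbor_joining(
    D: DistanceMatrix, clamp_negative: bool = False
) -> ClusterTree:
    """Build the neighbor-joining tree for a distance matrix.

    Negative branch lengths (possible on non-additive input) are kept by
    default; with ``clamp_negative`` they are set to zero and the deficit
    transferred to the adjacent sibling edge, preserving the path length
    between the joined pair.
    """
    D.validate()
    n = len(D.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 subjects")
    if not np.all(np.isfinite(D.values)):
        raise ValueError("non-finite distances")

    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_names = dict(enumerate(D.labels))

    def connect(a: int, b: int, length: float) -> None:
        adjacency[a][b] = length
        adjacency[b][a] = length

    if n == 2:
        connect(0, 1, float(D.values[0, 1]))
        return ClusterTree(adjacency, leaf_names)

    active = list(range(n))  # working order: node ids of current clusters
    dist = D.values.astype(float).copy()  # working matrix over `active`
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major: lexicographically smallest tie
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        d_ij = dist[i, j]
        li = d_ij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        if clamp_negative:
            li, lj = _clamp_pair(li, lj)
        node = next_id
        next_id += 1
        adjacency[node] = {}
        connect(node, active[i], li)
        connect(node, active[j], lj)
        new_row = (dist[i, :] + dist[j, :] - d_ij) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        dist = np.vstack([dist[keep][:, keep], new_row[keep]])
        dist = np.hstack([dist, np.append(new_row[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [node]

    # trifurcating final join
    a, b, c = active
    d_ab, d_ac, d_bc = dist[0, 1], dist[0, 2], dist[1, 2]
    node = next_id
    adjacency[node] = {}
    la = (d_ab + d_ac - d_bc) / 2.0
    lb = d_ab - la
    lc = d_ac - la
    if clamp_negative:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    connect(node, a, la)
    connect(node, b, lb)
    connect(node, c, lc)
    tree = ClusterTree(adjacency, leaf_names)
    tree.validate()
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # Kuhner-Felsenstein: zero a negative length, move the deficit to the
    # sibling edge so the path length between the joined pair is preserved
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def tree_path_distances(tree: ClusterTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (labels sorted)."""
    labels = sorted(tree.leaf_names.values())
    node_of = {name: node for node, name in tree.leaf_names.items()}
    n = len(labels)
    values = np.zeros((n, n))
    for i, label in enumerate(labels):
        start = node_of[label]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nbr, length in tree.adjacency[cur].items():
                if nbr not in dist:
                    dist[nbr] = dist[cur] + length
                    stack.append(nbr)
        for j, other in enumerate(labels):
            values[i, j] = dist[node_of[other]]
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, (values + values.T) / 2.0, scope="tree")
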