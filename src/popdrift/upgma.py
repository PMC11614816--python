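"""UPGMA population tree from a divergence-time matrix.

Average-linkage agglomeration of a symmetric, zero-diagonal, non-negative
distance matrix. Each merge sits at half the pairwise distance, so with
input distances in generations every node height is a time in generations
and the result is ultrametric by construction. Ties are broken by the
lexicographically smallest member label so the output is byte-deterministic;
Newick children are ordered by smallest leaf label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TreeNode:
    """Node of an ultrametric tree; leaves have height 0 and a name."""

    height: float
    name: str = ""
    children: tuple = ()
    min_label: str = ""
    n_leaves: int = 1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list:
        if self.is_leaf:
            return [self.name]
        out = []
        for child in self.children:
            out.extend(child.leaf_names())
        return out

    def leaf_depths(self, _acc: float = 0.0) -> dict:
        """Root-to-leaf path length per leaf (ultrametric check)."""
        if self.is_leaf:
            return {self.name: _acc}
        out = {}
        for child in self.children:
            out.update(child.leaf_depths(_acc + self.height - child.height))
        return out


def upgma(distance_matrix, labels) -> TreeNode:
    """Build the UPGMA tree of a symmetric distance matrix.

    Merge height is half the pairwise distance; the distance from a merged
    cluster to any other is the size-weighted average of its members'
    distances. Tied minimal distances resolve to the pair whose sorted
    (smallest-member-label, smallest-member-label) key is lexicographically
    first.
    """
    d = np.asarray(distance_matrix, dtype=float)
    labels = [str(x) for x in labels]
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("matrix shape does not match labels")
    if not np.allclose(d, d.T, rtol=0, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    if n == 1:
        return TreeNode(0.0, labels[0], min_label=labels[0])

    nodes = {i: TreeNode(0.0, labels[i], min_label=labels[i]) for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    next_id = n

    def key(i, j):
        return (i, j) if i < j else (j, i)

    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                dij = dist[key(i, j)]
                tie_key = tuple(sorted((nodes[i].min_label, nodes[j].min_label)))
                cand = (dij, tie_key, i, j)
                if best is None or cand < best:
                    best = cand
        dij, _, i, j = best
        merged = TreeNode(
            height=dij / 2.0,
            children=(nodes[i], nodes[j]),
            min_label=min(nodes[i].min_label, nodes[j].min_label),
            n_leaves=nodes[i].n_leaves + nodes[j].n_leaves,
        )
        si, sj = nodes[i].n_leaves, nodes[j].n_leaves
        for k in active:
            if k in (i, j):
                continue
            dist[key(next_id, k)] = (
                si * dist[key(i, k)] + sj * dist[key(j, k)]
            ) / (si + sj)
        active.discard(i)
        active.discard(j)
        active.add(next_id)
        nodes[next_id] = merged
        next_id += 1
    return nodes[next_id - 1]


def write_newick(tree: TreeNode, units: str = "generations",
                 generation_years: float = 25.0) -> str:
    """Serialize as Newick with deterministic child order.

    Branch lengths are in generations, or multiplied by
    ``generation_years`` when ``units="years"``.
    """
    if units not in {"generations", "years"}:
        raise ValueError("units must be 'generations' or 'years'")
    scale = generation_years if units == "years" else 1.0

    def fmt(node: TreeNode, parent_height: float) -> str:
        bl = (parent_height - node.height) * scale
        if node.is_leaf:
            return f"{node.name}:{bl:.10g}"
        kids = sorted(node.children, key=lambda c: c.min_label)
        inner = ",".join(fmt(c, node.height) for c in kids)
        return f"({inner}):{bl:.10g}"

    if tree.is_leaf:
        return f"{tree.name}:0;"
    kids = sorted(tree.children, key=lambda c: c.min_label)
    inner = ",".join(fmt(c, tree.height) for c in kids)
    return f"({inner});"
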