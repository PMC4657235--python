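"""UPGMA guide trees.

Textbook UPGMA: repeatedly merge the closest pair of clusters at height
d_min/2, replacing cluster-cluster distances by size-weighted arithmetic
means.  Ties are broken on the lexicographically smallest pair of cluster
indices so the tree is deterministic.  The result is ultrametric (all
root-to-leaf path lengths equal) and drives the order of progressive
profile merges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix


@dataclass(frozen=True)
class TreeNode:
    """A node of a rooted binary ultrametric guide tree."""

    height: float
    leaf: int | None = None  # sequence index for leaves
    children: tuple["TreeNode", "TreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.leaf]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class GuideTree:
    root: TreeNode
    ids: tuple[str, ...]

    def postorder(self):
        """Yield internal nodes children-first (the progressive merge order)."""
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if node.is_leaf:
                continue
            if seen:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))


def upgma(d: DistanceMatrix) -> GuideTree:
    """Build a UPGMA tree from a distance matrix (n >= 2)."""
    n = d.n
    if n < 2:
        raise ValueError("UPGMA needs at least two sequences")
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])
    nodes: dict[int, TreeNode] = {i: TreeNode(0.0, leaf=i) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    next_id = n
    while len(nodes) > 1:
        # closest pair; ties resolved on smallest (i, j)
        (i, j), dmin = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        height = dmin / 2.0
        merged = TreeNode(height, children=(nodes[i], nodes[j]))
        si, sj = sizes.pop(i), sizes.pop(j)
        del nodes[i], nodes[j]
        for other in list(nodes):
            a = dist.pop((min(i, other), max(i, other)))
            b = dist.pop((min(j, other), max(j, other)))
            dist[(other, next_id)] = (si * a + sj * b) / (si + sj)
        del dist[(i, j)]
        nodes[next_id] = merged
        sizes[next_id] = si + sj
        next_id += 1
    return GuideTree(root=nodes.popitem()[1], ids=d.ids)


def to_newick(tree: GuideTree) -> str:
    """Serialize with branch lengths = parent height - child height."""

    def fmt(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            label = tree.ids[node.leaf]
        else:
            label = "(" + ",".join(fmt(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return label
        return f"{label}:{parent_height - node.height:.12g}"

    return fmt(tree.root, None) + ";"
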