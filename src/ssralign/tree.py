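"""UPGMA tree construction and Newick serialization.

UPGMA (unweighted pair group method with arithmetic mean) agglomerates the
two closest clusters, places the new node at half their distance, and updates
cluster-to-cluster distances as size-weighted averages.  The result is a
rooted ultrametric tree.  Tie-breaking is deterministic: among equally close
pairs the pair with the lowest cluster-creation indices is joined, so repeated
runs on the same matrix yield byte-identical Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .distance import DistanceMatrix


@dataclass
class Clade:
    """A node of a rooted tree; leaves carry a name, internal nodes children."""

    name: str | None = None
    branch_length: float = 0.0
    children: tuple["Clade", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """A rooted tree with branch lengths; UPGMA output is ultrametric."""

    root: Clade

    def leaves(self) -> Iterator[Clade]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(reversed(node.children))

    def leaf_names(self) -> tuple[str, ...]:
        return tuple(leaf.name or "" for leaf in self.leaves())

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (branch lengths summed)."""
        depths: dict[str, float] = {}

        def walk(node: Clade, acc: float) -> None:
            acc += node.branch_length
            if node.is_leaf:
                depths[node.name or ""] = acc
            else:
                for child in node.children:
                    walk(child, acc)

        walk(self.root, -self.root.branch_length)  # root branch excluded
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.leaf_depths().values())
        return max(depths) - min(depths) <= tol


def upgma(dm: DistanceMatrix) -> Tree:
    """Build the UPGMA tree of a distance matrix (>= 2 taxa, no NaN)."""
    n = len(dm)
    if n < 2:
        raise ValueError("UPGMA requires at least 2 taxa")
    if np.isnan(dm.d).any():
        raise ValueError("distance matrix contains NaN")

    nodes: dict[int, Clade] = {
        i: Clade(name=dm.labels[i]) for i in range(n)
    }
    height: dict[int, float] = dict.fromkeys(range(n), 0.0)
    size: dict[int, int] = dict.fromkeys(range(n), 1)
    dist: dict[tuple[int, int], float] = {
        (i, j): float(dm.d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active: list[int] = list(range(n))
    next_id = n

    while len(active) > 1:
        # lowest-index pair among minima: deterministic tie-break
        best = min(
            ((i, j) for k, i in enumerate(active) for j in active[k + 1 :]),
            key=lambda p: (dist[p], p),
        )
        i, j = best
        h = dist[(i, j)] / 2.0
        nodes[i].branch_length = h - height[i]
        nodes[j].branch_length = h - height[j]
        parent = Clade(children=(nodes[i], nodes[j]))
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(k, next_id)] = (size[i] * dik + size[j] * djk) / (
                size[i] + size[j]
            )
        nodes[next_id] = parent
        height[next_id] = h
        size[next_id] = size[i] + size[j]
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    return Tree(root=nodes[active[0]])


_NEWICK_SPECIAL = set(" \t\n()[]':;,")


def _quote_label(name: str) -> str:
    if any(ch in _NEWICK_SPECIAL for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _render(node: Clade, with_branch_length: bool) -> str:
    if node.is_leaf:
        out = _quote_label(node.name or "")
    else:
        out = "(" + ",".join(_render(c, True) for c in node.children) + ")"
        if node.name:
            out += _quote_label(node.name)
    if with_branch_length:
        out += f":{float(node.branch_length)}"
    return out


def write_newick(tree: Tree) -> str:
    """Standard Newick text with branch lengths, ';'-terminated."""
    return _render(tree.root, False) + ";"
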