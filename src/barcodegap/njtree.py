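"""Neighbor-joining trees on K2P distances with site-bootstrap support.

Saitou–Nei neighbor joining exactly recovers any additive distance matrix
and is the standard distance-based companion to barcode distance analyses.
Trees are unrooted (represented with a trifurcating root), branch lengths
are in substitutions/site with negative estimates clamped to zero, and
clade support is the percentage of site-bootstrap replicates whose NJ tree
contains each internal bipartition of the point-estimate tree.  Output is
standard newick with support values as internal-node labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .distances import DistanceMatrix, build_matrix
from .seqio import SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "Clade",
    "Tree",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "write_newick",
]


@dataclass
class Clade:
    """A node of an (un)rooted tree; ``length`` is the branch to its parent."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Clade"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> list["Clade"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]


@dataclass
class Tree:
    """An unrooted tree stored with an arbitrary (root) trifurcation."""

    root: Clade
    n_clamped: int = 0  # negative branch-length estimates clamped to zero

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        paths = {}

        def collect(node: Clade, acc: tuple) -> None:
            if node.is_leaf:
                paths[node.name] = acc
            for c in node.children:
                collect(c, acc + ((c, c.length or 0.0),))

        collect(self.root, ())
        pa, pb = paths[a], paths[b]
        shared = 0
        while shared < min(len(pa), len(pb)) and pa[shared][0] is pb[shared][0]:
            shared += 1
        return sum(l for _, l in pa[shared:]) + sum(l for _, l in pb[shared:])


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial splits of the leaf set, one canonical side per edge.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf is kept, so the set is comparable
    across differently rooted representations of the same unrooted tree.
    """
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    splits = set()
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Ties in the Q criterion are broken toward the pair whose clusters
    contain the smallest leaf labels; negative branch-length estimates are
    clamped to zero with the total deficit logged.  Undefined (NaN) pairs
    must be excluded by the caller beforehand.
    """
    if matrix.n < 2:
        raise ValueError("neighbor joining requires at least 2 taxa")
    if np.isnan(matrix.d).any():
        raise ValueError(
            "matrix contains undefined pairs; exclude those samples first"
        )
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            logger.debug("clamped negative branch length %.6g to 0", x)
            return 0.0
        return x

    nodes = [Clade(name=lab) for lab in matrix.labels]
    # smallest leaf label within each active cluster, for tie-breaking
    keys = list(matrix.labels)
    D = matrix.d.astype(float).copy()
    active = list(range(matrix.n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            ((a, b) for a, b in cand if a < b),
            key=lambda ab: tuple(sorted((keys[active[ab[0]]], keys[active[ab[1]]]))),
        )
        ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = clamp(0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))))
        new = Clade(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # reuse slot i for the merged cluster, drop slot j
        for k in active:
            if k not in (i, j):
                D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = new
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    if len(active) == 3:
        a, b, c = active
        la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
        lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
        lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
        for k, l in zip((a, b, c), (la, lb, lc)):
            nodes[k].length = l
        root = Clade(children=[nodes[a], nodes[b], nodes[c]])
    else:
        a, b = active
        nodes[a].length = 0.0
        nodes[b].length = clamp(D[a, b])
        root = Clade(children=[nodes[a], nodes[b]])

    if n_clamped:
        logger.info("neighbor_joining: clamped %d negative branch lengths", n_clamped)
    return Tree(root=root, n_clamped=n_clamped)


def bootstrap_support(
    sset: SequenceSet, reps: int = 1000, seed: int = 0
) -> Tree:
    """NJ point-estimate tree annotated with site-bootstrap clade support.

    Columns are resampled with replacement; each replicate's NJ tree
    contributes to the support (percent of usable replicates) of every
    bipartition of the point-estimate tree.  Replicates whose resampled
    matrix contains saturated/undefined pairs are skipped and counted in
    the log.  Deterministic for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    point_matrix = build_matrix(sset)
    tree = neighbor_joining(point_matrix)
    target = bipartitions(tree)
    if not target:
        return tree

    L = sset.length
    rng = np.random.default_rng(seed)
    counts = {split: 0 for split in target}
    used = 0
    skipped = 0
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        weights = np.bincount(cols, minlength=L).astype(float)
        rep_matrix = build_matrix(sset, weights)
        if np.isnan(rep_matrix.d).any():
            skipped += 1
            continue
        rep_splits = bipartitions(neighbor_joining(rep_matrix))
        used += 1
        for split in target & rep_splits:
            counts[split] += 1
    if skipped:
        logger.info("bootstrap_support: skipped %d/%d saturated replicates",
                    skipped, reps)

    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = all_leaves - side
        if side in counts and used:
            node.support = 100.0 * counts[side] / used
    return tree


def _fmt_clade(node: Clade) -> str:
    if node.is_leaf:
        out = node.name or ""
    else:
        inner = ",".join(_fmt_clade(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:g}"
        out = f"({inner}){label}"
    if node.length is not None:
        out += f":{node.length:.6f}"
    return out


def write_newick(tree: Tree) -> str:
    """Serialise to newick; support values appear as internal-node labels."""
    return _fmt_clade(tree.root) + ";"
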