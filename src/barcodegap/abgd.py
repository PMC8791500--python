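"""Automatic Barcode Gap Discovery (ABGD), implemented from first principles.

ABGD partitions barcode samples without a fixed divergence threshold.  For
each prior bound ``p`` on intraspecific divergence drawn from a geometric
grid, it scans the ranked pairwise distances above ``p`` for the first
spacing between consecutive ranked distances that is anomalously wide —
wider than ``x`` times the typical local spacing — and takes that spacing
as the barcode gap.  Samples are then clustered by single linkage below the
gap, and the procedure recurses inside each cluster (using only that
cluster's distances) until no further gap is found.  The partition that is
stable across the widest contiguous run of priors is reported as the
consensus.

The gap statistic used here is a sliding-window variant: the local spacing
scale at rank ``i`` is the mean of the last (up to) 10 strictly positive
spacings preceding ``i``, and a gap is called at the first ``i`` (with
``d[i] > prior``) where ``d[i+1] - d[i] > x * w(i)``.  The threshold
returned is the midpoint of the gap interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

__all__ = [
    "AbgdParams",
    "Partition",
    "AbgdResult",
    "prior_grid",
    "find_gap",
    "cluster_at",
    "abgd_partition",
]

_WINDOW = 10  # ranks in the sliding spacing window


@dataclass(frozen=True)
class AbgdParams:
    """ABGD tuning parameters.

    Distances are expected as K2P (the conventional barcode setting with
    TS/TV = 2.0); the partitioner itself is model-agnostic.
    """

    pmin: float = 0.001
    pmax: float = 0.1
    steps: int = 10
    x: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.pmin <= self.pmax):
            raise ValueError("require 0 < pmin <= pmax")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.x <= 0:
            raise ValueError("x must be > 0")


@dataclass(frozen=True)
class Partition:
    """Assignment of samples to delimited groups (indices contiguous from 1)."""

    assignment: dict[str, int]
    n_groups: int

    def groups(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for sample, g in self.assignment.items():
            out.setdefault(g, []).append(sample)
        return [sorted(out[g]) for g in sorted(out)]

    def as_sets(self) -> frozenset[frozenset[str]]:
        """Canonical label-free representation, for partition equality."""
        return frozenset(frozenset(g) for g in self.groups())


@dataclass
class AbgdResult:
    """Per-prior partitions plus the consensus across priors."""

    priors: list[float]
    gaps: list[float | None]  # top-level gap threshold per prior
    partitions: list[Partition]
    consensus: Partition
    consensus_priors: tuple[float, float]  # first/last prior of the stable run
    gap_distance: float | None  # headline gap of the consensus run


def prior_grid(params: AbgdParams) -> list[float]:
    """Geometric progression of priors from pmin to pmax inclusive."""
    if params.steps == 1 or params.pmin == params.pmax:
        return [params.pmin]
    return list(np.geomspace(params.pmin, params.pmax, params.steps))


def find_gap(
    distances: Sequence[float], prior: float, x: float = 1.5
) -> float | None:
    """Locate the barcode gap in ranked pairwise distances.

    ``distances`` must be sorted ascending (ties allowed).  Scanning the
    inter-rank intervals ``(d[i], d[i+1])`` whose upper rank exceeds
    ``prior`` — the prior bounds intraspecific divergence, so the gap must
    end above it — return the midpoint of the first interval whose width
    exceeds ``x`` times the mean of the preceding (up to 10) strictly
    positive spacings.  None when no such interval exists.
    """
    d = list(distances)
    if len(d) < 2:
        return None
    spacings = [d[i + 1] - d[i] for i in range(len(d) - 1)]
    for i in range(len(d) - 1):
        if d[i + 1] <= prior:
            continue
        prev_pos = [s for s in spacings[:i] if s > 0][-_WINDOW:]
        if not prev_pos:
            continue
        w = sum(prev_pos) / len(prev_pos)
        if spacings[i] > x * w:
            return (d[i] + d[i + 1]) / 2.0
    return None


def cluster_at(matrix: DistanceMatrix, threshold: float) -> Partition:
    """Single-linkage partition: connected components of d < threshold.

    Undefined distances are treated as above-threshold (no edge).  Groups
    are numbered 1..k in order of their smallest member label.
    """
    n = matrix.n
    with np.errstate(invalid="ignore"):
        adj = np.nan_to_num(matrix.d, nan=np.inf) < threshold
    np.fill_diagonal(adj, False)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    # renumber components by smallest member label
    first_label = {}
    for lab, c in zip(matrix.labels, comp):
        cur = first_label.get(c)
        if cur is None or lab < cur:
            first_label[c] = lab
    order = sorted(first_label, key=lambda c: first_label[c])
    renum = {c: i + 1 for i, c in enumerate(order)}
    assignment = {lab: renum[c] for lab, c in zip(matrix.labels, comp)}
    return Partition(assignment=assignment, n_groups=len(order))


def _recursive_partition(
    matrix: DistanceMatrix, prior: float, x: float
) -> list[list[str]]:
    """Groups after recursive gap detection within ``matrix``'s samples."""
    if matrix.n <= 1:
        return [list(matrix.labels)]
    vals = matrix.condensed()
    vals = np.sort(vals[~np.isnan(vals)])
    gap = find_gap(vals.tolist(), prior, x)
    if gap is None:
        return [list(matrix.labels)]
    part = cluster_at(matrix, gap)
    if part.n_groups <= 1:
        return [list(matrix.labels)]
    out: list[list[str]] = []
    for group in part.groups():
        if len(group) <= 2:
            out.append(group)
        else:
            out.extend(_recursive_partition(matrix.submatrix(group), prior, x))
    return out


def _partition_from_groups(groups: list[list[str]]) -> Partition:
    ordered = sorted(groups, key=lambda g: min(g))
    assignment = {}
    for i, group in enumerate(ordered, start=1):
        for lab in group:
            assignment[lab] = i
    return Partition(assignment=assignment, n_groups=len(ordered))


def abgd_partition(matrix: DistanceMatrix, params: AbgdParams = AbgdParams()) -> AbgdResult:
    """Run ABGD over the full prior grid and form the consensus partition.

    For each prior: find the gap over all ranked distances, single-linkage
    cluster below it, and recurse within each group until no further gap is
    found.  A prior with no detectable gap yields the single-group
    partition.  The consensus is the partition shared by the longest run of
    consecutive priors; ties break toward fewer groups, then toward smaller
    priors.  The headline gap distance is the top-level gap at the first
    prior of that run.
    """
    priors = prior_grid(params)
    all_vals = matrix.condensed()
    all_vals = np.sort(all_vals[~np.isnan(all_vals)])

    gaps: list[float | None] = []
    partitions: list[Partition] = []
    for p in priors:
        gap = find_gap(all_vals.tolist(), p, params.x)
        gaps.append(gap)
        if gap is None:
            partitions.append(_partition_from_groups([list(matrix.labels)]))
        else:
            partitions.append(
                _partition_from_groups(_recursive_partition(matrix, p, params.x))
            )

    # longest run of consecutive priors with an identical partition
    runs: list[tuple[int, int]] = []  # (start, end) inclusive
    start = 0
    for i in range(1, len(partitions) + 1):
        if i == len(partitions) or partitions[i].as_sets() != partitions[start].as_sets():
            runs.append((start, i - 1))
            start = i
    best = max(
        runs,
        key=lambda r: (r[1] - r[0] + 1, -partitions[r[0]].n_groups, -r[0]),
    )
    consensus = partitions[best[0]]
    return AbgdResult(
        priors=priors,
        gaps=gaps,
        partitions=partitions,
        consensus=consensus,
        consensus_priors=(priors[best[0]], priors[best[1]]),
        gap_distance=gaps[best[0]],
    )
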