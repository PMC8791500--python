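"""Kimura two-parameter distances with pairwise deletion.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the proportions of compared sites showing a transition and a
transversion respectively, the distance estimate is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   [substitutions/site]

Sites where either sequence of a pair carries a gap or any IUPAC ambiguity
code are excluded for that pair only (pairwise deletion).  When the log
arguments are non-positive the estimator is undefined (saturation); such
pairs are reported as NaN and collected in ``DistanceMatrix.undefined_pairs``
rather than silently zeroed.

Site-bootstrap standard errors resample alignment columns with replacement
and recompute a chosen statistic per replicate.  Group summaries aggregate
within- and between-group distances at the species, genus, family or
population level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Hashable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceSet

__all__ = [
    "PairSiteCounts",
    "DistanceMatrix",
    "GroupSummary",
    "count_site_pairs",
    "k2p_distance",
    "k2p_from_pq",
    "build_matrix",
    "bootstrap_se",
    "summarize_groups",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_INVALID = 255


class PairSiteCounts(NamedTuple):
    """Per-pair site counts after pairwise deletion."""

    n_compared: int
    n_transitions: int
    n_transversions: int


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode sequences as a (n, L) uint8 matrix; A,C,G,T -> 0..3, else 255."""
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    table = np.full(256, _INVALID, dtype=np.uint8)
    for base, code in _CODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return table[arr].reshape(len(seqs), lengths.pop())


def count_site_pairs(a: str, b: str) -> PairSiteCounts:
    """Count compared sites, transitions and transversions for one pair.

    Sites with a gap or ambiguity code in either sequence are excluded
    from all three counts.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal sequence lengths: {len(a)} vs {len(b)}")
    x, y = encode_sequences([a, b])
    valid = (x != _INVALID) & (y != _INVALID)
    n_compared = int(valid.sum())
    diff = valid & (x != y)
    # transitions are within-purine (A<->G: codes 0,2) or within-pyrimidine
    # (C<->T: codes 1,3), i.e. codes congruent mod 2
    transition = diff & ((x % 2) == (y % 2))
    n_ts = int(transition.sum())
    n_tv = int(diff.sum()) - n_ts
    return PairSiteCounts(n_compared, n_ts, n_tv)


def k2p_from_pq(P: float, Q: float) -> float:
    """K2P distance from transition/transversion proportions; NaN if saturated."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(counts: PairSiteCounts) -> float:
    """K2P distance for one pair; NaN when no sites overlap or saturated."""
    if counts.n_compared == 0:
        return math.nan
    P = counts.n_transitions / counts.n_compared
    Q = counts.n_transversions / counts.n_compared
    return k2p_from_pq(P, Q)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over labelled samples.

    ``d`` holds substitutions/site with NaN for undefined (saturated or
    non-overlapping) pairs; ``se`` optionally holds parallel bootstrap
    standard errors.  ``undefined_pairs`` lists the label pairs whose
    estimate is undefined.
    """

    labels: list[str]
    d: np.ndarray
    se: np.ndarray | None = None
    undefined_pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != n:
            raise ValueError("duplicate labels in DistanceMatrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in labels]
        sub = self.d[np.ix_(idx, idx)]
        sub_se = self.se[np.ix_(idx, idx)] if self.se is not None else None
        labset = set(labels)
        undef = {p for p in self.undefined_pairs if p[0] in labset and p[1] in labset}
        return DistanceMatrix(list(labels), sub.copy(),
                              sub_se.copy() if sub_se is not None else None, undef)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values (i<j) in row-major order, NaNs included."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def write_tsv(self, path: str | Path) -> None:
        """Write as lower-triangular TSV with a leading label column."""
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                cells = [f"{self.d[i, j]:.6f}" if not math.isnan(self.d[i, j]) else "NA"
                         for j in range(i + 1)]
                fh.write(lab + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            labels = header[1:]
            n = len(labels)
            d = np.zeros((n, n))
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split("\t")
                for j, cell in enumerate(parts[1:]):
                    v = math.nan if cell == "NA" else float(cell)
                    d[i, j] = d[j, i] = v
        undef = {
            (labels[i], labels[j])
            for i in range(n) for j in range(i + 1, n)
            if math.isnan(d[i, j])
        }
        return cls(labels, d, undefined_pairs=undef)


def _pair_count_arrays(
    X: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised pairwise (n_compared, n_transitions, n_transversions).

    ``weights`` gives per-column multiplicities (site bootstrap); None
    means unit weights.  Counting is done with indicator-matrix products,
    which keeps the full-matrix build fast for ~1000 sequences.
    """
    n, L = X.shape
    w = np.ones(L) if weights is None else weights.astype(float)
    V = (X != _INVALID).astype(float)
    M = [(X == c).astype(float) for c in range(4)]
    Vw = V * w
    compared = Vw @ V.T
    matches = sum((Mb * w) @ Mb.T for Mb in M)
    ts = (M[0] * w) @ M[2].T + (M[2] * w) @ M[0].T \
        + (M[1] * w) @ M[3].T + (M[3] * w) @ M[1].T
    tv = compared - matches - ts
    return compared, ts, tv


def _k2p_matrix(compared: np.ndarray, ts: np.ndarray, tv: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / compared
        Q = tv / compared
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where(
            (compared > 0) & (w1 > 0) & (w2 > 0),
            -0.5 * np.log(np.maximum(w1, 1e-300))
            - 0.25 * np.log(np.maximum(w2, 1e-300)),
            np.nan,
        )
    np.fill_diagonal(d, 0.0)
    return d


def build_matrix(
    sset: SequenceSet, weights: np.ndarray | None = None
) -> DistanceMatrix:
    """K2P distance matrix over an aligned :class:`SequenceSet`.

    Each unordered pair is computed once via pairwise-deletion site counts;
    saturated or non-overlapping pairs become NaN and are recorded in
    ``undefined_pairs``.  ``weights`` supplies column multiplicities for
    site-bootstrap replicates.
    """
    labels = sset.ids
    X = encode_sequences([r.sequence for r in sset])
    compared, ts, tv = _pair_count_arrays(X, weights)
    d = _k2p_matrix(compared, ts, tv)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    undef = {
        (labels[i], labels[j])
        for i, j in zip(*iu)
        if math.isnan(d[i, j])
    }
    return DistanceMatrix(labels, d, undefined_pairs=undef)


def bootstrap_se(
    sset: SequenceSet,
    statistic: Callable[[DistanceMatrix], float],
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Site-bootstrap standard error of ``statistic``.

    Alignment columns are resampled with replacement (same length), the
    distance matrix is rebuilt per replicate and ``statistic`` re-evaluated;
    the SE is the standard deviation across replicates.  Replicates where
    the statistic is undefined (NaN) are dropped; if more than half are
    undefined the SE itself is reported as NaN.  Deterministic for a fixed
    seed.
    """
    if reps < 2:
        raise ValueError("bootstrap requires reps >= 2")
    L = sset.length
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        weights = np.bincount(cols, minlength=L).astype(float)
        values.append(statistic(build_matrix(sset, weights)))
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if ok.sum() < reps / 2:
        return math.nan
    return float(np.std(values[ok], ddof=1))


@dataclass
class GroupSummary:
    """Within- and between-group distance statistics at one grouping level.

    Within statistics are NaN for singleton groups.  ``n_undefined`` counts
    pairs excluded because their distance estimate was undefined.
    """

    level: str
    groups: list[Hashable]
    n_members: dict[Hashable, int]
    mean_within: dict[Hashable, float]
    max_within: dict[Hashable, float]
    n_within_pairs: dict[Hashable, int]
    mean_between: dict[tuple[Hashable, Hashable], float]
    min_between: dict[tuple[Hashable, Hashable], float]
    n_between_pairs: dict[tuple[Hashable, Hashable], int]
    n_undefined: int = 0
    se_within: dict[Hashable, float] = field(default_factory=dict)
    se_between: dict[tuple[Hashable, Hashable], float] = field(default_factory=dict)

    @staticmethod
    def pair_key(g: Hashable, h: Hashable) -> tuple[Hashable, Hashable]:
        return tuple(sorted((g, h), key=str))  # type: ignore[return-value]

    def get_mean_between(self, g: Hashable, h: Hashable) -> float:
        return self.mean_between[self.pair_key(g, h)]

    def get_min_between(self, g: Hashable, h: Hashable) -> float:
        return self.min_between[self.pair_key(g, h)]

    def overall_mean_within(self, mode: str = "unweighted") -> float:
        """Level-wide within-group mean.

        ``unweighted``: mean of per-group means over groups with >= 2
        members.  ``pooled``: mean over all within-group pairs.
        """
        eligible = [g for g in self.groups if self.n_members[g] >= 2
                    and not math.isnan(self.mean_within[g])]
        if not eligible:
            return math.nan
        if mode == "unweighted":
            return float(np.mean([self.mean_within[g] for g in eligible]))
        if mode == "pooled":
            tot = sum(self.mean_within[g] * self.n_within_pairs[g] for g in eligible)
            npairs = sum(self.n_within_pairs[g] for g in eligible)
            return tot / npairs
        raise ValueError(f"unknown mode {mode!r}")

    def overall_mean_between(self, mode: str = "unweighted") -> float:
        keys = [k for k in self.mean_between if not math.isnan(self.mean_between[k])]
        if not keys:
            return math.nan
        if mode == "unweighted":
            return float(np.mean([self.mean_between[k] for k in keys]))
        if mode == "pooled":
            tot = sum(self.mean_between[k] * self.n_between_pairs[k] for k in keys)
            npairs = sum(self.n_between_pairs[k] for k in keys)
            return tot / npairs
        raise ValueError(f"unknown mode {mode!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": str(g),
                "n": self.n_members[g],
                "mean_within": self.mean_within[g],
                "max_within": self.max_within[g],
                "se_within": self.se_within.get(g, math.nan),
            }
            for g in self.groups
        ]
        return pd.DataFrame(rows)


def summarize_groups(
    matrix: DistanceMatrix,
    grouping: Mapping[str, Hashable],
    level: str = "species",
) -> GroupSummary:
    """Aggregate a distance matrix into within/between group statistics.

    Every matrix label must be assigned to exactly one group.  Undefined
    pairs are excluded from all statistics and counted in ``n_undefined``.
    """
    missing = [lab for lab in matrix.labels if lab not in grouping]
    if missing:
        raise ValueError(f"grouping is missing labels: {missing[:5]}")
    groups = sorted({grouping[lab] for lab in matrix.labels}, key=str)
    members = {g: [lab for lab in matrix.labels if grouping[lab] == g] for g in groups}

    n_members, mean_w, max_w, n_w = {}, {}, {}, {}
    n_undef = 0
    for g in groups:
        idx = [matrix.index(lab) for lab in members[g]]
        n_members[g] = len(idx)
        if len(idx) < 2:
            mean_w[g] = max_w[g] = math.nan
            n_w[g] = 0
            continue
        sub = matrix.d[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
        ok = sub[~np.isnan(sub)]
        n_undef += int(np.isnan(sub).sum())
        if ok.size == 0:
            mean_w[g] = max_w[g] = math.nan
            n_w[g] = 0
        else:
            mean_w[g] = float(ok.mean())
            max_w[g] = float(ok.max())
            n_w[g] = int(ok.size)

    mean_b, min_b, n_b = {}, {}, {}
    for i, g in enumerate(groups):
        gi = [matrix.index(lab) for lab in members[g]]
        for h in groups[i + 1:]:
            hi = [matrix.index(lab) for lab in members[h]]
            block = matrix.d[np.ix_(gi, hi)].ravel()
            ok = block[~np.isnan(block)]
            n_undef += int(np.isnan(block).sum())
            key = GroupSummary.pair_key(g, h)
            if ok.size == 0:
                mean_b[key] = min_b[key] = math.nan
                n_b[key] = 0
            else:
                mean_b[key] = float(ok.mean())
                min_b[key] = float(ok.min())
                n_b[key] = int(ok.size)

    return GroupSummary(
        level=level,
        groups=groups,
        n_members=n_members,
        mean_within=mean_w,
        max_within=max_w,
        n_within_pairs=n_w,
        mean_between=mean_b,
        min_between=min_b,
        n_between_pairs=n_b,
        n_undefined=n_undef,
    )


def overall_mean_distance(matrix: DistanceMatrix) -> float:
    """Mean of all defined pairwise distances (Table-1 style overall mean)."""
    vals = matrix.condensed()
    ok = vals[~np.isnan(vals)]
    return float(ok.mean()) if ok.size else math.nan
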