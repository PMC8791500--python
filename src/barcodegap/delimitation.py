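"""Threshold- and barcoding-gap-based species identification rules.

A species is considered successfully identified by its barcode when it can
be told apart from every congener.  Failure requires all three of: a mean
distance to some congener below the threshold (default 0.0200
substitutions/site), no barcoding gap against that congener, and no
diagnosability.  The barcoding gap uses the min/max rule by default — the
minimum between-group distance strictly exceeds the maximum within-group
distance of both groups — with the classical tenfold mean-ratio rule
available as an option.  Diagnosability captures the case of a species that
lacks a gap against a congener yet forms an exclusive cluster: every one of
its sequences has its nearest non-self neighbour inside the species and no
haplotype is shared with the congener.

Per-species reports carry the flags used in barcode-survey tables:

    a — mean within-species distance above the threshold (possible split),
    b — closest congener below threshold, no gap, not diagnosable (failure),
    c — closest congener below threshold but a gap is present (identified).

Population-level split proposals apply the same threshold + gap criterion
to geographically separated populations within one species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .distances import DistanceMatrix, GroupSummary, summarize_groups

__all__ = [
    "DelimitationConfig",
    "SpeciesReport",
    "SplitProposal",
    "barcoding_gap_test",
    "classify_species",
    "propose_splits",
    "success_rate",
]


@dataclass(frozen=True)
class DelimitationConfig:
    """Decision-rule parameters for species identification."""

    threshold: float = 0.0200
    gap_rule: str = "minmax"  # {"minmax", "tenfold"}
    diagnosability_rule: str = "nearest_neighbor"  # {"nearest_neighbor", "gap_only"}

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.gap_rule not in ("minmax", "tenfold"):
            raise ValueError(f"unknown gap_rule {self.gap_rule!r}")
        if self.diagnosability_rule not in ("nearest_neighbor", "gap_only"):
            raise ValueError(f"unknown diagnosability_rule {self.diagnosability_rule!r}")


def _within_or_zero(summary: GroupSummary, g: Hashable, stat: dict) -> float:
    # singleton groups cannot overlap themselves; treat their within
    # statistic as 0 for gap purposes
    v = stat.get(g, math.nan)
    return 0.0 if math.isnan(v) else v


def barcoding_gap_test(
    summary: GroupSummary, g: Hashable, h: Hashable, rule: str = "minmax"
) -> bool:
    """Is there a barcoding gap between groups ``g`` and ``h``?

    minmax: min_between(g,h) strictly greater than the larger of the two
    within-group maxima.  tenfold: mean_between at least ten times the
    larger within-group mean.  Singleton groups contribute 0.
    """
    if rule == "minmax":
        mb = summary.get_min_between(g, h)
        wmax = max(_within_or_zero(summary, g, summary.max_within),
                   _within_or_zero(summary, h, summary.max_within))
        return not math.isnan(mb) and mb > wmax
    if rule == "tenfold":
        mb = summary.get_mean_between(g, h)
        wmean = max(_within_or_zero(summary, g, summary.mean_within),
                    _within_or_zero(summary, h, summary.mean_within))
        if math.isnan(mb):
            return False
        if wmean == 0.0:
            return mb > 0.0
        return mb >= 10.0 * wmean
    raise ValueError(f"unknown gap rule {rule!r}")


@dataclass(frozen=True)
class SpeciesReport:
    """Identification verdict and supporting distances for one species."""

    species: Hashable
    n_sequences: int
    identified: bool
    flags: frozenset[str]
    closest_congener: Hashable | None
    mean_within: float
    max_within: float
    mean_to_closest: float
    min_to_closest: float
    gap_with_closest: bool | None  # None for the sole species of its genus


def _nearest_neighbor_diagnosable(
    matrix: DistanceMatrix,
    grouping: Mapping[str, Hashable],
    species: Hashable,
    other: Hashable,
    haplotype_overlap: set[frozenset] | None,
) -> bool:
    """Exclusive-cluster test for ``species`` against congener ``other``.

    True when every sequence of the species is strictly nearer to another
    conspecific than to any non-conspecific in the matrix, and the two
    species share no haplotype.
    """
    if haplotype_overlap and frozenset((species, other)) in haplotype_overlap:
        return False
    members = [lab for lab in matrix.labels if grouping[lab] == species]
    if len(members) < 2:
        return False
    midx = np.array([matrix.index(lab) for lab in members])
    mask = np.zeros(matrix.n, dtype=bool)
    mask[midx] = True
    for i in midx:
        row = matrix.d[i]
        inside = row[mask & (np.arange(matrix.n) != i)]
        outside = row[~mask]
        if outside.size == 0:
            continue
        d_in = np.nanmin(inside) if inside.size else math.inf
        d_out = np.nanmin(outside)
        if not (d_in < d_out):
            return False
    return True


def classify_species(
    species: Hashable,
    genus_summary: GroupSummary,
    haplotype_overlap: set[frozenset] | None = None,
    config: DelimitationConfig = DelimitationConfig(),
    *,
    matrix: DistanceMatrix | None = None,
    grouping: Mapping[str, Hashable] | None = None,
) -> SpeciesReport:
    """Classify one species against its congeners.

    ``genus_summary`` is the species-level :class:`GroupSummary` for the
    genus; ``matrix`` and ``grouping`` (the per-genus matrix and its
    sample->species map) are required for the nearest-neighbour
    diagnosability rule.  A species alone in its genus is identified by
    definition with no closest congener.
    """
    if species not in genus_summary.groups:
        raise ValueError(f"species {species!r} not present in summary")
    if config.diagnosability_rule == "nearest_neighbor" and (
        matrix is None or grouping is None
    ):
        raise ValueError("nearest_neighbor rule requires matrix and grouping")

    congeners = [g for g in genus_summary.groups if g != species]
    n_seq = genus_summary.n_members[species]
    mean_w = genus_summary.mean_within.get(species, math.nan)
    max_w = genus_summary.max_within.get(species, math.nan)

    flags: set[str] = set()
    if not math.isnan(mean_w) and mean_w > config.threshold:
        flags.add("a")

    if not congeners:
        return SpeciesReport(
            species=species, n_sequences=n_seq, identified=True,
            flags=frozenset(flags), closest_congener=None,
            mean_within=mean_w, max_within=max_w,
            mean_to_closest=math.nan, min_to_closest=math.nan,
            gap_with_closest=None,
        )

    def mean_to(t: Hashable) -> float:
        return genus_summary.get_mean_between(species, t)

    defined = [t for t in congeners if not math.isnan(mean_to(t))]
    closest = min(defined, key=mean_to) if defined else congeners[0]
    mean_c = mean_to(closest)
    min_c = genus_summary.get_min_between(species, closest)
    gap_c = barcoding_gap_test(genus_summary, species, closest, config.gap_rule)

    def diagnosable_from(t: Hashable) -> bool:
        if config.diagnosability_rule == "gap_only":
            return False
        return _nearest_neighbor_diagnosable(
            matrix, grouping, species, t, haplotype_overlap
        )

    identified = True
    for t in defined:
        if mean_to(t) < config.threshold \
                and not barcoding_gap_test(genus_summary, species, t, config.gap_rule) \
                and not diagnosable_from(t):
            identified = False
            break

    if not math.isnan(mean_c) and mean_c < config.threshold:
        if gap_c:
            flags.add("c")
        elif not identified:
            flags.add("b")

    return SpeciesReport(
        species=species, n_sequences=n_seq, identified=identified,
        flags=frozenset(flags), closest_congener=closest,
        mean_within=mean_w, max_within=max_w,
        mean_to_closest=mean_c, min_to_closest=min_c,
        gap_with_closest=gap_c,
    )


@dataclass(frozen=True)
class SplitProposal:
    """A pair of populations within one species proposed as separate species."""

    species: Hashable
    population_a: Hashable
    population_b: Hashable
    mean_between: float
    min_between: float
    max_within_a: float
    max_within_b: float


def propose_splits(
    species: Hashable,
    population_grouping: Mapping[str, Hashable],
    matrix: DistanceMatrix,
    config: DelimitationConfig = DelimitationConfig(),
) -> list[SplitProposal]:
    """Propose population-level splits within one species.

    ``population_grouping`` maps the species' sample ids to region
    populations; ``matrix`` must cover (at least) those samples.  A pair of
    populations is proposed when its mean between-population distance
    exceeds the threshold and the barcoding gap test passes.
    """
    members = [lab for lab in matrix.labels if lab in population_grouping]
    pops = {population_grouping[lab] for lab in members}
    if len(pops) < 2:
        return []
    sub = matrix.submatrix(members)
    summary = summarize_groups(
        sub, {lab: population_grouping[lab] for lab in members}, level="population"
    )
    proposals = []
    for i, g in enumerate(summary.groups):
        for h in summary.groups[i + 1:]:
            mb = summary.get_mean_between(g, h)
            if math.isnan(mb) or mb <= config.threshold:
                continue
            if not barcoding_gap_test(summary, g, h, config.gap_rule):
                continue
            proposals.append(SplitProposal(
                species=species, population_a=g, population_b=h,
                mean_between=mb,
                min_between=summary.get_min_between(g, h),
                max_within_a=_within_or_zero(summary, g, summary.max_within),
                max_within_b=_within_or_zero(summary, h, summary.max_within),
            ))
    return proposals


class SuccessRate(NamedTuple):
    identified: int
    total: int
    fraction: float
    gap_fraction: float  # among identified species


def success_rate(reports: Sequence[SpeciesReport]) -> SuccessRate:
    """Identification success rate and gap prevalence among successes.

    Species that are the sole member of their genus count as exhibiting a
    gap (there is no congener comparison to fail).
    """
    if not reports:
        raise ValueError("no species reports")
    identified = [r for r in reports if r.identified]
    with_gap = [r for r in identified if r.gap_with_closest is not False]
    frac = len(identified) / len(reports)
    gap_frac = len(with_gap) / len(identified) if identified else math.nan
    return SuccessRate(len(identified), len(reports), frac, gap_frac)
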