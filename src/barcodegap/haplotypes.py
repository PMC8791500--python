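"""Haplotype collapsing, sharing between species, and regional privacy.

A haplotype is a unique sequence string over the common analysis window
(case-insensitive exact identity; ambiguity codes compare literally, so a
sequence with an N forms its own haplotype rather than being merged into a
compatible one).  Haplotype sharing between nominal species is evidence
against their separability; haplotypes private to one sampling region make
the geographic origin of a specimen recoverable from its barcode.

A (species, region) population is flagged as region-specific when every
haplotype observed in that population occurs in no other region for that
species; species sampled in a single region are excluded, since privacy is
vacuous there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable

import pandas as pd

from .seqio import SequenceSet

__all__ = [
    "Haplotype",
    "HaplotypeCatalog",
    "collapse",
    "shared_haplotypes",
    "region_specific_report",
]


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    sequence: str
    members: tuple[str, ...]
    species: frozenset
    regions: frozenset


@dataclass
class HaplotypeCatalog:
    """Collapsed unique sequences with member, species and region sets."""

    haplotypes: list[Haplotype]

    def __len__(self) -> int:
        return len(self.haplotypes)

    def by_id(self, haplotype_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.haplotype_id == haplotype_id:
                return h
        raise KeyError(haplotype_id)

    def member_haplotype(self) -> dict[str, str]:
        return {m: h.haplotype_id for h in self.haplotypes for m in h.members}

    def species_haplotypes(self) -> dict[Hashable, set[str]]:
        out: dict[Hashable, set[str]] = {}
        for h in self.haplotypes:
            for sp in h.species:
                out.setdefault(sp, set()).add(h.haplotype_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "haplotype": h.haplotype_id,
                "n_members": len(h.members),
                "species": ";".join(sorted(f"{g} {s}" for g, s in h.species)),
                "regions": ";".join(sorted(h.regions)),
            }
            for h in self.haplotypes
        ]
        return pd.DataFrame(rows)


def collapse(sset: SequenceSet) -> HaplotypeCatalog:
    """Collapse an aligned :class:`SequenceSet` into unique haplotypes.

    Haplotype ids ``H0001, H0002, ...`` are assigned in order of first
    occurrence, so the catalog is deterministic for a given record order
    and invariant to order up to relabelling.
    """
    sset.length  # raises if not aligned
    seen: dict[str, list] = {}
    order: list[str] = []
    for rec in sset:
        key = rec.sequence.upper()
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(rec)
    haplotypes = []
    for i, key in enumerate(order, start=1):
        recs = seen[key]
        haplotypes.append(Haplotype(
            haplotype_id=f"H{i:04d}",
            sequence=key,
            members=tuple(r.sample_id for r in recs),
            species=frozenset(r.species for r in recs),
            regions=frozenset(r.region for r in recs),
        ))
    return HaplotypeCatalog(haplotypes)


def shared_haplotypes(
    catalog: HaplotypeCatalog,
) -> list[tuple[Hashable, Hashable, list[str]]]:
    """Species pairs sharing at least one haplotype.

    Returns ``(species_a, species_b, shared haplotype ids)`` with each
    unordered pair reported once, sorted for determinism.
    """
    pair_haps: dict[tuple, list[str]] = {}
    for h in catalog.haplotypes:
        sps = sorted(h.species, key=str)
        for i, a in enumerate(sps):
            for b in sps[i + 1:]:
                pair_haps.setdefault((a, b), []).append(h.haplotype_id)
    return [
        (a, b, sorted(haps))
        for (a, b), haps in sorted(pair_haps.items(), key=lambda kv: str(kv[0]))
    ]


@dataclass(frozen=True)
class RegionFlag:
    """A (species, region) population whose haplotypes are all private."""

    species: Hashable
    region: str
    private_haplotypes: tuple[str, ...]


def region_specific_report(
    catalog: HaplotypeCatalog, sset: SequenceSet
) -> list[RegionFlag]:
    """Flag populations whose every haplotype is private to one region.

    ``sset`` supplies the member-level (species, region) metadata; the
    catalog's own species/region sets are per-haplotype and cannot resolve
    which member carried which region.  Only species sampled from two or
    more regions are considered.  For a flagged (species, region),
    observing any of the listed haplotypes in a specimen of that species
    pins its geographic origin to that region.
    """
    member_hap = catalog.member_haplotype()
    species_regions: dict[Hashable, set[str]] = {}
    pop_haps: dict[tuple[Hashable, str], set[str]] = {}
    hap_regions: dict[tuple[Hashable, str], set[str]] = {}
    for rec in sset:
        hap = member_hap[rec.sample_id]
        species_regions.setdefault(rec.species, set()).add(rec.region)
        pop_haps.setdefault((rec.species, rec.region), set()).add(hap)
        hap_regions.setdefault((rec.species, hap), set()).add(rec.region)

    flags = []
    for (sp, region), haps in sorted(pop_haps.items(), key=lambda kv: str(kv[0])):
        if len(species_regions[sp]) < 2:
            continue
        if all(hap_regions[(sp, h)] == {region} for h in haps):
            flags.append(RegionFlag(
                species=sp, region=region, private_haplotypes=tuple(sorted(haps)),
            ))
    return flags
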