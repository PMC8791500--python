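"""Barcode FASTA input/output with structured headers.

Barcode datasets are distributed as multi-FASTA files whose record names
encode the specimen metadata: genus, species label, sampling region and a
database accession (e.g. a BOLD process ID), typically joined with
underscores::

    >Alburnus_thessalicus_Volvi_GFFB311-18

This module parses such headers into :class:`SequenceRecord` objects,
validates the sequences against the IUPAC nucleotide alphabet (plus the
alignment gap ``-``), and truncates pre-aligned sequence sets to a common
analysis window.  Sequences are assumed pre-aligned: COI barcodes are
protein-coding and indel-free over the amplicon, so the only length
heterogeneity comes from reads of different lengths sharing the same 5'
anchor.  No multiple alignment is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

__all__ = [
    "HeaderSchema",
    "SequenceRecord",
    "SequenceSet",
    "read_fasta",
    "write_fasta",
    "truncate_to_overlap",
]


@dataclass(frozen=True)
class HeaderSchema:
    """How a FASTA header maps to specimen metadata.

    ``fields`` names the delimited fields in order; it must contain
    ``genus``, ``species``, ``region`` and ``accession`` exactly once.
    """

    delimiter: str = "_"
    fields: tuple[str, ...] = ("genus", "species", "region", "accession")

    def __post_init__(self) -> None:
        required = {"genus", "species", "region", "accession"}
        if set(self.fields) != required or len(self.fields) != 4:
            raise ValueError(
                f"schema fields must be a permutation of {sorted(required)}, "
                f"got {self.fields!r}"
            )

    def parse(self, header: str) -> dict[str, str]:
        parts = header.strip().split(self.delimiter)
        if len(parts) != len(self.fields):
            raise ValueError(
                f"header {header!r} does not match schema "
                f"{self.delimiter.join(self.fields)!r} "
                f"({len(parts)} fields, expected {len(self.fields)})"
            )
        return dict(zip(self.fields, parts))

    def format(self, record: "SequenceRecord") -> str:
        values = {
            "genus": record.genus,
            "species": record.species_label,
            "region": record.region,
            "accession": record.sample_id,
        }
        return self.delimiter.join(values[f] for f in self.fields)


DEFAULT_SCHEMA = HeaderSchema()


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with its specimen metadata.

    ``species_label`` is a free-form string (it may be informal, e.g.
    ``"sp. Volvi"``) and is never interpreted taxonomically; the pair
    ``(genus, species_label)`` identifies a species group.
    """

    sample_id: str
    genus: str
    species_label: str
    region: str
    sequence: str
    source: str = "study"  # {"study", "retrieved"}

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.sample_id}: sequence must be nonempty")
        seq = self.sequence.upper()
        bad = [(i, c) for i, c in enumerate(seq) if c not in IUPAC_CHARS]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"{self.sample_id}: invalid character {c!r} at position {i} "
                "(expected IUPAC nucleotide code or '-')"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def species(self) -> tuple[str, str]:
        return (self.genus, self.species_label)

    def __len__(self) -> int:
        return len(self.sequence)


class SequenceSet:
    """An ordered collection of :class:`SequenceRecord` with lookup indices.

    ``aligned`` is True when every record has the same length (the state
    required by the distance, haplotype and tree modules).
    """

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        seen: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.sample_id in seen:
                raise ValueError(
                    f"duplicate sample_id {rec.sample_id!r} at entries "
                    f"{seen[rec.sample_id]} and {i}"
                )
            seen[rec.sample_id] = i
        self._by_id = seen
        self.by_genus: dict[str, list[str]] = {}
        self.by_species: dict[tuple[str, str], list[str]] = {}
        self.by_region: dict[str, list[str]] = {}
        for rec in self.records:
            self.by_genus.setdefault(rec.genus, []).append(rec.sample_id)
            self.by_species.setdefault(rec.species, []).append(rec.sample_id)
            self.by_region.setdefault(rec.region, []).append(rec.sample_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SequenceRecord:
        return self.records[self._by_id[sample_id]]

    @property
    def ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def aligned(self) -> bool:
        lengths = {len(r) for r in self.records}
        return len(lengths) <= 1

    @property
    def length(self) -> int:
        """Common sequence length; raises if the set is not aligned."""
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"sequence lengths are heterogeneous: {sorted(lengths)}")
        return lengths.pop()

    def subset(self, sample_ids: Sequence[str]) -> "SequenceSet":
        return SequenceSet(self[sid] for sid in sample_ids)

    def genus_subset(self, genus: str) -> "SequenceSet":
        return self.subset(self.by_genus[genus])

    def species_grouping(self) -> dict[str, tuple[str, str]]:
        """Map sample_id -> (genus, species_label)."""
        return {r.sample_id: r.species for r in self.records}

    def region_grouping(self) -> dict[str, str]:
        return {r.sample_id: r.region for r in self.records}


def read_fasta(
    path: str | Path,
    schema: HeaderSchema = DEFAULT_SCHEMA,
    source: str = "study",
) -> SequenceSet:
    """Read a barcode FASTA into a :class:`SequenceSet`.

    Headers are parsed with ``schema``; sequences are upper-cased and
    validated.  Record order follows the file.  Duplicate ids, invalid
    characters and non-conforming headers raise ``ValueError``.
    """
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        meta = schema.parse(bio.id)
        records.append(
            SequenceRecord(
                sample_id=meta["accession"],
                genus=meta["genus"],
                species_label=meta["species"],
                region=meta["region"],
                sequence=str(bio.seq),
                source=source,
            )
        )
    return SequenceSet(records)


def write_fasta(
    sset: SequenceSet,
    path: str | Path,
    schema: HeaderSchema = DEFAULT_SCHEMA,
) -> None:
    """Write a :class:`SequenceSet` as single-line FASTA.

    Round trip: ``read_fasta(write_fasta(S))`` reproduces ``S`` exactly.
    """
    if len(sset) == 0:
        raise ValueError("refusing to write an empty SequenceSet")
    bio_records = [
        _BioSeqRecord(Seq(rec.sequence), id=schema.format(rec), description="")
        for rec in sset
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(bio_records)


def truncate_to_overlap(sset: SequenceSet, window: int | None = None) -> SequenceSet:
    """Trim every sequence to a common left-anchored window.

    Without an explicit ``window`` the maximal length covered by all
    records (the minimum record length) is used.  Trimming removes
    trailing positions only, matching the 5'-anchored barcode fragment.
    Idempotent; an already-uniform set at the target length is returned
    unchanged.
    """
    if len(sset) == 0:
        raise ValueError("cannot truncate an empty SequenceSet")
    shortest = min(len(r) for r in sset)
    if window is None:
        window = shortest
    elif window > shortest:
        raise ValueError(
            f"window {window} exceeds the shortest sequence length {shortest}"
        )
    if all(len(r) == window for r in sset):
        return sset
    return SequenceSet(
        replace(r, sequence=r.sequence[:window]) for r in sset
    )
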