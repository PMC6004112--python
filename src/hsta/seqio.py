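"""Sequence and taxonomy I/O.

Reference sequences are plain nucleotide FASTA; taxonomy is a TSV mapping
``id<TAB>order[<TAB>species]``.  Records are carried around as
:class:`TaxonRecord`, the unit every downstream stage (back-alignment,
profile building, simulation truth tables) consumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TaxonRecord",
    "read_fasta",
    "write_fasta",
    "read_taxonomy_tsv",
    "write_taxonomy_tsv",
    "attach_taxonomy",
]

_NUC = set("ACGTN")


@dataclass(frozen=True)
class TaxonRecord:
    """A labeled nucleotide sequence.

    ``order_label`` is the order-rank taxon name (e.g. ``Coleoptera``);
    ``species_label`` is present only for records identified to species.
    """

    id: str
    seq: str
    order_label: str = ""
    species_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.seq.upper()) - _NUC
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path | io.TextIOBase) -> list[TaxonRecord]:
    """Read a nucleotide FASTA into unlabeled :class:`TaxonRecord` objects.

    Duplicate ids are rejected.  CRLF input is accepted (Biopython strips it).
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            records.append(TaxonRecord(id=rec.id, seq=str(rec.seq)))
        return records
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def write_fasta(
    records: Iterable[TaxonRecord], path: str | Path | io.TextIOBase, wrap: int = 60
) -> None:
    """Write records as multi-line FASTA wrapped at ``wrap`` columns."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    handle = open(path, "w") if isinstance(path, (str, Path)) else path
    try:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(seqrecs)
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def read_gapped_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a gapped FASTA (an alignment) into parallel id and row lists."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return ids, rows


def write_gapped_fasta(
    ids: Iterable[str], rows: Iterable[str], path: str | Path, wrap: int = 60
) -> None:
    """Write alignment rows (which may contain gaps) as FASTA."""
    seqrecs = [SeqRecord(Seq(row), id=i, description="") for i, row in zip(ids, rows)]
    with open(path, "w") as handle:
        SeqIO.FastaIO.FastaWriter(handle, wrap=wrap).write_file(seqrecs)


def read_taxonomy_tsv(path: str | Path | io.TextIOBase) -> dict[str, tuple[str, str | None]]:
    """Read ``id<TAB>order[<TAB>species]`` into ``{id: (order, species)}``."""
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        out: dict[str, tuple[str, str | None]] = {}
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"taxonomy line {lineno}: expected id<TAB>order[<TAB>species]")
            if parts[0] in out:
                raise ValueError(f"duplicate taxonomy id {parts[0]!r}")
            species = parts[2] if len(parts) > 2 and parts[2] else None
            out[parts[0]] = (parts[1], species)
        return out
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def write_taxonomy_tsv(
    records: Iterable[TaxonRecord], path: str | Path | io.TextIOBase
) -> None:
    handle = open(path, "w") if isinstance(path, (str, Path)) else path
    try:
        for r in records:
            cols = [r.id, r.order_label]
            if r.species_label:
                cols.append(r.species_label)
            handle.write("\t".join(cols) + "\n")
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def attach_taxonomy(
    records: Iterable[TaxonRecord], taxonomy: Mapping[str, tuple[str, str | None]]
) -> list[TaxonRecord]:
    """Return records with order/species labels filled from a taxonomy map.

    Every record id must be present in the map.
    """
    out = []
    for r in records:
        if r.id not in taxonomy:
            raise KeyError(f"record {r.id!r} missing from taxonomy map")
        order, species = taxonomy[r.id]
        out.append(TaxonRecord(id=r.id, seq=r.seq, order_label=order, species_label=species))
    return out
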