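"""Translation and protein-guided back-alignment.

Reference coxI sequences are protein-coding: aligning them at the amino-acid
level and then threading each codon through the protein alignment
("back-alignment") yields a nucleotide MSA whose gaps always come in whole
codons and whose columns respect the reading frame.  Nucleotide profile HMMs
are then built from that codon alignment.

coxI is mitochondrial, so the invertebrate mitochondrial code is the default
genetic code; the standard code is selectable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .seqio import TaxonRecord

__all__ = [
    "translate",
    "choose_frame",
    "ProteinAlignment",
    "CodonAlignment",
    "back_align",
]

logger = logging.getLogger(__name__)

#: Biopython codon-table ids: 5 = invertebrate mitochondrial, 1 = standard.
GENETIC_CODES = {"invertebrate_mito": 5, "standard": 1}
DEFAULT_CODE = "invertebrate_mito"


def _table(code: str) -> CodonTable.CodonTable:
    try:
        return CodonTable.unambiguous_dna_by_id[GENETIC_CODES[code]]
    except KeyError:
        raise ValueError(f"unknown genetic code {code!r}; choose from {sorted(GENETIC_CODES)}")


def translate(
    seq: str,
    frame: int = 0,
    code: str = DEFAULT_CODE,
    internal_stop: str = "X",
) -> str:
    """Translate in-frame codons of ``seq``; trailing partial codon dropped.

    Codons containing ``N`` translate to ``'X'``.  Stop codons translate to
    ``'*'`` by default at the terminal position; internal stops are replaced
    by ``internal_stop`` (``'X'``) with a warning, since reference sets may
    contain pseudogene-like entries.
    """
    if not seq:
        raise ValueError("cannot translate an empty sequence")
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if len(seq) < 3 + frame:
        raise ValueError(f"sequence too short ({len(seq)} nt) for frame {frame}")
    table = _table(code)
    seq = seq.upper()
    aa = []
    codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
    for i, codon in enumerate(codons):
        if "N" in codon:
            aa.append("X")
        elif codon in table.stop_codons:
            if i < len(codons) - 1:
                logger.warning("internal stop codon %s at codon %d; emitting %r", codon, i + 1, internal_stop)
                aa.append(internal_stop)
            else:
                aa.append("*")
        else:
            aa.append(table.forward_table[codon])
    return "".join(aa)


def choose_frame(seq: str, code: str = DEFAULT_CODE) -> int:
    """Pick the reading frame with the fewest internal stop codons.

    Ties break toward the frame with the longest translation, then the
    lowest frame index.  This is the default used when the frame of a
    reference is not known a priori.
    """
    best = None
    for frame in (0, 1, 2):
        if len(seq) < 3 + frame:
            continue
        table = _table(code)
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        stops = sum(c in table.stop_codons for c in codons[:-1])
        key = (stops, -len(codons), frame)
        if best is None or key < best[0]:
            best = (key, frame)
    if best is None:
        raise ValueError("sequence shorter than one codon in every frame")
    return best[1]


@dataclass(frozen=True)
class ProteinAlignment:
    """An amino-acid MSA: equal-length gapped rows keyed by id."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise ValueError("all alignment rows must have the same length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rec_id: str) -> str:
        return self.rows[self.ids.index(rec_id)]


@dataclass(frozen=True)
class CodonAlignment:
    """A nucleotide MSA threaded through a protein MSA, gaps in whole codons."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    source: ProteinAlignment | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if self.rows:
            n = len(self.rows[0])
            if n % 3 != 0:
                raise ValueError("codon alignment length must be a multiple of 3")
            if any(len(r) != n for r in self.rows):
                raise ValueError("all alignment rows must have the same length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, rec_id: str) -> str:
        return self.rows[self.ids.index(rec_id)].replace("-", "")


def back_align(
    nuc_records: list[TaxonRecord],
    prot_msa: ProteinAlignment,
    frame: int | dict[str, int] | None = None,
    code: str = DEFAULT_CODE,
) -> CodonAlignment:
    """Thread nucleotide codons through a protein alignment.

    Each protein residue column expands to its source codon; each protein gap
    expands to ``---``.  For every id the ungapped protein row length times
    three must equal the in-frame nucleotide length (trailing partial codon
    dropped), otherwise a coordination error naming the id is raised.

    ``frame`` may be a single frame for all records, a per-id mapping, or
    ``None`` to auto-select per record via :func:`choose_frame`.
    """
    by_id = {r.id: r for r in nuc_records}
    if set(by_id) != set(prot_msa.ids):
        missing = set(prot_msa.ids) ^ set(by_id)
        raise ValueError(f"nucleotide records and protein rows do not match one-to-one: {sorted(missing)}")
    rows = []
    for rec_id in prot_msa.ids:
        rec = by_id[rec_id]
        if isinstance(frame, dict):
            f = frame.get(rec_id, 0)
        elif frame is None:
            f = choose_frame(rec.seq, code=code)
        else:
            f = frame
        inframe = rec.seq[f:]
        inframe = inframe[: len(inframe) - len(inframe) % 3]
        prot_row = prot_msa.row(rec_id)
        n_res = sum(c != "-" for c in prot_row)
        if n_res * 3 != len(inframe):
            raise ValueError(
                f"back-alignment length mismatch for {rec_id!r}: "
                f"{n_res} aligned residues need {n_res * 3} nt, have {len(inframe)} in frame {f}"
            )
        out = []
        pos = 0
        for aa in prot_row:
            if aa == "-":
                out.append("---")
            else:
                out.append(inframe[pos : pos + 3])
                pos += 3
        rows.append("".join(out))
    return CodonAlignment(ids=tuple(prot_msa.ids), rows=tuple(rows), source=prot_msa)
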