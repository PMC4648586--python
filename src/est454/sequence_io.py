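"""Sequence data model and FASTA/FASTQ I/O.

The pipeline's unit of data is the :class:`Read` — one EST (expressed
sequence tag), i.e. a single sequencing read derived from an mRNA, tagged
with the cDNA library it came from (one library per tissue x treatment
condition). Parsing and writing go through Biopython; sequences are
normalised to uppercase on ingest so that downstream identity computations
are case-insensitive.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "revcomp",
    "IUPAC_CODES",
]

# IUPAC nucleotide one-letter codes and the bases each stands for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_SET = frozenset(IUPAC_CODES)


class FastaParseError(ValueError):
    """Raised for a structurally invalid FASTA/FASTQ record."""


@dataclass(frozen=True)
class Read:
    """A single sequencing read belonging to a named library.

    Parameters
    ----------
    id : str
        Record identifier, unique within a dataset.
    library : str
        Library label, e.g. ``"root_treated"``.
    seq : str
        Uppercase IUPAC DNA string, length >= 1.
    qual : tuple of int, optional
        Per-base Phred scores, same length as ``seq``; absent for FASTA.
    """

    id: str
    library: str
    seq: str
    qual: tuple[int, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FastaParseError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _check_record(rec: SeqRecord, path: str | os.PathLike, fmt: str) -> None:
    if len(rec.seq) == 0:
        # Locate the offending header for the error message.
        lineno = None
        marker = (">" if fmt == "fasta" else "@") + rec.id
        try:
            with open(path) as fh:
                for i, line in enumerate(fh, start=1):
                    if line.rstrip("\n").split()[:1] == [marker]:
                        lineno = i
                        break
        except OSError:
            pass
        where = f" (line {lineno})" if lineno else ""
        raise FastaParseError(
            f"{path}: record {rec.id!r}{where} has a header but no sequence"
        )


def read_fasta(path: str | os.PathLike, library: str) -> list[Read]:
    """Parse a (possibly multi-line) FASTA file into Reads, order preserved."""
    reads: list[Read] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        _check_record(rec, path, "fasta")
        reads.append(Read(id=rec.id, library=library, seq=str(rec.seq).upper()))
    return reads


def write_fasta(reads: Iterable[Read], path: str | os.PathLike, width: int = 80) -> None:
    """Write Reads as FASTA wrapped at `width` columns.

    Qualities, if present, are dropped silently (documented contract).
    """
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike, library: str) -> list[Read]:
    """Parse Sanger-offset (Phred+33) FASTQ into Reads with qualities."""
    reads: list[Read] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        _check_record(rec, path, "fastq")
        reads.append(
            Read(
                id=rec.id,
                library=library,
                seq=str(rec.seq).upper(),
                qual=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string.

    Ambiguity codes map to their complements (V<->B, R<->Y, ...); N stays N.
    An involution: ``revcomp(revcomp(s)) == s``.
    """
    s = seq.upper()
    bad = set(s) - _IUPAC_SET
    if bad:
        raise ValueError(f"non-IUPAC character(s) in sequence: {sorted(bad)!r}")
    return str(Seq(s).reverse_complement())
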