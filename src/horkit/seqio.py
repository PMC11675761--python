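"""Sequence I/O and coordinate primitives.

All coordinates in this package are 0-based, half-open internally.  BED
output keeps that convention; the human-readable HOR scheme prints 1-based
start positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC one-letter ambiguity codes other than N collapse to N on load.
_AMBIGUITY = set("RYSWKMBDHV")


class FastaFormatError(ValueError):
    """Raised when a FASTA file is empty or structurally malformed."""


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval with strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Number of overlapping bases with *other* (strand-blind)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeSequence:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    residues: str
    ambiguous_replaced: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - NUCLEOTIDES
        if bad:
            raise ValueError(f"non-nucleotide residues in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> tuple[str, int]:
    """Uppercase, map U->T and non-N IUPAC ambiguity codes to N.

    Returns the normalized string and the number of ambiguity replacements.
    """
    s = raw.upper().replace("U", "T")
    n_replaced = 0
    if set(s) - NUCLEOTIDES:
        out = []
        for c in s:
            if c in NUCLEOTIDES:
                out.append(c)
            elif c in _AMBIGUITY:
                out.append("N")
                n_replaced += 1
            else:
                raise ValueError(f"invalid residue {c!r}")
        s = "".join(out)
    return s, n_replaced


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (plain or line-wrapped) FASTA file into GenomeSequence records.

    Residues are uppercased, U mapped to T, and IUPAC ambiguity codes other
    than N replaced by N (counted per record and logged as a warning).
    """
    path = Path(path)
    records: list[GenomeSequence] = []
    header: str | None = None
    chunks: list[str] = []
    saw_any = False

    def flush() -> None:
        if header is None:
            return
        residues, n_replaced = normalize_residues("".join(chunks))
        if n_replaced:
            logger.warning(
                "%s: replaced %d ambiguous residue(s) with N in record %s",
                path, n_replaced, header,
            )
        records.append(GenomeSequence(header, residues, ambiguous_replaced=n_replaced))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            saw_any = True
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
    if not saw_any:
        raise FastaFormatError(f"{path}: empty FASTA file")
    flush()
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def reverse_complement(s: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    bad = set(s) - NUCLEOTIDES
    if bad:
        raise ValueError(f"non-nucleotide residues: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def write_bed6(hits, path: str | Path) -> None:
    """Write monomer hits as BED6.

    Columns: chrom, start, end, name (type label), score (divergence x 10,
    rounded), strand.  Coordinates stay 0-based half-open.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.interval.start}\t{h.interval.end}\t{h.label}\t"
                f"{round(h.divergence * 10)}\t{h.interval.strand}\n"
            )
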