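"""Monomer detection by consensus scanning (the MonFinder stage).

Each ~1.6 kb consensus monomer is aligned semi-globally (query fully
aligned, free subject ends) against the subject sequence on both strands
with unit edit costs.  Candidate occurrences up to a divergence cap are
enumerated exhaustively by iterating best-alignment-then-mask, then pooled
across consensi and strands and reduced to a non-overlapping hit set.

Divergence of a hit is defined query-relative:

    divergence = edit_distance / len(consensus) * 100

which keeps thresholds comparable across hits regardless of indel-induced
changes in hit interval length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib

from .seqio import GenomeSequence, Interval, read_fasta, reverse_complement

DEFAULT_MAX_DIVERGENCE = 5.0
# A kept hit may share at most this fraction of its own length with
# previously kept hits: adjacent monomers abut, so boundary jitter must not
# suppress true neighbours.
DEFAULT_OVERLAP_FRACTION = 0.10
# Reject alignments whose subject interval is more than this far from the
# consensus length (pathological gap-heavy alignments at high thresholds).
DEFAULT_LENGTH_BAND = 0.20


@dataclass(frozen=True)
class ConsensusMonomer:
    """A labelled consensus query (m1/m2/m3, aka HLS1/HLS2/HLS3)."""

    label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.label or not self.sequence:
            raise ValueError("consensus label and sequence must be non-empty")


@dataclass(frozen=True)
class MonomerHit:
    """One detected monomer occurrence, in forward-strand coordinates."""

    seq_id: str
    interval: Interval
    label: str
    divergence: float
    matched_sequence: str = ""

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


def read_consensus_fasta(path: str | Path) -> list[ConsensusMonomer]:
    """Load consensus monomers from FASTA; headers are the type labels."""
    return [ConsensusMonomer(r.id, r.residues) for r in read_fasta(path)]


def _iter_candidates(
    query: str, target: str, max_edits: int, length_band: float
) -> list[tuple[int, int, int]]:
    """All (start, end, edit_distance) infix occurrences of query in target.

    Enumerated by repeatedly taking every best-scoring location, masking it
    with N (which matches nothing in an ACGT query) and re-aligning until
    the best score exceeds max_edits.  Exhaustive without windowing
    artifacts; deterministic.
    """
    qlen = len(query)
    lo = round(qlen * (1 - length_band))
    hi = round(qlen * (1 + length_band))
    buf = bytearray(target.encode())
    out: list[tuple[int, int, int]] = []
    # each round masks a constant fraction of qlen in new bases; bound generously
    for _ in range(len(target) // max(qlen // 4, 1) + 256):
        res = edlib.align(query, bytes(buf), mode="HW", task="locations", k=max_edits)
        dist = res["editDistance"]
        if dist < 0:
            break
        taken_end = -1
        for s, e in sorted(res["locations"]):
            e += 1  # edlib locations are end-inclusive
            if s < 0:
                s = 0
            if s < taken_end:  # keep leftmost of same-score overlapping variants
                continue
            taken_end = e
            buf[s:e] = b"N" * (e - s)
            if lo <= e - s <= hi:
                out.append((s, e, dist))
    else:
        raise RuntimeError("candidate enumeration failed to terminate")
    return out


def scan_monomers(
    seq: GenomeSequence,
    consensi: list[ConsensusMonomer],
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    length_band: float = DEFAULT_LENGTH_BAND,
) -> list[MonomerHit]:
    """Detect all monomer occurrences on both strands of *seq*.

    Returns non-overlapping hits (after :func:`resolve_overlaps`) sorted by
    forward-strand start.  Reverse-strand hits are reported in forward
    coordinates with strand '-' and a reverse-complemented
    ``matched_sequence`` (i.e. in reading orientation).
    """
    if not consensi:
        raise ValueError("consensus set must be non-empty")
    if not 0 < max_divergence <= 50:
        raise ValueError("max_divergence must be in (0, 50]")
    n = len(seq.residues)
    candidates: list[MonomerHit] = []
    for cons in consensi:
        if len(cons.sequence) > n:
            raise ValueError(
                f"consensus {cons.label} ({len(cons.sequence)} bp) longer than "
                f"subject {seq.id} ({n} bp)"
            )
        max_edits = int(max_divergence / 100.0 * len(cons.sequence))
        for strand in "+-":
            target = seq.residues if strand == "+" else reverse_complement(seq.residues)
            for s, e, dist in _iter_candidates(
                cons.sequence, target, max_edits, length_band
            ):
                if strand == "-":
                    s, e = n - e, n - s
                matched = seq.residues[s:e]
                if strand == "-":
                    matched = reverse_complement(matched)
                candidates.append(
                    MonomerHit(
                        seq_id=seq.id,
                        interval=Interval(s, e, strand),
                        label=cons.label,
                        divergence=dist / len(cons.sequence) * 100.0,
                        matched_sequence=matched,
                    )
                )
    return resolve_overlaps(candidates, overlap_fraction)


def resolve_overlaps(
    candidates: list[MonomerHit],
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> list[MonomerHit]:
    """Greedy non-overlapping selection by ascending divergence.

    Ties break by ascending start, then label order, then '+' before '-'.
    A candidate is kept iff it overlaps every kept hit by at most
    ``overlap_fraction`` of its own length.  Output sorted by start.
    """
    ranked = sorted(
        candidates,
        key=lambda h: (h.divergence, h.interval.start, h.label, h.interval.strand == "-"),
    )
    kept: list[MonomerHit] = []
    for cand in ranked:
        limit = overlap_fraction * len(cand.interval)
        if all(cand.interval.overlap(k.interval) <= limit for k in kept):
            kept.append(cand)
    kept.sort(key=lambda h: (h.interval.start, h.interval.end))
    return kept


def write_hits_tsv(hits: list[MonomerHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tstrand\tlabel\tdivergence\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.label}\t"
                f"{h.divergence:.3f}\n"
            )


def read_hits_tsv(path: str | Path) -> list[MonomerHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(
                MonomerHit(
                    seq_id=f[idx["seq_id"]],
                    interval=Interval(
                        int(f[idx["start"]]), int(f[idx["end"]]), f[idx["strand"]]
                    ),
                    label=f[idx["label"]],
                    divergence=float(f[idx["divergence"]]),
                )
            )
    return hits
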