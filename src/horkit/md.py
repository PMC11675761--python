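"""Monomer-distance (MD) diagrams.

For each monomer inside a tandem array, the MD diagram plots the number of
monomer positions (the *period*) to the next monomer of the same type
against the monomer's enumeration index.  A pure n-mer HOR appears as a
horizontal segment at height n: canonical NBPF triplets sit at period 3,
runs of 2mer variants at period 2.  Successor search never crosses an
array boundary, so variant insertions and inter-array gaps leave blank
spaces in the diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .hor import TandemArray
from .monfinder import MonomerHit

DEFAULT_MAX_PERIOD = 10


@dataclass(frozen=True)
class MDPoint:
    enumeration: int  # 1-based index among tandemly organized monomers
    period: int       # monomer positions to the next same-type monomer
    bp_distance: int  # start-to-start distance in bp
    array_id: str
    label: str


def compute_md(
    hits_in_arrays: list[tuple[str, list[MonomerHit]]],
    max_period: int = DEFAULT_MAX_PERIOD,
) -> list[MDPoint]:
    """MD points for monomers grouped per tandem array, in reading order.

    ``hits_in_arrays`` holds (array_id, hits) pairs; hits within an array
    must be in reading order (minus-strand arrays right-to-left).
    Enumeration is global and 1-based across arrays in the given order.
    A hit yields a point only if a later hit of the same type exists in the
    same array within ``max_period`` positions.
    """
    if max_period < 1:
        raise ValueError("max_period must be >= 1")
    points: list[MDPoint] = []
    enum_base = 0
    for array_id, hits in hits_in_arrays:
        starts = [h.start for h in hits]
        if hits and hits[0].strand == "-":
            if starts != sorted(starts, reverse=True):
                raise ValueError(f"{array_id}: minus-strand hits not in reading order")
        elif starts != sorted(starts):
            raise ValueError(f"{array_id}: hits not sorted by start")
        for i, h in enumerate(hits):
            for j in range(i + 1, min(i + max_period, len(hits) - 1) + 1):
                if hits[j].label == h.label:
                    points.append(
                        MDPoint(
                            enumeration=enum_base + i + 1,
                            period=j - i,
                            bp_distance=abs(hits[j].start - h.start),
                            array_id=array_id,
                            label=h.label,
                        )
                    )
                    break
        enum_base += len(hits)
    return points


def arrays_to_md_input(
    arrays: list[TandemArray],
) -> list[tuple[str, list[MonomerHit]]]:
    """Flatten tandem arrays into per-array reading-order hit lists."""
    out = []
    for a in arrays:
        hits: list[MonomerHit] = []
        for c in a.copies:
            hits.extend(c.hits)
        if hits and hits[0].strand == "-":
            hits.sort(key=lambda h: -h.start)
        else:
            hits.sort(key=lambda h: h.start)
        out.append((a.array_id, hits))
    return out


def period_segments(points: list[MDPoint], period: int, min_points: int = 2) -> int:
    """Number of horizontal segments at a given period.

    A segment is a maximal run of points at that period with consecutive
    enumeration indices, at least ``min_points`` long.
    """
    enums = sorted(p.enumeration for p in points if p.period == period)
    if not enums:
        return 0
    segments = 0
    run = 1
    for a, b in zip(enums, enums[1:]):
        if b == a + 1:
            run += 1
        else:
            segments += run >= min_points
            run = 1
    segments += run >= min_points
    return segments


def write_md_tsv(points: list[MDPoint], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("enumeration\tperiod\tbp_distance\tarray_id\tlabel\n")
        for p in points:
            fh.write(
                f"{p.enumeration}\t{p.period}\t{p.bp_distance}\t{p.array_id}\t"
                f"{p.label}\n"
            )
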