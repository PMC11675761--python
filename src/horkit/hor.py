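"""HOR parsing: canonical/variant copies, tandem arrays, aligned schemes.

An ordered monomer-hit array is parsed into higher-order-repeat (HOR)
copies: a canonical 3mer copy is exactly (m1, m2, m3); anything shorter or
out of order is a variant (e.g. the 2mer m1,m2 or a lone m1).  Adjacent
copies group into tandem arrays (labelled A1, A2, ... in positional order),
which carry the headline statistic: the number of canonical copies in
tandem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .monfinder import MonomerHit
from .seqio import Interval

# Monomers within a copy and copies within an array may be separated by at
# most this many bases; NBPF monomers abut, so the default is tight.
DEFAULT_GAP_MAX = 500
DEFAULT_MIN_COPIES = 2
DEFAULT_HOR_ORDER = 3


@dataclass
class HORCopy:
    labels: list[str]
    interval: Interval
    strand: str
    canonical: bool
    hits: list[MonomerHit] = field(default_factory=list, repr=False)

    @property
    def start(self) -> int:
        return self.interval.start


@dataclass
class TandemArray:
    array_id: str
    copies: list[HORCopy]

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    @property
    def n_canonical(self) -> int:
        return sum(c.canonical for c in self.copies)

    @property
    def n_variant(self) -> int:
        return self.n_copies - self.n_canonical

    @property
    def canonical_runs(self) -> list[int]:
        runs, run = [], 0
        for c in self.copies:
            if c.canonical:
                run += 1
            elif run:
                runs.append(run)
                run = 0
        if run:
            runs.append(run)
        return runs

    @property
    def interval(self) -> Interval:
        return Interval(self.copies[0].interval.start, self.copies[-1].interval.end)


def _order_labels(hor_order: int) -> list[str]:
    return [f"m{i}" for i in range(1, hor_order + 1)]


def parse_hor_copies(
    hits: list[MonomerHit],
    hor_order: int = DEFAULT_HOR_ORDER,
    gap_max: int = DEFAULT_GAP_MAX,
) -> list[HORCopy]:
    """Greedy left-to-right parse of monomer hits into HOR copies.

    Hits are first chained: consecutive same-strand hits with gap
    (next.start - prev.end) <= gap_max belong to one chain.  Minus-strand
    chains are read right-to-left (their reading orientation).  Within a
    chain, a copy starts at each m1 and extends through the longest prefix
    of (m1, m2, ..., m<order>); a monomer that is not m1 opens a variant
    copy which may still extend along the ascending canonical order (m2,
    m3).  Exactly (m1, ..., m<order>) is canonical, all else variant.
    """
    starts = [h.start for h in hits]
    if starts != sorted(starts):
        raise ValueError("hits must be sorted by start position")
    order = _order_labels(hor_order)
    rank = {lab: i for i, lab in enumerate(order)}

    chains: list[list[MonomerHit]] = []
    for h in hits:
        prev = chains[-1][-1] if chains and chains[-1] else None
        if (
            prev is not None
            and prev.strand == h.strand
            and h.start - prev.end <= gap_max
        ):
            chains[-1].append(h)
        else:
            chains.append([h])

    copies: list[HORCopy] = []
    for chain in chains:
        strand = chain[0].strand
        reading = chain if strand == "+" else chain[::-1]
        i = 0
        while i < len(reading):
            j = i + 1
            while (
                j < len(reading)
                and reading[j].label in rank
                and reading[j - 1].label in rank
                and rank[reading[j].label] == rank[reading[j - 1].label] + 1
            ):
                j += 1
            group = reading[i:j]
            labels = [h.label for h in group]
            lo = min(h.start for h in group)
            hi = max(h.end for h in group)
            copies.append(
                HORCopy(
                    labels=labels,
                    interval=Interval(lo, hi, strand),
                    strand=strand,
                    canonical=labels == order,
                    hits=group,
                )
            )
            i = j
    copies.sort(key=lambda c: c.interval.start)
    return copies


def group_tandem_arrays(
    copies: list[HORCopy],
    gap_max: int = DEFAULT_GAP_MAX,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> tuple[list[TandemArray], list[HORCopy]]:
    """Group adjacent HOR copies into tandem arrays.

    Maximal chains with inter-copy gap <= gap_max and at least
    ``min_copies`` copies become arrays labelled A1, A2, ... in positional
    order; shorter chains are returned separately as individual copies.
    """
    starts = [c.interval.start for c in copies]
    if starts != sorted(starts):
        raise ValueError("copies must be sorted by start position")
    chains: list[list[HORCopy]] = []
    for c in copies:
        if chains and c.interval.start - chains[-1][-1].interval.end <= gap_max:
            chains[-1].append(c)
        else:
            chains.append([c])
    arrays: list[TandemArray] = []
    individuals: list[HORCopy] = []
    for chain in chains:
        if len(chain) >= min_copies:
            arrays.append(TandemArray(array_id=f"A{len(arrays) + 1}", copies=chain))
        else:
            individuals.extend(chain)
    return arrays, individuals


def count_canonical_tandem(arrays: list[TandemArray], min_run: int = 0) -> int:
    """Canonical copies inside tandem arrays.

    With ``min_run`` == 0 this is the total number of canonical copies over
    all arrays; with ``min_run`` == r > 0 only maximal canonical runs longer
    than r are counted (r = 3 gives the 'more than three copies' figure).
    """
    if min_run < 0:
        raise ValueError("min_run must be >= 0")
    if min_run == 0:
        return sum(a.n_canonical for a in arrays)
    return sum(
        run for a in arrays for run in a.canonical_runs if run > min_run
    )


def count_canonical_in_arrays_over(arrays: list[TandemArray], min_copies: int = 3) -> int:
    """Alternative 'more than N copies' reading: whole arrays with > min_copies copies."""
    return sum(a.n_canonical for a in arrays if a.n_copies > min_copies)


def render_scheme(
    arrays: list[TandemArray],
    individuals: list[HORCopy] | None = None,
    hor_order: int = DEFAULT_HOR_ORDER,
) -> str:
    """Aligned monomeric scheme, one row per HOR copy.

    Each row prints the 1-based start of the copy (suffixed ``(-)`` for
    reverse-complement copies) followed by the type labels in aligned
    columns, blank where a type is absent.  Arrays are separated by blank
    lines; individual copies follow under their own heading.
    """
    order = _order_labels(hor_order)
    col = {lab: i for i, lab in enumerate(order)}
    width = max(len(lab) for lab in order)

    def row(c: HORCopy) -> str:
        cells = [" " * width] * hor_order
        for lab in c.labels:
            if lab in col:
                cells[col[lab]] = lab.ljust(width)
        pos = f"{c.interval.start + 1}"
        if c.strand == "-":
            pos += "(-)"
        return f"{pos:>12}  " + " ".join(cells).rstrip()

    blocks = []
    for a in arrays:
        lines = [f"# {a.array_id}  copies={a.n_copies} canonical={a.n_canonical} "
                 f"variant={a.n_variant}"]
        lines += [row(c) for c in a.copies]
        blocks.append("\n".join(lines))
    if individuals:
        lines = ["# individual copies"]
        lines += [row(c) for c in individuals]
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def scheme_tsv(
    arrays: list[TandemArray], individuals: list[HORCopy] | None = None
) -> str:
    lines = ["array_id\tcopy_index\tstart\tend\tstrand\tlabels\tcanonical"]
    for a in arrays:
        for i, c in enumerate(a.copies, start=1):
            lines.append(
                f"{a.array_id}\t{i}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.strand}\t{','.join(c.labels)}\t{int(c.canonical)}"
            )
    for c in individuals or []:
        lines.append(
            f"individual\t0\t{c.interval.start}\t{c.interval.end}\t{c.strand}\t"
            f"{','.join(c.labels)}\t{int(c.canonical)}"
        )
    return "\n".join(lines) + "\n"


def summary_dict(
    arrays: list[TandemArray],
    individuals: list[HORCopy],
    n_hits: int,
    min_run: int = 3,
) -> dict:
    return {
        "monomer_hits": n_hits,
        "n_arrays": len(arrays),
        "n_individual_copies": len(individuals),
        "canonical_in_tandem": count_canonical_tandem(arrays, 0),
        f"canonical_in_tandem_run_gt{min_run}": count_canonical_tandem(arrays, min_run),
        f"canonical_in_arrays_gt{min_run}_copies": count_canonical_in_arrays_over(
            arrays, min_run
        ),
        "arrays": [
            {
                "array_id": a.array_id,
                "start": a.interval.start,
                "end": a.interval.end,
                "n_copies": a.n_copies,
                "n_canonical": a.n_canonical,
                "n_variant": a.n_variant,
                "canonical_runs": a.canonical_runs,
            }
            for a in arrays
        ],
    }


def write_summary_json(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
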