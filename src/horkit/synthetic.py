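"""Planted-truth synthetic genomes with NBPF-like HOR architecture.

The generator lays out tandem arrays of ~1.6 kb monomers organized as 3mer
HOR copies (with optional 2mer/1mer variant copies, reverse-complement
arrays and single-copy "individual" insertions), separated by random
spacers, with i.i.d. per-base substitution and indel noise.  It returns
the sequence together with exact truth records (hit intervals, copies,
arrays), so recovery by the detection pipeline can be asserted bit-exactly.

Ancestral monomer types are independent random sequences kept at >= 10%
mutual divergence by rejection sampling, so classification at the 5%
working threshold has a unique correct answer.  The generator targets
testability, not evolutionary realism: no duplication/conversion process,
no phylogeny, uniform base composition.

Species presets mirror the canonical/variant inventories observed on
chromosome 1 of the four great-ape assemblies the toolkit is aimed at
(six human arrays of which one is split by a variant block, four short
gorilla tandems, chimpanzee 2mer variants only, a single orangutan
monomer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classify import pairwise_divergence
from .hor import HORCopy, TandemArray
from .monfinder import ConsensusMonomer, MonomerHit
from .seqio import GenomeSequence, Interval, reverse_complement

DEFAULT_MONOMER_LENGTH = 1600
DEFAULT_HOR_ORDER = 3
DEFAULT_SPACER_LENGTH = 2000
MIN_ANCESTOR_DIVERGENCE = 10.0
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ArrayPlan:
    """One tandem array: either ``copies`` canonical copies or an explicit
    per-copy ``variant_pattern`` (list of label lists, e.g. [["m1","m2"]])."""

    copies: int = 0
    variant_pattern: list[list[str]] | None = None
    strand: str = "+"

    def templates(self, order_labels: list[str]) -> list[list[str]]:
        if self.variant_pattern is not None:
            return [list(t) for t in self.variant_pattern]
        return [list(order_labels) for _ in range(self.copies)]


@dataclass
class PlantSpec:
    arrays: list[ArrayPlan]
    monomer_length: int = DEFAULT_MONOMER_LENGTH
    hor_order: int = DEFAULT_HOR_ORDER
    spacer_length: int = DEFAULT_SPACER_LENGTH
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate <= 0.2:
            raise ValueError("substitution_rate must be in [0, 0.2]")
        if not 0 <= self.indel_rate <= 0.2:
            raise ValueError("indel_rate must be in [0, 0.2]")
        if self.monomer_length < 50:
            raise ValueError("monomer_length must be >= 50")
        for a in self.arrays:
            if a.variant_pattern is None and a.copies < 1:
                raise ValueError("array copies must be >= 1")

    @property
    def order_labels(self) -> list[str]:
        return [f"m{i}" for i in range(1, self.hor_order + 1)]


@dataclass
class PlantTruth:
    ancestral_monomers: dict[str, str]
    planted_hits: list[MonomerHit]
    planted_copies: list[HORCopy]
    planted_arrays: list[TandemArray]

    def consensus_set(self) -> list[ConsensusMonomer]:
        return [ConsensusMonomer(lab, s) for lab, s in self.ancestral_monomers.items()]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def draw_ancestors(
    rng: np.random.Generator,
    hor_order: int = DEFAULT_HOR_ORDER,
    monomer_length: int = DEFAULT_MONOMER_LENGTH,
    max_attempts: int = 50,
) -> dict[str, str]:
    """Random ancestral monomer types at >= 10% mutual divergence."""
    labels = [f"m{i}" for i in range(1, hor_order + 1)]
    for _ in range(max_attempts):
        seqs = [_random_seq(rng, monomer_length) for _ in labels]
        ok = all(
            pairwise_divergence(seqs[i], seqs[j]) >= MIN_ANCESTOR_DIVERGENCE
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        )
        if ok:
            return dict(zip(labels, seqs))
    raise RuntimeError(
        "could not draw sufficiently divergent ancestors; "
        "increase monomer_length"
    )


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float) -> str:
    """Apply i.i.d. substitutions and indels (insert/delete equally likely)."""
    if sub_rate == 0 and indel_rate == 0:
        return seq
    out = []
    for c in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:  # insertion before the base
            out.append(str(rng.choice(_BASES), "ascii"))
        if rng.random() < sub_rate:
            alt = [b for b in "ACGT" if b != c]
            out.append(alt[rng.integers(3)])
        else:
            out.append(c)
    return "".join(out)


def generate(
    spec: PlantSpec,
    ancestors: dict[str, str] | None = None,
    seq_id: str = "synthetic",
) -> tuple[GenomeSequence, PlantTruth]:
    """Build a planted genome and its exact truth records.

    ``ancestors`` may be shared across calls (e.g. one consensus set used
    to plant several synthetic species); by default they are drawn from the
    spec's seed.  Bit-reproducible for identical inputs.
    """
    rng = np.random.default_rng(spec.seed)
    if ancestors is None:
        ancestors = draw_ancestors(rng, spec.hor_order, spec.monomer_length)
    order = spec.order_labels

    parts: list[str] = []
    pos = 0
    hits: list[MonomerHit] = []
    copies: list[HORCopy] = []
    arrays: list[TandemArray] = []

    def emit_spacer() -> None:
        nonlocal pos
        s = _random_seq(rng, spec.spacer_length)
        parts.append(s)
        pos += len(s)

    emit_spacer()
    for plan in spec.arrays:
        templates = plan.templates(order)
        # build in reading orientation, then flip whole array if '-'
        arr_parts: list[str] = []
        arr_pos = 0
        arr_hits: list[tuple[int, int, str, str]] = []  # start, end, label, seq
        arr_copies: list[list[int]] = []  # hit indices per copy
        for template in templates:
            copy_hits = []
            for lab in template:
                inst = _mutate(
                    rng, ancestors[lab], spec.substitution_rate, spec.indel_rate
                )
                copy_hits.append(len(arr_hits))
                arr_hits.append((arr_pos, arr_pos + len(inst), lab, inst))
                arr_parts.append(inst)
                arr_pos += len(inst)
            arr_copies.append(copy_hits)
        arr_seq = "".join(arr_parts)
        if plan.strand == "-":
            arr_seq = reverse_complement(arr_seq)
            alen = len(arr_seq)
            arr_hits = [(alen - e, alen - s, lab, inst) for s, e, lab, inst in arr_hits]

        this_hits: list[MonomerHit] = []
        for s, e, lab, inst in arr_hits:
            this_hits.append(
                MonomerHit(
                    seq_id=seq_id,
                    interval=Interval(pos + s, pos + e, plan.strand),
                    label=lab,
                    divergence=0.0,
                    matched_sequence=inst,
                )
            )
        this_copies: list[HORCopy] = []
        for idxs in arr_copies:
            chits = [this_hits[i] for i in idxs]
            lo = min(h.start for h in chits)
            hi = max(h.end for h in chits)
            labels = [this_hits[i].label for i in idxs]
            this_copies.append(
                HORCopy(
                    labels=labels,
                    interval=Interval(lo, hi, plan.strand),
                    strand=plan.strand,
                    canonical=labels == order,
                    hits=chits,
                )
            )
        this_copies.sort(key=lambda c: c.interval.start)
        arrays.append(TandemArray(array_id=f"A{len(arrays) + 1}", copies=this_copies))
        hits.extend(sorted(this_hits, key=lambda h: h.start))
        copies.extend(this_copies)
        parts.append(arr_seq)
        pos += len(arr_seq)
        emit_spacer()

    seq = GenomeSequence(seq_id, "".join(parts))
    truth = PlantTruth(
        ancestral_monomers=dict(ancestors),
        planted_hits=hits,
        planted_copies=copies,
        planted_arrays=arrays,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# Species presets: canonical/variant inventories of the four chromosome-1
# assemblies the toolkit targets, at copy-level resolution.

def _plans_human() -> list[ArrayPlan]:
    v12 = ["m1", "m2"]
    can = ["m1", "m2", "m3"]
    return [
        ArrayPlan(copies=5),                                   # A1
        ArrayPlan(variant_pattern=[can] * 6 + [v12] * 3),      # A2
        ArrayPlan(variant_pattern=[can] * 4 + [v12] * 4 + [can] * 10 + [v12]),  # A3
        ArrayPlan(copies=13, strand="-"),                      # A4
        ArrayPlan(variant_pattern=[v12] * 2 + [can] * 11),     # A5
        ArrayPlan(variant_pattern=[can] * 12 + [v12]),         # A6
    ]


def _plans_gorilla() -> list[ArrayPlan]:
    v12 = ["m1", "m2"]
    can = ["m1", "m2", "m3"]
    plans = [
        ArrayPlan(variant_pattern=[can] * 3 + [v12]),
        ArrayPlan(variant_pattern=[can] * 2 + [v12]),
        ArrayPlan(variant_pattern=[can] * 2 + [v12]),
        ArrayPlan(variant_pattern=[can] * 2 + [v12], strand="-"),
    ]
    plans += [ArrayPlan(variant_pattern=[v12]) for _ in range(6)]
    plans += [ArrayPlan(variant_pattern=[["m1"]]) for _ in range(3)]
    return plans


def _plans_chimpanzee() -> list[ArrayPlan]:
    v12 = ["m1", "m2"]
    plans = [ArrayPlan(variant_pattern=[v12, v12])]
    plans += [ArrayPlan(variant_pattern=[v12]) for _ in range(10)]
    plans += [ArrayPlan(variant_pattern=[["m1"]])]
    return plans


def _plans_orangutan() -> list[ArrayPlan]:
    return [ArrayPlan(variant_pattern=[["m1"]])]


SPECIES_PLANS = {
    "human": _plans_human,
    "gorilla": _plans_gorilla,
    "chimpanzee": _plans_chimpanzee,
    "orangutan": _plans_orangutan,
}

# Within-array monomer copies of a type differ by a few percent in real
# NBPF arrays; 2% substitutions + 0.2% indels keeps planted divergence
# well under the 5% working threshold.
DEFAULT_SUBSTITUTION_RATE = 0.02
DEFAULT_INDEL_RATE = 0.002


def species_spec(
    species: str,
    seed: int = 0,
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE,
    indel_rate: float = DEFAULT_INDEL_RATE,
    monomer_length: int = DEFAULT_MONOMER_LENGTH,
) -> PlantSpec:
    try:
        plans = SPECIES_PLANS[species]()
    except KeyError:
        raise ValueError(f"unknown species preset {species!r}") from None
    return PlantSpec(
        arrays=plans,
        monomer_length=monomer_length,
        substitution_rate=substitution_rate,
        indel_rate=indel_rate,
        seed=seed,
    )


def truth_to_json(truth: PlantTruth, path: str | Path) -> None:
    doc = {
        "ancestral_monomers": truth.ancestral_monomers,
        "hits": [
            {
                "start": h.start, "end": h.end, "strand": h.strand, "label": h.label,
            }
            for h in truth.planted_hits
        ],
        "arrays": [
            {
                "array_id": a.array_id,
                "n_copies": a.n_copies,
                "n_canonical": a.n_canonical,
                "canonical_runs": a.canonical_runs,
                "copies": [
                    {"start": c.interval.start, "end": c.interval.end,
                     "strand": c.strand, "labels": c.labels,
                     "canonical": c.canonical}
                    for c in a.copies
                ],
            }
            for a in truth.planted_arrays
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
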