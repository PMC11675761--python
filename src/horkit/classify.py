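"""Monomer classification, consensus building and divergence tables.

Monomers extracted from tandem arrays are grouped into types by
single-linkage clustering under a pairwise-divergence cutoff (5% for
NBPF/Olduvai work, after Willard's alpha-satellite convention), a majority
consensus is built per group, and consensus-vs-consensus divergences are
tabulated within and between species.

Two divergence definitions coexist in this package and are deliberately
distinct:

* hit divergence (monfinder): edit distance / consensus length -- query
  relative, not symmetric in principle;
* :func:`pairwise_divergence` here: edit distance / max(len a, len b) --
  symmetric, zero iff identical, used for clustering and tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import edlib
import numpy as np

from .seqio import GenomeSequence, write_fasta
from .monfinder import ConsensusMonomer

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 5.0
CANONICAL_LABELS = ("m1", "m2", "m3")


@dataclass
class MonomerClass:
    label: str
    members: list[str]
    member_indices: list[int]
    consensus: str = ""


@dataclass(frozen=True)
class DivergenceRecord:
    label_a: str
    label_b: str
    divergence: float


def pairwise_divergence(a: str, b: str) -> float:
    """Global-alignment edit distance as a percentage of the longer sequence."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return dist / max(len(a), len(b)) * 100.0


def divergence_matrix(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        mat[i, j] = mat[j, i] = pairwise_divergence(seqs[i], seqs[j])
    return mat


def cluster_monomers(
    monomer_seqs: list[str],
    threshold: float = DEFAULT_THRESHOLD,
    build_consensi: bool = True,
) -> list[MonomerClass]:
    """Single-linkage clustering of monomer sequences at a divergence cutoff.

    Classes are ordered by their first member's input position and labelled
    m1, m2, m3, ... in that order; deterministic.
    """
    if not monomer_seqs:
        raise ValueError("no monomer sequences to cluster")
    if not 0 < threshold <= 50:
        raise ValueError("threshold must be in (0, 50]")
    n = len(monomer_seqs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mat = divergence_matrix(monomer_seqs)
    for i, j in combinations(range(n), 2):
        if mat[i, j] <= threshold:
            parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: g[0])
    classes = []
    for k, idxs in enumerate(ordered, start=1):
        members = [monomer_seqs[i] for i in idxs]
        cls = MonomerClass(label=f"m{k}", members=members, member_indices=idxs)
        if build_consensi:
            cls.consensus = build_consensus(members)
        classes.append(cls)
    return classes


def _medoid_index(members: list[str]) -> int:
    if len(members) == 1:
        return 0
    mat = divergence_matrix(members)
    sums = mat.sum(axis=1)
    return int(np.argmin(sums))  # ties -> first by input order


def build_consensus(members: list[str]) -> str:
    """Majority-vote consensus of monomer sequences.

    Members are aligned semi-globally to the medoid (the member minimizing
    summed divergence to all others); per medoid column the majority symbol
    over {A, C, G, T, gap} wins, majority-gap columns are dropped, and base
    ties break in the fixed order A < C < G < T.  Insertions relative to
    the medoid are not voted (they are gaps in most members by
    construction).  Deterministic.
    """
    if not members:
        raise ValueError("need at least one member")
    medoid = members[_medoid_index(members)]
    m = len(medoid)
    counts = np.zeros((m, 5), dtype=np.int64)  # A C G T gap
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for member in members:
        res = edlib.align(member, medoid, mode="HW", task="path")
        (t0, t1) = res["locations"][0]
        counts[:t0, 4] += 1
        counts[t1 + 1 :, 4] += 1
        qpos, tpos = 0, t0
        for length, op in _cigar_ops(res["cigar"]):
            if op in "=XM":
                for _ in range(length):
                    counts[tpos, base_idx.get(member[qpos], 4)] += 1
                    qpos += 1
                    tpos += 1
            elif op == "I":  # insertion in member relative to medoid
                qpos += length
            elif op == "D":  # medoid bases unmatched in member
                counts[tpos : tpos + length, 4] += 1
                tpos += length
    out = []
    for col in counts:
        best = int(np.argmax(col[:4]))  # ties break A<C<G<T
        if col[4] > col[best]:  # gap wins only on strict majority over bases
            continue
        out.append("ACGT"[best])
    return "".join(out)


def _cigar_ops(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def divergence_table(
    consensus_sets: dict[str, list[ConsensusMonomer]],
) -> list[DivergenceRecord]:
    """Within- and cross-species consensus divergences.

    Emits (i) cross-species same-label records plus a per-species-pair mean
    (labelled ``<species>-mean``) and (ii) within-species cross-label
    records (m1/m2, m1/m3, m2/m3), symmetric-deduplicated.
    """
    records: list[DivergenceRecord] = []
    sets = {sp: {c.label: c.sequence for c in cs} for sp, cs in consensus_sets.items()}
    species = list(sets)

    for sp in species:
        labels = sorted(sets[sp])
        for la, lb in combinations(labels, 2):
            records.append(
                DivergenceRecord(
                    f"{sp}-{la}", f"{sp}-{lb}",
                    pairwise_divergence(sets[sp][la], sets[sp][lb]),
                )
            )

    if len(species) < 2:
        logger.warning("fewer than 2 consensus sets: cross-species table omitted")
        return records

    for sa, sb in combinations(species, 2):
        shared = sorted(set(sets[sa]) & set(sets[sb]))
        missing = set(sets[sa]) ^ set(sets[sb])
        if missing:
            logger.warning("labels %s missing from one of %s/%s; skipped",
                           sorted(missing), sa, sb)
        pair_vals = []
        for lab in shared:
            d = pairwise_divergence(sets[sa][lab], sets[sb][lab])
            records.append(DivergenceRecord(f"{sa}-{lab}", f"{sb}-{lab}", d))
            pair_vals.append(d)
        if pair_vals:
            records.append(
                DivergenceRecord(f"{sa}-mean", f"{sb}-mean", float(np.mean(pair_vals)))
            )
    return records


def write_divergence_tsv(records: list[DivergenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label_a\tlabel_b\tdivergence_pct\n")
        for r in records:
            fh.write(f"{r.label_a}\t{r.label_b}\t{r.divergence:.2f}\n")


def write_consensus_fasta(
    classes: list[MonomerClass], path: str | Path, species: str | None = None
) -> None:
    prefix = f"{species}." if species else ""
    write_fasta(
        [GenomeSequence(f"{prefix}{c.label}", c.consensus) for c in classes], path
    )
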