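"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (dictionaries, quadratic DP, direct
rule transcriptions) and shares no code with the package internals.
"""

from __future__ import annotations


def brute_spectrum(residues: str, k: int, lo: int, hi: int) -> dict[int, int]:
    """Dictionary-of-occurrence-lists fragment-length histogram."""
    occ: dict[str, list[int]] = {}
    for i in range(len(residues) - k + 1):
        key = residues[i : i + k]
        if "N" in key:
            continue
        occ.setdefault(key, []).append(i)
    counts: dict[int, int] = {}
    for positions in occ.values():
        for a, b in zip(positions, positions[1:]):
            d = b - a
            if lo <= d <= hi:
                counts[d] = counts.get(d, 0) + 1
    return counts


def edit_distance(a: str, b: str) -> int:
    """Quadratic dynamic-programming Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def complement_base(c: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[c]


def greedy_overlap_resolution(cands, overlap_fraction: float = 0.10):
    """Direct transcription of the greedy selection rule.

    ``cands``: (divergence, start, end, label, strand) tuples.  Returns the
    kept tuples sorted by start.
    """
    ranked = sorted(cands, key=lambda c: (c[0], c[1], c[3], c[4] == "-"))
    kept = []
    for cand in ranked:
        _, s, e, _, _ = cand
        limit = overlap_fraction * (e - s)
        ok = True
        for _, ks, ke, _, _ in kept:
            if max(0, min(e, ke) - max(s, ks)) > limit:
                ok = False
                break
        if ok:
            kept.append(cand)
    return sorted(kept, key=lambda c: c[1])


def greedy_parse(labels: list[str], order: list[str]) -> list[list[str]]:
    """Greedy left-to-right decomposition of a label sequence into copies:
    maximal runs ascending one step at a time along the canonical order."""
    rank = {lab: i for i, lab in enumerate(order)}
    copies = []
    i = 0
    while i < len(labels):
        copy = [labels[i]]
        while (
            i + 1 < len(labels)
            and rank[labels[i + 1]] == rank[labels[i]] + 1
        ):
            i += 1
            copy.append(labels[i])
        copies.append(copy)
        i += 1
    return copies
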