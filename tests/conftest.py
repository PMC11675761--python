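from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from horkit.monfinder import MonomerHit
from horkit.seqio import GenomeSequence, Interval

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def make_hits(
    labels: list[str],
    monomer_length: int = 100,
    gap: int = 0,
    start: int = 0,
    strand: str = "+",
    seq_id: str = "test",
) -> list[MonomerHit]:
    """Abutting monomer hits with the given labels, for parser/MD tests.

    ``labels`` are in reading order; minus-strand hits are laid out
    right-to-left genomically, and the returned list is sorted by start.
    """
    genomic = labels if strand == "+" else labels[::-1]
    hits = []
    pos = start
    for lab in genomic:
        hits.append(
            MonomerHit(
                seq_id=seq_id,
                interval=Interval(pos, pos + monomer_length, strand),
                label=lab,
                divergence=0.0,
            )
        )
        pos += monomer_length + gap
    return hits


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


@pytest.fixture
def small_genome(rng):
    """Noise-free planted genome: one array of 4 canonical copies."""
    from horkit.synthetic import ArrayPlan, PlantSpec, generate

    spec = PlantSpec(arrays=[ArrayPlan(copies=4)], monomer_length=400,
                     spacer_length=1000, seed=7)
    return generate(spec, seq_id="mini")


def genome_seq(rng: np.random.Generator, length: int, seq_id: str = "g") -> GenomeSequence:
    return GenomeSequence(seq_id, random_dna(rng, length))
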