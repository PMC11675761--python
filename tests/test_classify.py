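import numpy as np
import pytest

from horkit.classify import (
    build_consensus,
    cluster_monomers,
    divergence_table,
    pairwise_divergence,
)
from horkit.monfinder import ConsensusMonomer
from conftest import random_dna
from oracles import edit_distance


def _mutate_subs(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestPairwiseDivergence:
    def test_identity(self):
        assert pairwise_divergence("ACGT", "ACGT") == 0.0

    def test_single_substitution(self):
        assert pairwise_divergence("ACGT", "ACGA") == 25.0

    def test_symmetry_and_length_normalization(self):
        a, b = "ACGTACGT", "ACGT"
        assert pairwise_divergence(a, b) == pairwise_divergence(b, a)
        assert pairwise_divergence(a, b) == pytest.approx(4 / 8 * 100)

    def test_matches_dp_oracle_on_random_pair(self, rng):
        a = random_dna(rng, 500)
        b = random_dna(rng, 500)
        assert pairwise_divergence(a, b) == pytest.approx(
            edit_distance(a, b) / 500 * 100
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pairwise_divergence("", "ACGT")


class TestClusterMonomers:
    def test_identical_sequences_one_class(self, rng):
        s = random_dna(rng, 200)
        (cls,) = cluster_monomers([s] * 10, 5.0)
        assert cls.label == "m1"
        assert len(cls.members) == 10
        assert cls.consensus == s

    def test_three_planted_families(self, rng):
        ancestors = [random_dna(rng, 300) for _ in range(3)]
        seqs, family = [], []
        for _ in range(12):
            k = int(rng.integers(3))
            seqs.append(_mutate_subs(rng, ancestors[k], 0.01))
            family.append(k)
        classes = cluster_monomers(seqs, 5.0)
        assert len(classes) == 3
        # memberships match the connected components of the <=5% graph,
        # which under planted 1% intra / >=15% inter noise are the families
        for cls in classes:
            fams = {family[i] for i in cls.member_indices}
            assert len(fams) == 1
        # labels follow first-member position order
        first = [cls.member_indices[0] for cls in classes]
        assert first == sorted(first)

    def test_permutation_invariance_up_to_relabeling(self, rng):
        ancestors = [random_dna(rng, 250) for _ in range(2)]
        seqs = [_mutate_subs(rng, ancestors[i % 2], 0.01) for i in range(8)]
        base = cluster_monomers(seqs, 5.0)
        perm = list(rng.permutation(8))
        permuted = cluster_monomers([seqs[i] for i in perm], 5.0)
        base_sets = {frozenset(cls.members) for cls in base}
        perm_sets = {frozenset(cls.members) for cls in permuted}
        assert base_sets == perm_sets

    def test_rerun_is_bit_identical(self, rng):
        seqs = [random_dna(rng, 150) for _ in range(6)]
        a = cluster_monomers(seqs, 20.0)
        b = cluster_monomers(seqs, 20.0)
        assert [(c.label, c.members, c.consensus) for c in a] == [
            (c.label, c.members, c.consensus) for c in b
        ]

    def test_raising_threshold_never_splits(self, rng):
        ancestors = [random_dna(rng, 200) for _ in range(3)]
        seqs = [_mutate_subs(rng, ancestors[i % 3], 0.02) for i in range(9)]
        n_classes = [
            len(cluster_monomers(seqs, t, build_consensi=False))
            for t in (2.0, 5.0, 10.0, 30.0, 50.0)
        ]
        assert n_classes == sorted(n_classes, reverse=True)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cluster_monomers([], 5.0)


class TestBuildConsensus:
    def test_unanimity(self):
        assert build_consensus(["ACGT", "ACGT", "ACGT"]) == "ACGT"

    def test_majority_at_last_column(self):
        assert build_consensus(["ACGT", "ACGA", "ACGA"]) == "ACGA"

    def test_idempotence_single_member(self, rng):
        s = random_dna(rng, 300)
        assert build_consensus([s]) == s

    def test_adding_consensus_copies_is_stable(self, rng):
        seqs = [_mutate_subs(rng, random_dna(rng, 200), 0.02) for _ in range(5)]
        c = build_consensus(seqs)
        assert build_consensus(seqs + [c, c, c, c, c, c]) == c

    def test_recovers_ancestor_from_mutated_copies(self, rng):
        ancestor = random_dna(rng, 1600)
        members = [_mutate_subs(rng, ancestor, 0.02) for _ in range(20)]
        consensus = build_consensus(members)
        assert pairwise_divergence(consensus, ancestor) <= 0.5

    def test_handles_indel_noise(self, rng):
        ancestor = random_dna(rng, 800)
        members = []
        for _ in range(15):
            m = _mutate_subs(rng, ancestor, 0.02)
            # one random deletion and one random insertion per member
            i = int(rng.integers(len(m)))
            m = m[:i] + m[i + 1 :]
            j = int(rng.integers(len(m)))
            m = m[:j] + random_dna(rng, 1) + m[j:]
            members.append(m)
        consensus = build_consensus(members)
        assert pairwise_divergence(consensus, ancestor) <= 1.0


class TestDivergenceTable:
    def _sets(self, rng, identical=False):
        labels = ["m1", "m2", "m3"]
        base = {lab: random_dna(rng, 300) for lab in labels}
        if identical:
            other = dict(base)
        else:
            other = {lab: _mutate_subs(rng, s, 0.10) for lab, s in base.items()}
        as_cons = lambda d: [ConsensusMonomer(l, s) for l, s in d.items()]
        return {"human": as_cons(base), "chimpanzee": as_cons(other)}

    def test_identical_sets_zero_cross_species(self, rng):
        records = divergence_table(self._sets(rng, identical=True))
        cross = [r for r in records if r.label_a.split("-")[0] != r.label_b.split("-")[0]]
        assert cross and all(r.divergence == 0.0 for r in cross)

    def test_record_structure(self, rng):
        records = divergence_table(self._sets(rng))
        keys = {(r.label_a, r.label_b) for r in records}
        # 3 within-species pairs per species + 3 same-label cross + 1 mean
        assert ("human-m1", "human-m2") in keys
        assert ("human-m1", "chimpanzee-m1") in keys
        assert ("human-mean", "chimpanzee-mean") in keys
        assert len(records) == 3 + 3 + 3 + 1

    def test_mean_is_average_of_same_label_records(self, rng):
        records = divergence_table(self._sets(rng))
        same = [
            r.divergence
            for r in records
            if r.label_a.startswith("human-m") and r.label_b.startswith("chimpanzee-m")
        ]
        (mean_rec,) = [r for r in records if r.label_a == "human-mean"]
        assert mean_rec.divergence == pytest.approx(np.mean(same))

    def test_single_set_partial_output(self, rng):
        labels = ["m1", "m2"]
        sets = {"human": [ConsensusMonomer(l, random_dna(rng, 100)) for l in labels]}
        records = divergence_table(sets)
        assert len(records) == 1  # within-species pair only
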