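"""Stacked k-mer encoders against a naive window-counting oracle."""

from itertools import product

import numpy as np
import pytest

import rpifusion as rf
from rpifusion.errors import DimensionError
from rpifusion.sequence import CONJOINT_TRIAD_GROUPS

from conftest import random_protein, random_rna


def naive_kmer_freqs(symbols: str, alphabet: str, k: int) -> np.ndarray:
    """Independent oracle: enumerate every window, count, divide."""
    words = ["".join(w) for w in product(alphabet, repeat=k)]
    counts = {w: 0 for w in words}
    for i in range(len(symbols) - k + 1):
        counts[symbols[i : i + k]] += 1
    total = max(len(symbols) - k + 1, 0)
    if total == 0:
        return np.zeros(len(words))
    return np.array([counts[w] / total for w in words])


def naive_rna_ik(residues: str) -> np.ndarray:
    return np.concatenate(
        [naive_kmer_freqs(residues, "ACGU", k) for k in (1, 2, 3, 4)]
    )


def naive_protein_ict(residues: str) -> np.ndarray:
    groups = "".join(str(CONJOINT_TRIAD_GROUPS[c]) for c in residues)
    return np.concatenate(
        [naive_kmer_freqs(groups, "1234567", k) for k in (1, 2, 3)]
    )


class TestRnaIk:
    def test_dim_340(self):
        rec = rf.SequenceRecord("r", "rna", "ACGUACG")
        assert rf.encode_rna_ik(rec).dim == 340

    def test_homopolymer(self):
        rec = rf.SequenceRecord("r", "rna", "AAAA")
        v = rf.encode_rna_ik(rec).values
        # A, AA, AAA, AAAA are the first entries of their sub-blocks
        hot = [0, 4, 4 + 16, 4 + 16 + 64]
        assert np.allclose(v[hot], 1.0)
        assert np.count_nonzero(v) == 4

    def test_acgu_example(self):
        rec = rf.SequenceRecord("r", "rna", "ACGU")
        v = rf.encode_rna_ik(rec).values
        assert np.allclose(v[:4], 0.25)
        idx2 = {w: i for i, w in enumerate(
            "".join(p) for p in product("ACGU", repeat=2))}
        for w in ("AC", "CG", "GU"):
            assert v[4 + idx2[w]] == pytest.approx(1 / 3)
        assert np.allclose(v, naive_rna_ik("ACGU"))

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            rec = random_rna(rng, int(rng.integers(1, 51)))
            assert np.array_equal(
                rf.encode_rna_ik(rec).values, naive_rna_ik(rec.residues)
            )

    def test_subblock_normalization(self):
        rng = np.random.default_rng(4)
        rec = random_rna(rng, 30)
        v = rf.encode_rna_ik(rec).values
        for lo, hi in [(0, 4), (4, 20), (20, 84), (84, 340)]:
            assert v[lo:hi].sum() == pytest.approx(1.0)

    def test_short_sequence_zero_subblocks(self):
        rec = rf.SequenceRecord("r", "rna", "AC")
        v = rf.encode_rna_ik(rec).values
        assert v[:20].sum() == pytest.approx(2.0)  # 1-mer + 2-mer blocks
        assert np.all(v[20:] == 0.0)  # 3-mer and 4-mer blocks empty

    def test_permutation_sensitivity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            rec = random_rna(rng, 25)
            rev = rf.SequenceRecord("x", "rna", rec.residues[::-1])
            a, b = rf.encode_rna_ik(rec).values, rf.encode_rna_ik(rev).values
            assert np.allclose(a[:4], b[:4])  # 1-mer invariant
            if rec.residues != rec.residues[::-1]:
                assert not np.allclose(a, b)


class TestProteinIct:
    def test_dim_399(self):
        rec = rf.SequenceRecord("p", "protein", "ACDEFG")
        assert rf.encode_protein_ict(rec).dim == 399

    def test_homopolymer_groups(self):
        rec = rf.SequenceRecord("p", "protein", "AAA")
        v = rf.encode_protein_ict(rec).values
        hot = [0, 7, 7 + 49]  # group-1 words 1, 11, 111
        assert np.allclose(v[hot], 1.0)
        assert np.count_nonzero(v) == 3

    def test_arc_example(self):
        # A->group1, R->group5, C->group7
        rec = rf.SequenceRecord("p", "protein", "ARC")
        v = rf.encode_protein_ict(rec).values
        assert v[0] == pytest.approx(1 / 3)  # group 1
        assert v[4] == pytest.approx(1 / 3)  # group 5
        assert v[6] == pytest.approx(1 / 3)  # group 7
        idx2 = {w: i for i, w in enumerate(
            "".join(p) for p in product("1234567", repeat=2))}
        assert v[7 + idx2["15"]] == pytest.approx(0.5)
        assert v[7 + idx2["57"]] == pytest.approx(0.5)
        assert np.array_equal(v, naive_protein_ict("ARC"))

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            rec = random_protein(rng, int(rng.integers(1, 51)))
            assert np.array_equal(
                rf.encode_protein_ict(rec).values,
                naive_protein_ict(rec.residues),
            )


class TestFusion:
    def test_739_and_rna_first(self):
        rng = np.random.default_rng(7)
        r = rf.encode_rna_ik(random_rna(rng, 30))
        p = rf.encode_protein_ict(random_protein(rng, 30))
        fused = rf.fuse_sequence_block(r, p)
        assert fused.dim == 739
        assert np.array_equal(fused.values[:340], r.values)

    def test_dim_mismatch(self):
        bad = rf.FeatureBlock("rna_ik", np.zeros(10))
        ok = rf.FeatureBlock("protein_ict", np.zeros(399))
        with pytest.raises(DimensionError):
            rf.fuse_sequence_block(bad, ok)
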