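"""Stacked k-mer sequence encoders.

RNA sequences are encoded by the improved k-mer scheme (IK): the frequency
vectors of all k-mers for k = 1..4 are concatenated, giving
4 + 16 + 64 + 256 = 340 dimensions. Protein sequences use the improved
conjoint triad (ICT): residues are first mapped to seven physicochemical
groups (by dipole and side-chain volume), and group k-mer frequencies for
k = 1..3 are stacked, giving 7 + 49 + 343 = 399 dimensions. Fusing the two
(RNA first) yields the 739-dimensional sequence feature block.

Each k-mer sub-block is a probability distribution: counts over the
L - k + 1 windows divided by the window count, so the sub-block sums to 1
(or is all-zero when the sequence is shorter than k). Index order within a
sub-block is lexicographic (A < C < G < U; group 1 < ... < 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .errors import AlphabetError, DimensionError
from .io import SequenceRecord

RNA_BASES = "ACGU"

#: Conjoint-triad partition of the 20 amino acids into 7 groups.
CONJOINT_TRIAD_GROUPS: dict[str, int] = {}
for _group, _residues in enumerate(
    ["AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "CU"], start=1
):  # U (selenocysteine) joins the cysteine group
    for _r in _residues:
        CONJOINT_TRIAD_GROUPS[_r] = _group

RNA_IK_DIM = 4 + 16 + 64 + 256  # 340
PROTEIN_ICT_DIM = 7 + 49 + 343  # 399
SEQUENCE_DIM = RNA_IK_DIM + PROTEIN_ICT_DIM  # 739


@dataclass(frozen=True)
class FeatureBlock:
    """A named, ordered numeric feature vector for one sample."""

    name: str  # one of: sequence, structure, physchem, ppi (or a sub-block)
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if self.values.ndim != 1:
            raise DimensionError(f"{self.name}: expected a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise DimensionError(f"{self.name}: non-finite values")

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


def _kmer_frequencies(symbols: list[int], n_symbols: int, k: int) -> np.ndarray:
    """Frequencies of all length-k words over an integer sequence.

    The denominator is the window count L - k + 1 so the vector sums to 1;
    sequences shorter than k yield the all-zero vector.
    """
    L = len(symbols)
    counts = np.zeros(n_symbols**k, dtype=np.float64)
    if L < k:
        return counts
    arr = np.asarray(symbols, dtype=np.int64)
    # lexicographic index of each window, base n_symbols
    idx = np.zeros(L - k + 1, dtype=np.int64)
    for j in range(k):
        idx = idx * n_symbols + arr[j : L - k + 1 + j]
    np.add.at(counts, idx, 1.0)
    return counts / (L - k + 1)


def encode_rna_ik(seq: SequenceRecord) -> FeatureBlock:
    """Improved k-mer encoding of an RNA sequence (340 dimensions)."""
    if seq.kind != "rna":
        raise AlphabetError(f"{seq.id}: encode_rna_ik requires an RNA record")
    symbols = [RNA_BASES.index(c) for c in seq.residues]
    parts = [_kmer_frequencies(symbols, 4, k) for k in (1, 2, 3, 4)]
    return FeatureBlock(name="rna_ik", values=np.concatenate(parts))


def encode_protein_ict(seq: SequenceRecord) -> FeatureBlock:
    """Improved conjoint-triad encoding of a protein sequence (399 dims)."""
    if seq.kind != "protein":
        raise AlphabetError(
            f"{seq.id}: encode_protein_ict requires a protein record"
        )
    groups = [CONJOINT_TRIAD_GROUPS[c] - 1 for c in seq.residues]
    parts = [_kmer_frequencies(groups, 7, k) for k in (1, 2, 3)]
    return FeatureBlock(name="protein_ict", values=np.concatenate(parts))


def fuse_sequence_block(
    rna_block: FeatureBlock, prot_block: FeatureBlock
) -> FeatureBlock:
    """Concatenate RNA (340) and protein (399) encodings, RNA first."""
    if rna_block.dim != RNA_IK_DIM:
        raise DimensionError(
            f"RNA block has dim {rna_block.dim}, expected {RNA_IK_DIM}"
        )
    if prot_block.dim != PROTEIN_ICT_DIM:
        raise DimensionError(
            f"protein block has dim {prot_block.dim}, expected {PROTEIN_ICT_DIM}"
        )
    return FeatureBlock(
        name="sequence",
        values=np.concatenate([rna_block.values, prot_block.values]),
    )


def sequence_feature_names() -> list[str]:
    """Column names for the fused 739-dim sequence block."""
    names = []
    for k in (1, 2, 3, 4):
        for word in product(RNA_BASES, repeat=k):
            names.append(f"rna_{k}mer_{''.join(word)}")
    for k in (1, 2, 3):
        for word in product("1234567", repeat=k):
            names.append(f"prot_{k}mer_{''.join(word)}")
    return names
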