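"""Synthetic dataset generator with a planted, recoverable interaction rule.

The generator emulates all four input kinds the pipeline consumes:
RNA/protein FASTA sequences, secondary-structure strings, a PPI edge
list, and labeled interaction pairs. Sequences have i.i.d. uniform
composition; a fixed RNA motif and a fixed protein motif are inserted
(2-4 copies) into randomly designated carrier molecules, and a pair is
interacting precisely when its RNA contains the RNA motif AND its protein
contains the protein motif — a signal recoverable from k-mer frequencies,
the pipeline's primary channel. Carrier proteins additionally form a
high-score PPI clique so the PPI channel carries correlated signal, while
structure strings are signal-free stem-loop (RNA) and C/E/H run-length
(protein) samples. Negative pairs are drawn uniformly from the non-
interacting combinations, the same number as positives by default.
All randomness flows from the config seed through one generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, ExhaustedSpace
from .io import (
    InteractionPair,
    PpiEdgeList,
    SequenceRecord,
    StructureString,
    write_fasta,
    write_pairs,
    write_ppi_edges,
    write_structures,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    n_rna: int = 120
    n_protein: int = 120
    n_positive: int = 400
    rna_length_range: tuple[int, int] = (100, 300)
    protein_length_range: tuple[int, int] = (80, 250)
    rna_motif: str = "GGACUACG"
    protein_motif: str = "HRDCWK"
    motif_insertion_prob: float = 0.5
    label_noise: float = 0.0
    ppi_density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.rna_motif) - set("ACGU"):
            raise ConfigError("rna_motif must be over ACGU")
        if set(self.protein_motif) - set(AMINO_ACIDS):
            raise ConfigError("protein_motif must be over amino-acid letters")
        if not 0.0 <= self.motif_insertion_prob <= 1.0:
            raise ConfigError("motif_insertion_prob must be in [0, 1]")
        if not 0.0 <= self.label_noise < 0.5:
            raise ConfigError("label_noise must be in [0, 0.5)")
        if not 0.0 <= self.ppi_density <= 1.0:
            raise ConfigError("ppi_density must be in [0, 1]")


@dataclass
class SyntheticDataset:
    rnas: list[SequenceRecord]
    proteins: list[SequenceRecord]
    rna_structures: dict[str, list[StructureString]]
    protein_structures: dict[str, list[StructureString]]
    ppi_edges: PpiEdgeList
    positives: list[InteractionPair]
    rna_carriers: list[str] = field(default_factory=list)
    protein_carriers: list[str] = field(default_factory=list)
    config: SimulationConfig = field(repr=False, default=None)

    def interacting_pairs(self) -> set[tuple[str, str]]:
        """Every (rna_id, protein_id) satisfying the planted rule."""
        return {
            (r, p) for r in self.rna_carriers for p in self.protein_carriers
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.rnas, outdir / "rna.fasta")
        write_fasta(self.proteins, outdir / "protein.fasta")
        write_structures(self.rna_structures, outdir / "rna_structures.tsv")
        write_structures(
            self.protein_structures, outdir / "protein_structures.tsv"
        )
        write_ppi_edges(self.ppi_edges, outdir / "ppi_edges.tsv")
        write_pairs(self.positives, outdir / "positive_pairs.tsv")


def _random_sequence(
    rng: np.random.Generator, alphabet: str, length_range: tuple[int, int]
) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(list(alphabet), size=length))


def _insert_motif(rng: np.random.Generator, seq: str, motif: str) -> str:
    """Overwrite the motif at 2-4 random positions (strong planted signal)."""
    chars = list(seq)
    n_copies = int(rng.integers(2, 5))
    for _ in range(n_copies):
        start = int(rng.integers(0, len(seq) - len(motif) + 1))
        chars[start : start + len(motif)] = motif
    return "".join(chars)


def _stem_loop_structure(rng: np.random.Generator, length: int) -> str:
    """Balanced dot-bracket string of exactly the requested length."""
    parts: list[str] = []
    pos = 0
    while pos < length:
        remaining = length - pos
        if remaining < 9:  # not enough for min stem(3)+loop(3)+stem(3)
            parts.append("." * remaining)
            pos = length
            break
        max_stem = min(8, (remaining - 3) // 2)
        stem = int(rng.integers(3, max_stem + 1))
        max_loop = min(8, remaining - 2 * stem)
        loop = int(rng.integers(3, max_loop + 1))
        gap = int(rng.integers(0, min(6, remaining - 2 * stem - loop) + 1))
        parts.append("(" * stem + "." * loop + ")" * stem + "." * gap)
        pos += 2 * stem + loop + gap
    return "".join(parts)


def _run_length_structure(rng: np.random.Generator, length: int) -> str:
    parts: list[str] = []
    pos = 0
    while pos < length:
        run = int(rng.integers(3, 11))
        parts.append(str(rng.choice(list("CEH"))) * min(run, length - pos))
        pos += run
    return "".join(parts)[:length]


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate sequences, structures, PPI edges, and positive pairs."""
    rng = np.random.default_rng(cfg.seed)

    rnas = []
    for i in range(cfg.n_rna):
        seq = _random_sequence(rng, "ACGU", cfg.rna_length_range)
        if rng.random() < cfg.motif_insertion_prob:
            seq = _insert_motif(rng, seq, cfg.rna_motif)
        rnas.append(SequenceRecord(id=f"rna{i:04d}", kind="rna", residues=seq))

    proteins = []
    for i in range(cfg.n_protein):
        seq = _random_sequence(rng, AMINO_ACIDS, cfg.protein_length_range)
        if rng.random() < cfg.motif_insertion_prob:
            seq = _insert_motif(rng, seq, cfg.protein_motif)
        proteins.append(
            SequenceRecord(id=f"prot{i:04d}", kind="protein", residues=seq)
        )

    # interaction rule: positive iff RNA carries the RNA motif AND the
    # protein carries the protein motif (containment, so chance occurrences
    # of a motif in a non-designated carrier count too)
    rna_carriers = [r.id for r in rnas if cfg.rna_motif in r.residues]
    prot_carriers = [p.id for p in proteins if cfg.protein_motif in p.residues]
    candidates = [(r, p) for r in rna_carriers for p in prot_carriers]
    if len(candidates) < cfg.n_positive:
        raise ConfigError(
            f"only {len(candidates)} carrier pairs available, "
            f"need {cfg.n_positive}"
        )
    chosen = rng.choice(len(candidates), size=cfg.n_positive, replace=False)
    positives = [
        InteractionPair(candidates[i][0], candidates[i][1], 1)
        for i in sorted(chosen)
    ]

    rna_structures = {
        r.id: [
            StructureString(
                id=r.id, kind="rna",
                symbols=_stem_loop_structure(rng, len(r)),
            )
        ]
        for r in rnas
    }
    protein_structures = {
        p.id: [
            StructureString(
                id=p.id, kind="protein",
                symbols=_run_length_structure(rng, len(p)),
            )
        ]
        for p in proteins
    }

    # PPI: carrier proteins form a high-score clique; sparse low-score
    # background among the rest
    edges: dict[tuple[str, str], float] = {}
    carrier_set = set(prot_carriers)
    ids = [p.id for p in proteins]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if a in carrier_set and b in carrier_set:
                s = float(rng.uniform(0.7, 1.0))
            elif rng.random() < cfg.ppi_density:
                s = float(rng.uniform(0.0, 0.3))
            else:
                continue
            edges[(a, b)] = s
            edges[(b, a)] = s
    ppi = PpiEdgeList(edges=edges)

    return SyntheticDataset(
        rnas=rnas,
        proteins=proteins,
        rna_structures=rna_structures,
        protein_structures=protein_structures,
        ppi_edges=ppi,
        positives=positives,
        rna_carriers=rna_carriers,
        protein_carriers=prot_carriers,
        config=cfg,
    )


def sample_negatives(
    positives: list[InteractionPair],
    rna_ids: list[str],
    protein_ids: list[str],
    n: int | None = None,
    seed: int = 0,
    exclude: set[tuple[str, str]] | None = None,
) -> list[InteractionPair]:
    """Uniform non-interacting pairs, without replacement.

    Default n equals the positive count (class-balanced negative
    sampling). ``exclude`` optionally widens the excluded set beyond the
    positive list itself (e.g. to every combination satisfying a planted
    interaction rule, so no sampled negative is secretly interacting).
    Raises ExhaustedSpace when fewer than n eligible combinations exist.
    """
    if n is None:
        n = len(positives)
    rng = np.random.default_rng(seed)
    positive_set = {(p.rna_id, p.protein_id) for p in positives}
    if exclude:
        positive_set = positive_set | exclude
    total = len(rna_ids) * len(protein_ids) - len(positive_set)
    if n > total:
        raise ExhaustedSpace(
            f"requested {n} negatives but only {total} non-positive "
            "combinations exist"
        )
    candidates = [
        (r, p)
        for r in rna_ids
        for p in protein_ids
        if (r, p) not in positive_set
    ]
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return [
        InteractionPair(candidates[i][0], candidates[i][1], 0)
        for i in sorted(chosen)
    ]


def simulate_labeled_dataset(
    cfg: SimulationConfig,
) -> tuple[SyntheticDataset, list[InteractionPair]]:
    """Full labeled set: positives + equal negatives, with label noise.

    Negatives are sampled from the combinations that do NOT satisfy the
    planted rule (not merely outside the sampled positive list), so the
    labels are consistent with the generative model. Returns the dataset
    and the combined pair list (labels flipped independently with
    probability ``cfg.label_noise``).
    """
    ds = simulate_dataset(cfg)
    negatives = sample_negatives(
        ds.positives,
        [r.id for r in ds.rnas],
        [p.id for p in ds.proteins],
        seed=cfg.seed + 1,
        exclude=ds.interacting_pairs(),
    )
    rng = np.random.default_rng(cfg.seed + 2)
    pairs = []
    for p in ds.positives + negatives:
        label = p.label
        if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
            label = 1 - label
        pairs.append(InteractionPair(p.rna_id, p.protein_id, label))
    return ds, pairs
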