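"""Readers and writers for the pipeline's external file formats.

Four input kinds are consumed:

* FASTA sequence files (RNA or protein),
* per-molecule secondary-structure strings as two-column TSV
  (``id<TAB>symbols``; dot-bracket for RNA, C/E/H for protein),
* labeled interaction pairs as TSV (``rna_id<TAB>protein_id<TAB>label``),
* a protein-protein interaction edge list as TSV
  (``protein_a<TAB>protein_b<TAB>score``) with scores in [0, 1].

All TSV dialects are tab-separated UTF-8; lines starting with ``#`` are
comments. Structure files carry ONE structure string per molecule; when a
structure predictor emits several suboptimal structures they may be supplied
as separate rows under the same id and are averaged after encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import (
    AlphabetError,
    DuplicatePair,
    MalformedFasta,
    ScoreRangeError,
    SymbolError,
    UnknownId,
)

Kind = Literal["rna", "protein"]

RNA_ALPHABET = frozenset("ACGU")
# the 20 standard residues plus U (selenocysteine), treated as cysteine
# by the downstream encoders
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYU")
RNA_STRUCT_ALPHABET = frozenset(".()")
PROTEIN_STRUCT_ALPHABET = frozenset("CEH")


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA or protein sequence: an id plus an uppercase residue string."""

    id: str
    kind: Kind
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"{self.id}: empty sequence")
        alphabet = RNA_ALPHABET if self.kind == "rna" else PROTEIN_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise AlphabetError(
                f"{self.id}: invalid {self.kind} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class StructureString:
    """Secondary-structure annotation aligned to one sequence.

    RNA uses dot-bracket symbols (``.`` unpaired, ``(``/``)`` paired);
    proteins use the three-class alphabet C (coil), E (sheet), H (helix).
    """

    id: str
    kind: Kind
    symbols: str

    def __post_init__(self) -> None:
        alphabet = (
            RNA_STRUCT_ALPHABET if self.kind == "rna" else PROTEIN_STRUCT_ALPHABET
        )
        bad = set(self.symbols) - alphabet
        if bad:
            raise SymbolError(
                f"{self.id}: invalid {self.kind} structure symbols {sorted(bad)}"
            )
        if self.kind == "rna" and self.symbols.count("(") != self.symbols.count(")"):
            warnings.warn(
                f"{self.id}: unbalanced parentheses (truncated structure?)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class InteractionPair:
    rna_id: str
    protein_id: str
    label: int  # 1 = interacting (positive), 0 = non-interacting

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class PpiEdgeList:
    """Symmetric protein-protein interaction scores in [0, 1].

    Stored as a dict keyed by (a, b) with both orientations present;
    self-edges are pinned to 1.0 (a protein fully 'interacts' with itself,
    matching the unit diagonal of the score matrix).
    """

    edges: dict[tuple[str, str], float]

    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.edges:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def score(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.edges.get((a, b), 0.0)


def _iter_data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_fasta(path: str | Path, kind: Kind) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Sequences are uppercased; for RNA, T is mapped to U. Records containing
    out-of-alphabet characters raise :class:`AlphabetError` naming the
    offending id; duplicate ids raise :class:`MalformedFasta`.
    """
    try:
        bio_records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython is permissive
        raise MalformedFasta(f"{path}: {exc}") from exc
    if not bio_records:
        raise MalformedFasta(f"{path}: no FASTA records found")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in bio_records:
        if rec.id in seen:
            raise MalformedFasta(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if kind == "rna":
            residues = residues.replace("T", "U")
        records.append(SequenceRecord(id=rec.id, kind=kind, residues=residues))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_structures(path: str | Path, kind: Kind) -> dict[str, list[StructureString]]:
    """Read a two-column TSV (id, symbols) of structure strings.

    Returns a mapping id -> list of structures (several rows per id are
    allowed; encoded vectors are averaged downstream).
    """
    out: dict[str, list[StructureString]] = {}
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 2:
            raise SymbolError(f"{path}:{lineno}: expected 'id<TAB>symbols'")
        sid, symbols = fields[0], fields[1]
        out.setdefault(sid, []).append(
            StructureString(id=sid, kind=kind, symbols=symbols)
        )
    return out


def write_structures(
    structures: dict[str, list[StructureString]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, structs in structures.items():
            for s in structs:
                fh.write(f"{sid}\t{s.symbols}\n")


def read_pairs(path: str | Path) -> list[InteractionPair]:
    """Read labeled interaction pairs from TSV (rna_id, protein_id, label)."""
    pairs: list[InteractionPair] = []
    seen: set[tuple[str, str]] = set()
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        rna_id, protein_id, label_str = fields[0], fields[1], fields[2]
        if label_str not in ("0", "1"):
            raise ValueError(
                f"{path}:{lineno}: label must be 0 or 1, got {label_str!r}"
            )
        key = (rna_id, protein_id)
        if key in seen:
            raise DuplicatePair(f"{path}:{lineno}: duplicate pair {key}")
        seen.add(key)
        pairs.append(InteractionPair(rna_id, protein_id, int(label_str)))
    return pairs


def write_pairs(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(f"{p.rna_id}\t{p.protein_id}\t{p.label}\n")


def read_ppi_edges(path: str | Path) -> PpiEdgeList:
    """Read a PPI edge list TSV and symmetrize it.

    Each (a, b, s) row is stored in both orientations; self-edges are
    forced to score 1.0. Scores outside [0, 1] raise ScoreRangeError.
    """
    edges: dict[tuple[str, str], float] = {}
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        a, b, s_str = fields[0], fields[1], fields[2]
        score = float(s_str)
        if not 0.0 <= score <= 1.0:
            raise ScoreRangeError(f"{path}:{lineno}: score {score} outside [0, 1]")
        if a == b:
            score = 1.0
        edges[(a, b)] = score
        edges[(b, a)] = score
    return PpiEdgeList(edges=edges)


def write_ppi_edges(ppi: PpiEdgeList, path: str | Path) -> None:
    written: set[tuple[str, str]] = set()
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), s in ppi.edges.items():
            if (b, a) in written:
                continue
            written.add((a, b))
            fh.write(f"{a}\t{b}\t{s:.6g}\n")


def assemble_pairs(
    pairs: Iterable[InteractionPair],
    rnas: Iterable[SequenceRecord],
    proteins: Iterable[SequenceRecord],
) -> list[InteractionPair]:
    """Check that every pair id resolves against the loaded collections."""
    rna_ids = {r.id for r in rnas}
    protein_ids = {p.id for p in proteins}
    out = []
    for pair in pairs:
        if pair.rna_id not in rna_ids:
            raise UnknownId(f"unknown RNA id {pair.rna_id!r}")
        if pair.protein_id not in protein_ids:
            raise UnknownId(f"unknown protein id {pair.protein_id!r}")
        out.append(pair)
    return out
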