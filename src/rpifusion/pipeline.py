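"""Dataset-level feature assembly: one matrix per feature family.

Each labeled pair is encoded into up to four feature blocks — sequence
(739), structure (40), physicochemical (25), and PPI (100) — by encoding
every unique molecule once and assembling per-pair rows. Feature-family
toggles support ablation experiments over any non-empty subset of the
four families.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError
from .io import (
    InteractionPair,
    PpiEdgeList,
    SequenceRecord,
    StructureString,
)
from .physchem import (
    PropertyTable,
    encode_protein_physchem,
    encode_rna_physchem,
    load_property_table,
    physchem_feature_names,
)
from .ppi import build_ppi_matrix, fit_projection, lookup_ppi, ppi_feature_names
from .sequence import (
    encode_protein_ict,
    encode_rna_ik,
    fuse_sequence_block,
    sequence_feature_names,
)
from .structure import (
    encode_structures_averaged,
    fuse_structure_block,
    structure_feature_names,
)

ALL_BLOCKS = ("sequence", "structure", "physchem", "ppi")


def feature_names(enabled: tuple[str, ...] = ALL_BLOCKS) -> dict[str, list[str]]:
    names = {
        "sequence": sequence_feature_names(),
        "structure": structure_feature_names(),
        "physchem": physchem_feature_names(),
        "ppi": ppi_feature_names(),
    }
    return {k: names[k] for k in enabled}


def encode_dataset(
    pairs: list[InteractionPair],
    rnas: list[SequenceRecord],
    proteins: list[SequenceRecord],
    rna_structures: dict[str, list[StructureString]] | None = None,
    protein_structures: dict[str, list[StructureString]] | None = None,
    ppi_edges: PpiEdgeList | None = None,
    enabled: tuple[str, ...] = ALL_BLOCKS,
    rna_table: PropertyTable | None = None,
    protein_table: PropertyTable | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Encode pairs into per-family matrices; returns (blocks, labels)."""
    unknown = set(enabled) - set(ALL_BLOCKS)
    if unknown:
        raise ConfigError(f"unknown feature families: {sorted(unknown)}")
    if not enabled:
        raise ConfigError("at least one feature family must be enabled")
    if "structure" in enabled and (
        rna_structures is None or protein_structures is None
    ):
        raise ConfigError("structure family enabled but structures missing")
    if "ppi" in enabled and ppi_edges is None:
        raise ConfigError("ppi family enabled but no PPI edge list given")

    rna_by_id = {r.id: r for r in rnas}
    prot_by_id = {p.id: p for p in proteins}

    rna_seq_cache: dict[str, np.ndarray] = {}
    prot_seq_cache: dict[str, np.ndarray] = {}
    rna_struct_cache: dict[str, np.ndarray] = {}
    prot_struct_cache: dict[str, np.ndarray] = {}
    rna_pc_cache: dict[str, np.ndarray] = {}
    prot_pc_cache: dict[str, np.ndarray] = {}

    if "physchem" in enabled:
        rna_table = rna_table or load_property_table("rna_dinucleotide")
        protein_table = protein_table or load_property_table("protein_residue")

    projection = None
    if "ppi" in enabled:
        projection = fit_projection(build_ppi_matrix(ppi_edges))

    blocks: dict[str, list[np.ndarray]] = {name: [] for name in enabled}
    labels = np.array([p.label for p in pairs], dtype=np.int64)

    for pair in pairs:
        rna = rna_by_id[pair.rna_id]
        prot = prot_by_id[pair.protein_id]
        if "sequence" in enabled:
            if rna.id not in rna_seq_cache:
                rna_seq_cache[rna.id] = encode_rna_ik(rna).values
            if prot.id not in prot_seq_cache:
                prot_seq_cache[prot.id] = encode_protein_ict(prot).values
            blocks["sequence"].append(
                np.concatenate(
                    [rna_seq_cache[rna.id], prot_seq_cache[prot.id]]
                )
            )
        if "structure" in enabled:
            if rna.id not in rna_struct_cache:
                rna_struct_cache[rna.id] = encode_structures_averaged(
                    rna_structures[rna.id]
                )
            if prot.id not in prot_struct_cache:
                prot_struct_cache[prot.id] = encode_structures_averaged(
                    protein_structures[prot.id]
                )
            blocks["structure"].append(
                fuse_structure_block(
                    rna_struct_cache[rna.id], prot_struct_cache[prot.id]
                ).values
            )
        if "physchem" in enabled:
            if rna.id not in rna_pc_cache:
                rna_pc_cache[rna.id] = encode_rna_physchem(rna, rna_table)
            if prot.id not in prot_pc_cache:
                prot_pc_cache[prot.id] = encode_protein_physchem(
                    prot, protein_table
                )
            blocks["physchem"].append(
                np.concatenate([rna_pc_cache[rna.id], prot_pc_cache[prot.id]])
            )
        if "ppi" in enabled:
            blocks["ppi"].append(lookup_ppi(projection, prot.id).values)

    matrices = {name: np.vstack(rows) for name, rows in blocks.items()}
    # consistency with the single-pair fusion path
    if "sequence" in enabled:
        assert matrices["sequence"].shape[1] == 739
    if projection is not None and projection.zero_vector_rate > 0:
        import logging

        logging.getLogger(__name__).info(
            "PPI zero-vector rate: %.3f", projection.zero_vector_rate
        )
    return matrices, labels


# re-exported here so callers can fuse single pairs through the same API
__all__ = [
    "ALL_BLOCKS",
    "encode_dataset",
    "feature_names",
    "fuse_sequence_block",
]
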