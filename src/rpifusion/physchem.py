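"""Reduced physicochemical descriptors for RNA and protein sequences.

The RNA descriptor condenses each of 22 dinucleotide properties (content
fractions, helix-step geometry, nearest-neighbour energetics, and
hydrophilicity scales) to one scalar: the lag-1 auto-covariance of the
z-normalized property values along the sequence's overlapping
dinucleotides — a dinucleotide auto-covariance profile at minimal lag.
The protein descriptor condenses each of 3 residue properties
(hydrophobicity, hydrophilicity, residue mass) to the first-tier
sequence-order correlation factor of pseudo amino-acid composition: the
mean squared difference of normalized values at adjacent positions.
Fusing the two (RNA first) yields the 25-dimensional physicochemical
feature block.

Property values are z-normalized across the 16 dinucleotides (or 20
residues) before encoding, so rescaling a raw property column leaves the
encoder output unchanged. Default tables ship with the package
(``data/*.tsv``); users may supply their own via the same TSV layout
(rows = units, columns = properties).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DegenerateProperty, DimensionError, SequenceTooShort
from .io import SequenceRecord
from .sequence import FeatureBlock

#: the 22 RNA dinucleotide properties, in canonical column order
RNA_PROPERTY_NAMES = (
    "Adenine content", "GC content", "Purine content", "Keto content",
    "Cytosine content", "Thymine content", "Guanine content",
    "Tilt", "Twist", "Roll", "Rise", "Shift", "Slide",
    "Stacking energy", "Entropy", "Entropy 1", "Enthalpy", "Enthalpy 1",
    "Free energy", "Free energy 1", "Hydrophilicity", "Hydrophilicity 1",
)
PROTEIN_PROPERTY_NAMES = ("hydrophobicity", "hydrophilicity", "mass")

RNA_PHYSCHEM_DIM = len(RNA_PROPERTY_NAMES)  # 22
PROTEIN_PHYSCHEM_DIM = len(PROTEIN_PROPERTY_NAMES)  # 3
PHYSCHEM_DIM = RNA_PHYSCHEM_DIM + PROTEIN_PHYSCHEM_DIM  # 25

TableKind = Literal["rna_dinucleotide", "protein_residue"]


@dataclass
class PropertyTable:
    """Per-unit property values: units are 16 dinucleotides or 20 residues."""

    kind: TableKind
    table: pd.DataFrame  # index = units, columns = property names

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)


def load_property_table(
    kind: TableKind, path: str | Path | None = None
) -> PropertyTable:
    """Load a property table TSV; ``path=None`` loads the bundled default."""
    if path is None:
        fname = (
            "rna_dinucleotide_properties.tsv"
            if kind == "rna_dinucleotide"
            else "protein_residue_properties.tsv"
        )
        ref = resources.files("rpifusion.data").joinpath(fname)
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    expected = (
        RNA_PROPERTY_NAMES if kind == "rna_dinucleotide" else PROTEIN_PROPERTY_NAMES
    )
    if tuple(df.columns) != expected:
        raise DimensionError(
            f"{kind} table must have columns {list(expected)}, "
            f"got {list(df.columns)}"
        )
    n_units = 16 if kind == "rna_dinucleotide" else 20
    if len(df) != n_units:
        raise DimensionError(f"{kind} table must have {n_units} rows")
    return PropertyTable(kind=kind, table=df.astype(np.float64))


def normalize_property(raw: PropertyTable) -> PropertyTable:
    """Standardize each property to mean 0, sd 1 across its units."""
    df = raw.table
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=0)
    constant = sds[sds == 0.0].index.tolist()
    if constant:
        raise DegenerateProperty(
            f"constant across units: {constant}"
        )
    return PropertyTable(kind=raw.kind, table=(df - means) / sds)


def _lag1_autocovariance(v: np.ndarray) -> float:
    # (1/(m-1)) sum_j (v_j - vbar)(v_{j+1} - vbar) over the m values
    m = v.size
    d = v - v.mean()
    return float(np.dot(d[:-1], d[1:]) / (m - 1))


def encode_rna_physchem(
    seq: SequenceRecord, table: PropertyTable | None = None
) -> np.ndarray:
    """22 lag-1 dinucleotide auto-covariances, one per property."""
    if table is None:
        table = load_property_table("rna_dinucleotide")
    if len(seq) < 3:
        raise SequenceTooShort(
            f"{seq.id}: RNA physicochemical encoding needs length >= 3"
        )
    norm = normalize_property(table).table
    dinucs = [seq.residues[j : j + 2] for j in range(len(seq) - 1)]
    out = np.empty(len(norm.columns), dtype=np.float64)
    for c, prop in enumerate(norm.columns):
        v = norm[prop].loc[dinucs].to_numpy()
        out[c] = _lag1_autocovariance(v)
    return out


def encode_protein_physchem(
    seq: SequenceRecord, table: PropertyTable | None = None
) -> np.ndarray:
    """3 first-tier sequence-order correlation factors, one per property."""
    if table is None:
        table = load_property_table("protein_residue")
    if len(seq) < 2:
        raise SequenceTooShort(
            f"{seq.id}: protein physicochemical encoding needs length >= 2"
        )
    norm = normalize_property(table).table
    # selenocysteine takes the cysteine property values
    residues = list(seq.residues.replace("U", "C"))
    out = np.empty(len(norm.columns), dtype=np.float64)
    for c, prop in enumerate(norm.columns):
        v = norm[prop].loc[residues].to_numpy()
        out[c] = float(np.mean((v[:-1] - v[1:]) ** 2))
    return out


def fuse_physchem_block(
    rna_vec: np.ndarray, prot_vec: np.ndarray
) -> FeatureBlock:
    """Concatenate RNA (22) and protein (3) descriptors, RNA first (dim 25)."""
    rna_vec = np.asarray(rna_vec, dtype=np.float64)
    prot_vec = np.asarray(prot_vec, dtype=np.float64)
    if rna_vec.shape != (RNA_PHYSCHEM_DIM,):
        raise DimensionError(
            f"RNA physchem vector has shape {rna_vec.shape}, "
            f"expected ({RNA_PHYSCHEM_DIM},)"
        )
    if prot_vec.shape != (PROTEIN_PHYSCHEM_DIM,):
        raise DimensionError(
            f"protein physchem vector has shape {prot_vec.shape}, "
            f"expected ({PROTEIN_PHYSCHEM_DIM},)"
        )
    return FeatureBlock(
        name="physchem", values=np.concatenate([rna_vec, prot_vec])
    )


def physchem_feature_names() -> list[str]:
    rna = [f"rna_ac_{n.replace(' ', '_')}" for n in RNA_PROPERTY_NAMES]
    prot = [f"prot_socf_{n}" for n in PROTEIN_PROPERTY_NAMES]
    return rna + prot
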