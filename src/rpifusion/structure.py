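"""Secondary-structure encoding by cosine-series compression.

Structure strings are digitized symbol-by-symbol — for RNA, "." -> 0 and
"(" or ")" -> 1 (pairing direction is ignored beyond paired/unpaired); for
proteins, C -> 0, E -> 1, H -> 2 — and the resulting integer series of
length l is compressed to a fixed 20 coefficients

    X_i = sqrt(2/l) * sum_{n=0}^{l-1} x_n cos[(pi/l)(n + 1/2)(i + 1/2)],
    i = 0..19,

the half-sample-shifted cosine kernel (the orthonormal type-IV discrete
cosine transform when i < l). Coefficients are signed. The formula is
defined for any i, so series shorter than 20 still yield 20 coefficients
without zero-padding. Fusing RNA and protein coefficients (RNA first)
gives the 40-dimensional structure block.
"""

from __future__ import annotations

import numpy as np

from .errors import DimensionError, EmptySeries, SymbolError
from .io import StructureString
from .sequence import FeatureBlock

N_STRUCT_COEFFS = 20
STRUCTURE_DIM = 2 * N_STRUCT_COEFFS  # 40

_RNA_MAP = {".": 0, "(": 1, ")": 1}
_PROTEIN_MAP = {"C": 0, "E": 1, "H": 2}


def digitize_structure(s: StructureString) -> np.ndarray:
    """Map a structure string to its integer series (length preserved)."""
    table = _RNA_MAP if s.kind == "rna" else _PROTEIN_MAP
    try:
        return np.array([table[c] for c in s.symbols], dtype=np.float64)
    except KeyError as exc:
        raise SymbolError(f"{s.id}: unknown structure symbol {exc}") from exc


def cosine_transform(
    series: np.ndarray, n_coeffs: int = N_STRUCT_COEFFS
) -> np.ndarray:
    """First ``n_coeffs`` half-sample-shifted cosine coefficients of a series.

    Returns exactly ``n_coeffs`` signed values regardless of the series
    length l (the kernel is defined for any frequency index i).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise EmptySeries("cosine_transform requires a non-empty 1-D series")
    l = x.size
    n = np.arange(l)
    i = np.arange(n_coeffs)
    kernel = np.cos(np.pi / l * np.outer(i + 0.5, n + 0.5))  # (n_coeffs, l)
    return np.sqrt(2.0 / l) * kernel @ x


def encode_structure(s: StructureString) -> np.ndarray:
    """Digitize and transform one structure string to 20 coefficients."""
    return cosine_transform(digitize_structure(s))


def encode_structures_averaged(structs: list[StructureString]) -> np.ndarray:
    """Encode several suboptimal structures of one molecule and average.

    Averaging happens after the transform, so alternative structures of
    different lengths (e.g. from truncation) still combine cleanly.
    """
    if not structs:
        raise EmptySeries("no structures to encode")
    return np.mean([encode_structure(s) for s in structs], axis=0)


def fuse_structure_block(
    rna_coeffs: np.ndarray, prot_coeffs: np.ndarray
) -> FeatureBlock:
    """Concatenate RNA and protein coefficient vectors, RNA first (dim 40)."""
    rna_coeffs = np.asarray(rna_coeffs, dtype=np.float64)
    prot_coeffs = np.asarray(prot_coeffs, dtype=np.float64)
    if rna_coeffs.shape != (N_STRUCT_COEFFS,):
        raise DimensionError(
            f"RNA coefficients have shape {rna_coeffs.shape}, "
            f"expected ({N_STRUCT_COEFFS},)"
        )
    if prot_coeffs.shape != (N_STRUCT_COEFFS,):
        raise DimensionError(
            f"protein coefficients have shape {prot_coeffs.shape}, "
            f"expected ({N_STRUCT_COEFFS},)"
        )
    return FeatureBlock(
        name="structure", values=np.concatenate([rna_coeffs, prot_coeffs])
    )


def structure_feature_names() -> list[str]:
    return [f"rna_dct_{i}" for i in range(N_STRUCT_COEFFS)] + [
        f"prot_dct_{i}" for i in range(N_STRUCT_COEFFS)
    ]
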