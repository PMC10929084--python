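"""Protein-protein interaction features.

A symmetric score matrix (unit diagonal, entries in [0, 1]) is built over a
reference protein set capped at 400 proteins — when more are supplied, the
400 of highest degree (ties broken by id) are kept. The matrix rows are
compressed by principal-component projection to 100 dimensions; each
protein's PPI feature is its projected row, zero-padded when the matrix
rank is below 100. Proteins outside the reference set (e.g. proteins with
no known interactions) receive the all-zero 100-vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .io import PpiEdgeList
from .sequence import FeatureBlock

logger = logging.getLogger(__name__)

PPI_DIM = 100
REFERENCE_CAP = 400


@dataclass
class PpiMatrix:
    proteins: list[str]
    scores: np.ndarray  # square, symmetric, unit diagonal

    @property
    def side(self) -> int:
        return len(self.proteins)


@dataclass
class PpiProjection:
    components: np.ndarray  # (n_axes, side) projection basis
    mean: np.ndarray  # row mean removed before projection
    per_protein: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    n_components: int = PPI_DIM
    _zero_lookups: int = 0
    _total_lookups: int = 0

    @property
    def zero_vector_rate(self) -> float:
        """Fraction of lookups that fell back to the all-zero vector."""
        if self._total_lookups == 0:
            return 0.0
        return self._zero_lookups / self._total_lookups


def build_ppi_matrix(
    edges: PpiEdgeList, reference_cap: int = REFERENCE_CAP
) -> PpiMatrix:
    """Assemble the score matrix over the (capped) reference protein set."""
    proteins = edges.proteins()
    if len(proteins) > reference_cap:
        degree = {p: 0 for p in proteins}
        for (a, b), _ in edges.edges.items():
            if a != b:
                degree[a] += 1
        proteins = sorted(proteins, key=lambda p: (-degree[p], p))[:reference_cap]
    else:
        proteins = sorted(proteins)
    side = len(proteins)
    m = np.zeros((side, side), dtype=np.float64)
    idx = {p: i for i, p in enumerate(proteins)}
    for (a, b), s in edges.edges.items():
        if a in idx and b in idx:
            m[idx[a], idx[b]] = s
    np.fill_diagonal(m, 1.0)
    return PpiMatrix(proteins=proteins, scores=m)


def fit_projection(m: PpiMatrix, n_components: int = PPI_DIM) -> PpiProjection:
    """Principal-component projection of the matrix rows.

    Rows are mean-centered and projected onto the top
    ``min(n_components, side, rank)`` principal axes; each protein's vector
    is zero-padded to exactly ``n_components`` entries. The per-axis sign
    ambiguity is fixed by making the largest-magnitude loading of each axis
    positive, so identical inputs give bit-identical projections.
    """
    side = m.side
    if side == 0:
        return PpiProjection(
            components=np.zeros((0, 0)), mean=np.zeros(0),
            n_components=n_components,
        )
    k = min(n_components, side)
    pca = PCA(n_components=k, svd_solver="full")
    projected = pca.fit_transform(m.scores)
    components = pca.components_.copy()  # (k, side)
    # sign convention: largest-|loading| entry of each axis is positive
    for ax in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[ax])))
        if components[ax, j] < 0:
            components[ax] = -components[ax]
            projected[:, ax] = -projected[:, ax]
    per_protein = {}
    for i, p in enumerate(m.proteins):
        vec = np.zeros(n_components, dtype=np.float64)
        vec[: projected.shape[1]] = projected[i]
        per_protein[p] = vec
    return PpiProjection(
        components=components,
        mean=pca.mean_.copy(),
        per_protein=per_protein,
        n_components=n_components,
    )


def lookup_ppi(proj: PpiProjection, protein_id: str) -> FeatureBlock:
    """The protein's projected row, or all zeros for unknown proteins."""
    proj._total_lookups += 1
    vec = proj.per_protein.get(protein_id)
    if vec is None:
        proj._zero_lookups += 1
        if not hasattr(proj, "_warned"):
            proj._warned = set()
        if protein_id not in proj._warned:  # warn once per protein
            proj._warned.add(protein_id)
            logger.warning(
                "protein %r absent from PPI reference set; using zero vector",
                protein_id,
            )
        vec = np.zeros(proj.n_components, dtype=np.float64)
    return FeatureBlock(name="ppi", values=vec)


def ppi_feature_names(n_components: int = PPI_DIM) -> list[str]:
    return [f"ppi_pc_{i}" for i in range(n_components)]
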