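"""Relationship matrices: pedigree A (tabular method) and genomic G
(VanRaden method 1).

The additive relationship matrix A gives expected genome sharing from the
pedigree; the genomic relationship matrix G estimates realised sharing from
SNP calls, ``G = WW' / (2 * sum_j p_j (1 - p_j))`` with ``W = M - 2p``
centred on observed allele frequencies. A small identity blend keeps G
invertible for mixed-model equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import MISSING_CALL, GenotypePanel, Pedigree

__all__ = [
    "RelationshipMatrix",
    "additive_relationship_matrix",
    "vanraden_grm",
    "stabilize",
]


@dataclass
class RelationshipMatrix:
    ids: list[str]
    matrix: np.ndarray
    kind: str  # "pedigree_A" | "genomic_G"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("relationship matrix must be symmetric")

    def submatrix(self, keep: list[str]) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[a] for a in keep])
        return RelationshipMatrix(list(keep), self.matrix[np.ix_(idx, idx)], self.kind)


def additive_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Tabular method: a_ii = 1 + a(sire,dam)/2; a_ij = (a(j,sire) +
    a(j,dam)) / 2 for earlier j; unknown parents contribute 0."""
    parents = ped.parent_indices()
    n = parents.shape[0]
    if np.any(parents >= np.arange(n)[:, None]):
        # Pedigree construction guarantees parents-first; defensive check
        raise ValueError("pedigree is not topologically ordered")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = parents[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ped.animals, A, "pedigree_A")


def vanraden_grm(panel: GenotypePanel) -> RelationshipMatrix:
    """VanRaden method-1 GRM with observed (sample) allele frequencies.

    Missing calls are imputed to 2p (zero contribution after centring);
    monomorphic SNPs contribute to neither numerator nor denominator.
    """
    calls = panel.calls.astype(float)
    calls[panel.calls == MISSING_CALL] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic SNPs for a GRM")
    W = calls[:, poly] - 2.0 * p[poly]
    W[np.isnan(W)] = 0.0
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(list(panel.ids), G, "genomic_G")


def stabilize(G: RelationshipMatrix, blend_weight: float = 0.01) -> RelationshipMatrix:
    """Blend with the identity: G* = (1 - w) G + w I, bounding eigenvalues
    away from zero so mixed-model equations stay solvable."""
    if not 0.0 <= blend_weight < 1.0:
        raise ValueError("blend_weight must be in [0, 1)")
    if blend_weight == 0.0:
        return G
    n = len(G.ids)
    M = (1.0 - blend_weight) * G.matrix + blend_weight * np.eye(n)
    return RelationshipMatrix(list(G.ids), M, G.kind)
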