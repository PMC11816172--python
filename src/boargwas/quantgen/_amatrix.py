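"""Numerator relationship matrix by the tabular method."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import PedigreeTable

__all__ = ["RelationshipMatrix", "build_A"]


@dataclass
class RelationshipMatrix:
    """Additive (numerator) relationship matrix over ordered animals.

    ``parents`` maps each animal to its (sire, dam) pair (None = unknown);
    it travels with the matrix so downstream deregression can form parent
    averages without re-reading the pedigree.
    """

    values: np.ndarray
    animals: list
    parents: dict = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.animals), len(self.animals)):
            raise ValueError("relationship matrix shape does not match animal list")

    @property
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F = diag(A) - 1."""
        return np.diag(self.values) - 1.0

    def submatrix(self, ids) -> np.ndarray:
        idx = {a: i for i, a in enumerate(self.animals)}
        rows = [idx[str(a)] for a in ids]
        return self.values[np.ix_(rows, rows)]


def build_A(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Tabular-method numerator relationship matrix.

    Animals are processed in topological order. For animal i with parents
    (s, d): A[i, j] = (A[s, j] + A[d, j]) / 2 for earlier j (missing parent
    contributes 0) and A[i, i] = 1 + A[s, d] / 2, so the diagonal carries
    1 + F.
    """
    animals = pedigree.animals
    idx = {a: i for i, a in enumerate(animals)}
    parents = pedigree.parents()
    n = len(animals)
    a_mat = np.zeros((n, n))
    for i, animal in enumerate(animals):
        sire, dam = parents[animal]
        si = idx[sire] if sire is not None else None
        di = idx[dam] if dam is not None else None
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * a_mat[si, :i]
        if di is not None:
            row += 0.5 * a_mat[di, :i]
        a_mat[i, :i] = row
        a_mat[:i, i] = row
        diag = 1.0
        if si is not None and di is not None:
            diag += 0.5 * a_mat[si, di]
        a_mat[i, i] = diag
    return RelationshipMatrix(a_mat, animals, parents=parents)
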