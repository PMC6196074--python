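"""Pairwise dissimilarities: p-distances on alignments, Hamming on 0/1 matrices.

Both are observed-difference proportions; unknown states and gaps are
excluded from the comparable-column count (pairwise deletion) or globally
(complete deletion).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .matrix import ABSENT, PRESENT, UNKNOWN, BinaryCharacterMatrix, ResidueAlignment

__all__ = ["DistanceMatrix", "p_distance", "hamming_distance"]


class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    def __init__(self, taxa: Sequence[str], values: np.ndarray):
        taxa = list(taxa)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(taxa), len(taxa)):
            raise ValueError("distance array shape does not match taxa")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(values < 0):
            raise ValueError("negative dissimilarity")
        self.taxa = taxa
        self.values = values

    def __getitem__(self, pair) -> float:
        i, j = pair
        if isinstance(i, str):
            i = self.taxa.index(i)
        if isinstance(j, str):
            j = self.taxa.index(j)
        return float(self.values[i, j])

    def __len__(self) -> int:
        return len(self.taxa)

    def reorder(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.values[np.ix_(idx, idx)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"DistanceMatrix({len(self.taxa)} taxa)"


def _pairwise_mismatch(rows: np.ndarray, comparable: np.ndarray, taxa: Sequence[str]) -> np.ndarray:
    n = rows.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = comparable[i] & comparable[j]
            denom = int(ok.sum())
            if denom == 0:
                raise ValueError(f"taxa {taxa[i]!r} and {taxa[j]!r} share no comparable columns")
            d[i, j] = d[j, i] = np.count_nonzero(rows[i, ok] != rows[j, ok]) / denom
    return d


def p_distance(alignment: ResidueAlignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Observed proportion of differing residues per comparable column pair.

    ``deletion='pairwise'`` drops gap/ambiguity columns per pair;
    ``'complete'`` drops any column with a gap/ambiguity in any row.
    """
    if len(alignment.taxa) < 2:
        raise ValueError("need at least two sequences")
    arr = np.array([list(r) for r in alignment.rows])
    if alignment.alphabet == "nucleotide":
        determinate = np.isin(arr, list("ACGTU"))
    else:
        determinate = np.isin(arr, list("ACDEFGHIKLMNPQRSTVWY"))
    if deletion == "complete":
        keep = determinate.all(axis=0)
        arr, determinate = arr[:, keep], determinate[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    return DistanceMatrix(alignment.taxa, _pairwise_mismatch(arr, determinate, alignment.taxa))


def hamming_distance(matrix: BinaryCharacterMatrix, deletion: str = "pairwise") -> DistanceMatrix:
    """Fraction of determinate characters at which two taxa differ (0/1 states).

    Identical to the p-distance on the binary coding; unknown cells are
    excluded pairwise (or globally under ``deletion='complete'``).
    """
    determinate = matrix.states != UNKNOWN
    states = matrix.states
    if deletion == "complete":
        keep = determinate.all(axis=0)
        states, determinate = states[:, keep], determinate[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    return DistanceMatrix(matrix.taxa, _pairwise_mismatch(states, determinate, matrix.taxa))
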