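"""Bag-of-simplices vectorization of volume-optimal cycles.

Each snapshot's set of cycles is treated as a "text" whose words are the
residue-pair edges appearing in the cycles.  The weight of an unordered
residue pair (i, j) is the summed lifetime of all volume-optimal cycles
whose edge set contains that pair:

    s_ij = sum over cycles C_k containing (i, j) of (d_k - b_k)

giving an R(R-1)/2-dimensional non-negative vector per snapshot (595 for a
35-residue chain).  Weights inherit the radius convention of the homology
stage and therefore carry Angstrom units.

Edge-to-coordinate mapping is lexicographic over (i, j) with i < j, 0-based
in memory; on-disk headers use 1-based residue numbers (see tdafold.io).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .homology import PersistentCycle

__all__ = [
    "feature_dimension",
    "edge_index",
    "edge_pairs",
    "bag_of_simplices",
    "stack_features",
    "FeatureVector",
    "FeatureMatrix",
]


def feature_dimension(n_residues: int) -> int:
    """Number of unordered residue pairs, R(R-1)/2; 595 for R = 35."""
    if n_residues < 2:
        raise InvalidArgumentError("need at least 2 residues")
    return n_residues * (n_residues - 1) // 2


def edge_index(i: int, j: int, n_residues: int) -> int:
    """Lexicographic coordinate of the unordered pair (i, j), i < j."""
    if not (0 <= i < j < n_residues):
        raise InvalidArgumentError(f"edge ({i}, {j}) out of range for R={n_residues}")
    return i * n_residues - i * (i + 1) // 2 + (j - i - 1)


def edge_pairs(n_residues: int) -> list[tuple[int, int]]:
    """All unordered pairs in lexicographic order (the coordinate basis)."""
    return [(i, j) for i in range(n_residues) for j in range(i + 1, n_residues)]


@dataclass(frozen=True)
class FeatureVector:
    """One snapshot's edge-weight vector s_ij (A), lexicographic pair order."""

    weights: np.ndarray
    n_residues: int
    snapshot_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.shape[0] != feature_dimension(self.n_residues):
            raise InvalidArgumentError(
                f"weights must have dimension R(R-1)/2 = "
                f"{feature_dimension(self.n_residues)}, got {w.shape}"
            )
        if np.any(w < 0):
            raise InvalidArgumentError("edge weights must be non-negative")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class FeatureMatrix:
    """Stacked feature vectors: rows = edge features, columns = snapshots."""

    values: np.ndarray  # (N, M), non-negative
    n_residues: int
    snapshot_ids: tuple[str, ...]
    trajectory_ids: tuple[str, ...] = ()
    frame_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != feature_dimension(self.n_residues):
            raise InvalidArgumentError("row count must equal R(R-1)/2")
        if v.shape[1] != len(self.snapshot_ids):
            raise InvalidArgumentError("one snapshot id per column required")
        if np.any(v < 0):
            raise InvalidArgumentError("feature matrix must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n_features(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_snapshots(self) -> int:
        return int(self.values.shape[1])


def bag_of_simplices(
    cycles: list[PersistentCycle],
    n_residues: int,
    snapshot_id: str = "",
) -> FeatureVector:
    """Edge-weight vector of one snapshot from its volume-optimal cycles.

    Each cycle contributes its lifetime d - b once to every edge in its
    edge *set* (a repeated edge in a pathological input counts once); pairs
    in no cycle get weight 0.
    """
    weights = np.zeros(feature_dimension(n_residues))
    for cyc in cycles:
        if not cyc.death > cyc.birth:
            raise InvalidArgumentError("cycle must have death > birth")
        lifetime = cyc.death - cyc.birth
        for i, j in set(cyc.cycle):
            weights[edge_index(i, j, n_residues)] += lifetime
    return FeatureVector(weights, n_residues, snapshot_id)


def stack_features(vectors: list[FeatureVector]) -> FeatureMatrix:
    """Column-stack feature vectors in input order, metadata preserved."""
    if not vectors:
        raise InvalidArgumentError("need at least one feature vector")
    n_res = vectors[0].n_residues
    if any(v.n_residues != n_res for v in vectors):
        raise InvalidArgumentError("all vectors must share one residue count")
    values = np.column_stack([v.weights for v in vectors])
    return FeatureMatrix(
        values=values,
        n_residues=n_res,
        snapshot_ids=tuple(v.snapshot_id for v in vectors),
    )
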