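"""Core in-memory containers: a snapshot's Cα point cloud and a trajectory.

A snapshot is nothing more than the ordered Cα positions p_1 ... p_R of an
R-residue chain, in Angstrom.  Residue indices are 0-based everywhere in
memory; the on-disk writers renumber to 1-based (see :mod:`tdafold.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["PointCloud", "Trajectory"]


@dataclass(frozen=True)
class PointCloud:
    """Ordered Cα coordinates of one snapshot, shape (R, 3), Angstrom."""

    coords: np.ndarray
    residue_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise InvalidArgumentError(
                f"coords must have shape (R, 3) with R >= 1, got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise InvalidArgumentError("coordinates must be finite")
        if self.residue_labels is not None and len(self.residue_labels) != coords.shape[0]:
            raise InvalidArgumentError("residue_labels length must match residue count")
        object.__setattr__(self, "coords", coords)

    @property
    def n_residues(self) -> int:
        return int(self.coords.shape[0])

    def radius_of_gyration(self) -> float:
        centered = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((centered**2).sum(axis=1).mean()))


@dataclass(frozen=True)
class Trajectory:
    """An ordered sequence of snapshots sampled every ``frame_interval`` ps."""

    trajectory_id: str
    frames: tuple[PointCloud, ...]
    frame_interval: float = 250.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) < 1:
            raise InvalidArgumentError("a trajectory needs at least one frame")
        n = frames[0].n_residues
        if any(f.n_residues != n for f in frames):
            raise InvalidArgumentError("all frames must share one residue count")
        if not self.frame_interval > 0:
            raise InvalidArgumentError("frame_interval must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        return self.frames[0].n_residues

    def coords_array(self) -> np.ndarray:
        """Stack all frames into an (n_frames, R, 3) array."""
        return np.stack([f.coords for f in self.frames])


def as_point_cloud(obj: PointCloud | Sequence | np.ndarray) -> PointCloud:
    """Coerce an (R, 3) array-like into a :class:`PointCloud`."""
    if isinstance(obj, PointCloud):
        return obj
    return PointCloud(np.asarray(obj, dtype=float))
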