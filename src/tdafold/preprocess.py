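"""Trajectory-ensemble cleaning: frozen-frame removal and native-RMSD filtering.

Two artifacts must be handled before any topological analysis: snapshots in
which every atom has collapsed onto one identical coordinate triple (a
distributed-computing merge artifact), and trajectories that never actually
reach the native state.  Degenerate frames are removed wherever they occur;
a trajectory is kept only if its minimum frame-wise Kabsch RMSD to the
native structure is strictly below the cutoff (1.0 A by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyTrajectoryError, InvalidArgumentError
from .structures import PointCloud, Trajectory, as_point_cloud

__all__ = [
    "kabsch_rmsd",
    "strip_degenerate_frames",
    "filter_trajectories",
    "FilterReport",
]

_DEGENERATE_VAR_TOL = 1e-12  # A^2, per-axis coordinate variance across residues


def kabsch_rmsd(P: PointCloud | np.ndarray, Q: PointCloud | np.ndarray) -> float:
    """Minimum RMSD between two Cα clouds over rigid-body superpositions.

    Rotations are proper (no reflection), the standard structural-biology
    convention; the result is symmetric in its arguments.
    """
    P = as_point_cloud(P).coords
    Q = as_point_cloud(Q).coords
    if P.shape != Q.shape:
        raise InvalidArgumentError(
            f"point clouds differ in size: {P.shape} vs {Q.shape}"
        )
    if P.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 residues for superposition")
    p = P - P.mean(axis=0)
    q = Q - Q.mean(axis=0)
    # Kabsch via SVD of the covariance; flip the smallest singular direction
    # when the optimal orthogonal map would be a reflection.  The RMSD is
    # evaluated from the explicit residuals (not the singular-value identity),
    # which avoids catastrophic cancellation for near-identical clouds.
    cov = p.T @ q
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u * np.array([1.0, 1.0, d])) @ vt
    resid = p @ rot - q
    return float(np.sqrt((resid**2).sum() / P.shape[0]))


def _is_degenerate(frame: PointCloud) -> bool:
    """True iff all residues share one identical coordinate triple."""
    return bool(np.all(frame.coords.var(axis=0) <= _DEGENERATE_VAR_TOL))


def strip_degenerate_frames(traj: Trajectory) -> tuple[Trajectory, int]:
    """Remove every frame whose residues all sit at one point.

    The rule is applied to all frames, not only trailing ones; order of the
    surviving frames is preserved.  Raises if nothing would remain.
    """
    keep = [f for f in traj.frames if not _is_degenerate(f)]
    removed = traj.n_frames - len(keep)
    if not keep:
        raise EmptyTrajectoryError(
            f"trajectory {traj.trajectory_id!r}: every frame is degenerate"
        )
    if removed == 0:
        return traj, 0
    return (
        Trajectory(
            traj.trajectory_id,
            tuple(keep),
            frame_interval=traj.frame_interval,
            rng_seed=traj.rng_seed,
        ),
        removed,
    )


@dataclass(frozen=True)
class FilterReport:
    """Per-trajectory filtering outcome (min RMSD, kept flag, frames removed)."""

    trajectory_ids: tuple[str, ...]
    min_rmsd: tuple[float, ...]
    kept: tuple[bool, ...]
    frames_removed: tuple[int, ...]
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trajectory_id": self.trajectory_ids,
                "min_rmsd": self.min_rmsd,
                "kept": self.kept,
                "frames_removed": self.frames_removed,
            }
        )

    @property
    def n_kept(self) -> int:
        return int(sum(self.kept))


def filter_trajectories(
    ensemble: list[Trajectory],
    native: PointCloud,
    cutoff: float = 1.0,
) -> tuple[list[Trajectory], FilterReport]:
    """Keep trajectories whose minimum Kabsch RMSD to native is < cutoff.

    Degenerate frames are stripped first (and counted in the report) so a
    frozen tail can neither qualify nor disqualify a trajectory.  The
    inequality at the cutoff is strict: a trajectory at exactly the cutoff
    is excluded.
    """
    if not ensemble:
        raise InvalidArgumentError("empty ensemble")
    native = as_point_cloud(native)
    for traj in ensemble:
        if traj.n_residues != native.n_residues:
            raise InvalidArgumentError(
                f"trajectory {traj.trajectory_id!r} has {traj.n_residues} residues,"
                f" native has {native.n_residues}"
            )
    ids, mins, kept_flags, removed_counts = [], [], [], []
    kept_trajs = []
    for traj in ensemble:
        cleaned, removed = strip_degenerate_frames(traj)
        min_rmsd = min(kabsch_rmsd(f, native) for f in cleaned.frames)
        keep = min_rmsd < cutoff
        ids.append(traj.trajectory_id)
        mins.append(min_rmsd)
        kept_flags.append(keep)
        removed_counts.append(removed)
        if keep:
            kept_trajs.append(cleaned)
    report = FilterReport(
        trajectory_ids=tuple(ids),
        min_rmsd=tuple(mins),
        kept=tuple(kept_flags),
        frames_removed=tuple(removed_counts),
        cutoff=cutoff,
    )
    return kept_trajs, report
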