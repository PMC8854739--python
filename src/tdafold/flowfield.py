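"""Dynamics in the NMF-reduced space: flow fields, histograms, path labels.

Each trajectory becomes a sequence of L-dimensional non-negative NMF score
vectors (units Å).  The velocity at frame t is the per-frame score
displacement score(t+1) − score(t), attributed to the cell containing
score(t); displacements never span trajectory boundaries.  Binning the
velocities on a regular grid gives the mean-velocity flow field used to
locate fixed points and folding corridors; cells supported by too few
samples (≤ min_count) carry no velocity estimate.  Because a cell mean can
average opposing motions into an apparent standstill, the velocity
*distribution* within a region is also exposed.

``classify_paths`` operationalizes the two-path picture: a trajectory is
labeled by which of two selected score components first exceeds a
threshold.  This is a derived statistic of this package, not a
field-standard quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "ReducedTrajectory",
    "FlowField",
    "frame_velocities",
    "bin_flow",
    "velocity_histogram",
    "density_histogram",
    "classify_paths",
]


@dataclass(frozen=True)
class ReducedTrajectory:
    """Per-frame NMF score vectors of one trajectory (frames x L, Å)."""

    trajectory_id: str
    scores: np.ndarray
    frame_interval: float = 250.0

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] < 1:
            raise InvalidArgumentError("scores must be a (frames, L) array")
        if np.any(s < -1e-9):
            raise InvalidArgumentError("NMF scores must be non-negative")
        object.__setattr__(self, "scores", s)

    @property
    def n_frames(self) -> int:
        return int(self.scores.shape[0])


@dataclass(frozen=True)
class FlowField:
    """Grid-binned sample counts and mean velocities in reduced space.

    ``mean_velocity`` is NaN wherever ``counts`` ≤ ``min_count`` (the cell
    is reported but carries no velocity estimate).
    """

    axes: tuple[int, ...]
    bin_edges: tuple[np.ndarray, ...]
    counts: np.ndarray
    mean_velocity: np.ndarray  # counts.shape + (len(axes),)
    min_count: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cell indices, centers, count, velocity components."""
        idx = np.indices(self.counts.shape).reshape(len(self.axes), -1).T
        rows = {}
        for k, ax in enumerate(self.axes):
            rows[f"cell_{ax}"] = idx[:, k]
            centers = 0.5 * (self.bin_edges[k][:-1] + self.bin_edges[k][1:])
            rows[f"center_{ax}"] = centers[idx[:, k]]
        rows["count"] = self.counts.ravel()
        vel = self.mean_velocity.reshape(-1, len(self.axes))
        for k, ax in enumerate(self.axes):
            rows[f"v_{ax}"] = vel[:, k]
        return pd.DataFrame(rows)


def frame_velocities(rt: ReducedTrajectory) -> list[tuple[np.ndarray, np.ndarray]]:
    """(position, velocity) pairs of one trajectory by finite difference.

    Velocity at frame t is score(t+1) − score(t) in Å per frame interval,
    attributed to the earlier frame's position; a single-frame trajectory
    yields an empty list with a warning.
    """
    if rt.n_frames < 2:
        warnings.warn(
            f"trajectory {rt.trajectory_id!r} has a single frame; no velocities",
            stacklevel=2,
        )
        return []
    pos = rt.scores[:-1]
    vel = np.diff(rt.scores, axis=0)
    return [(pos[i], vel[i]) for i in range(len(pos))]


def ensemble_velocities(
    ensemble: list[ReducedTrajectory],
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Concatenate per-trajectory velocity points; boundaries never spanned."""
    points: list[tuple[np.ndarray, np.ndarray]] = []
    for rt in ensemble:
        points.extend(frame_velocities(rt))
    return points


def _project(
    points: list[tuple[np.ndarray, np.ndarray]], axes: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    if not points:
        raise InvalidArgumentError("no velocity points supplied")
    pos = np.array([p for p, _ in points])[:, list(axes)]
    vel = np.array([v for _, v in points])[:, list(axes)]
    return pos, vel


def bin_flow(
    points: list[tuple[np.ndarray, np.ndarray]],
    axes: tuple[int, ...],
    bins_per_axis: int = 20,
    min_count: int = 100,
) -> FlowField:
    """Mean velocity per grid cell over the selected score components.

    Bin edges span the data range on each axis.  A cell's mean velocity is
    the arithmetic mean of its members' velocities and is only reported for
    cells with strictly more than ``min_count`` samples.
    """
    if bins_per_axis < 2:
        raise InvalidArgumentError("bins_per_axis must be >= 2")
    if len(set(axes)) != len(axes):
        raise InvalidArgumentError("axes must be distinct")
    pos, vel = _project(points, axes)
    ndim = len(axes)
    edges = []
    codes = []
    for k in range(ndim):
        lo, hi = pos[:, k].min(), pos[:, k].max()
        if hi <= lo:
            hi = lo + 1e-9
        e = np.linspace(lo, hi, bins_per_axis + 1)
        edges.append(e)
        c = np.clip(np.searchsorted(e, pos[:, k], side="right") - 1, 0, bins_per_axis - 1)
        codes.append(c)
    flat = np.ravel_multi_index(codes, (bins_per_axis,) * ndim)
    counts = np.bincount(flat, minlength=bins_per_axis**ndim)
    sums = np.zeros((bins_per_axis**ndim, ndim))
    for k in range(ndim):
        sums[:, k] = np.bincount(flat, weights=vel[:, k], minlength=bins_per_axis**ndim)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts[:, None]
    mean[counts <= min_count] = np.nan
    shape = (bins_per_axis,) * ndim
    return FlowField(
        axes=tuple(axes),
        bin_edges=tuple(edges),
        counts=counts.reshape(shape),
        mean_velocity=mean.reshape(shape + (ndim,)),
        min_count=min_count,
    )


def velocity_histogram(
    points: list[tuple[np.ndarray, np.ndarray]],
    axes: tuple[int, int],
    region: tuple[tuple[float, float], tuple[float, float]],
    bins: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of velocity components within a position region.

    Selects points whose projected position lies strictly inside the
    per-axis open intervals of ``region`` and histograms the corresponding
    velocity components.  An empty selection yields an empty histogram
    with a warning, not an error.
    """
    for lo, hi in region:
        if not hi > lo:
            raise InvalidArgumentError("region intervals must be non-empty")
    pos, vel = _project(points, axes)
    inside = np.ones(len(pos), bool)
    for k, (lo, hi) in enumerate(region):
        inside &= (pos[:, k] > lo) & (pos[:, k] < hi)
    if not inside.any():
        warnings.warn("no samples inside the requested region", stacklevel=2)
        empty_edges = np.linspace(0.0, 1.0, bins + 1)
        return np.zeros((bins, bins)), empty_edges, empty_edges
    hist, ex, ey = np.histogram2d(vel[inside, 0], vel[inside, 1], bins=bins)
    return hist, ex, ey


def density_histogram(
    positions: np.ndarray,
    axes: tuple[int, ...],
    bins: int = 20,
) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Plain sample counts on a grid over the selected score components.

    Returns raw counts; any logarithmic display transform is up to the
    caller and is not stored.
    """
    if bins < 2:
        raise InvalidArgumentError("bins must be >= 2")
    positions = np.asarray(positions, float)
    if positions.ndim != 2 or positions.shape[0] == 0:
        raise InvalidArgumentError("positions must be a non-empty (n, L) array")
    proj = positions[:, list(axes)]
    counts, edges = np.histogramdd(proj, bins=bins)
    return counts, tuple(edges)


def classify_paths(
    ensemble: list[ReducedTrajectory],
    component_first: int,
    component_second: int,
    threshold: float,
) -> pd.DataFrame:
    """Label each trajectory by which score component crosses a threshold first.

    Crossing = first frame with score > threshold.  Label "A" if
    ``component_first`` crosses strictly earlier than ``component_second``,
    "B" if the second crosses first (or only the second crosses);
    trajectories where neither crosses are labeled "unresolved".  Swapping
    the two component arguments swaps the A and B labels.
    """
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    rows = []
    for rt in ensemble:
        c1 = _first_crossing(rt.scores[:, component_first], threshold)
        c2 = _first_crossing(rt.scores[:, component_second], threshold)
        if c1 is None and c2 is None:
            label = "unresolved"
        elif c2 is None or (c1 is not None and c1 < c2):
            label = "A"
        else:
            label = "B"
        rows.append(
            {
                "trajectory_id": rt.trajectory_id,
                "label": label,
                "crossing_first": c1,
                "crossing_second": c2,
            }
        )
    return pd.DataFrame(rows)


def _first_crossing(series: np.ndarray, threshold: float) -> int | None:
    above = np.nonzero(series > threshold)[0]
    return int(above[0]) if above.size else None
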