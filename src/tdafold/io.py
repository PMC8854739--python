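"""On-disk formats: multi-model PDB, XYZ tables, CSV/JSON stage artifacts.

All residue numbering on disk is 1-based (matching the usual residue naming
such as V9 or K32); in-memory indices are 0-based throughout the package.
PDB handling goes through biotite; tabular artifacts are plain CSV so every
intermediate stage can be inspected and re-run independently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .homology import PersistentCycle
from .structures import PointCloud, Trajectory
from .vectorize import FeatureMatrix, edge_pairs

__all__ = [
    "write_pdb_multimodel",
    "read_pdb_multimodel",
    "write_xyz_table",
    "read_xyz_table",
    "read_trajectory",
    "write_diagrams_csv",
    "write_cycles_json",
    "read_cycles_json",
    "write_feature_matrix_csv",
    "read_feature_matrix_csv",
]


def write_pdb_multimodel(traj: Trajectory, path: str | Path) -> None:
    """One MODEL per frame, Cα-only ATOM records, 1-based residue numbers."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_res = traj.n_residues
    arrays = []
    for frame in traj.frames:
        atoms = struc.AtomArray(n_res)
        atoms.coord = np.asarray(frame.coords, dtype=np.float32)
        atoms.chain_id = np.full(n_res, "A")
        atoms.res_id = np.arange(1, n_res + 1)
        atoms.res_name = np.full(n_res, "ALA")
        atoms.atom_name = np.full(n_res, "CA")
        atoms.element = np.full(n_res, "C")
        arrays.append(atoms)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb_multimodel(
    path: str | Path, trajectory_id: str | None = None, frame_interval: float = 250.0
) -> Trajectory:
    """Read a Cα multi-model PDB back into a trajectory."""
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    frames = tuple(PointCloud(c) for c in coords)
    tid = trajectory_id or Path(path).stem
    return Trajectory(tid, frames, frame_interval=frame_interval)


def write_xyz_table(traj: Trajectory, path: str | Path) -> None:
    """Whitespace table (frame, residue, x, y, z); frame and residue 1-based."""
    with open(path, "w") as fh:
        fh.write("frame residue x y z\n")
        for f_idx, frame in enumerate(traj.frames, start=1):
            for r_idx, (x, y, z) in enumerate(frame.coords, start=1):
                fh.write(f"{f_idx} {r_idx} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_table(
    path: str | Path, trajectory_id: str | None = None, frame_interval: float = 250.0
) -> Trajectory:
    frames_coords: dict[int, list[tuple[int, list[float]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0] == "frame":
                continue
            try:
                f_idx, r_idx = int(parts[0]), int(parts[1])
                xyz = [float(v) for v in parts[2:5]]
                if len(xyz) != 3:
                    raise ValueError("expected 3 coordinates")
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            frames_coords.setdefault(f_idx, []).append((r_idx, xyz))
    if not frames_coords:
        raise ParseError(f"{path}: no data rows")
    frames = []
    for f_idx in sorted(frames_coords):
        rows = sorted(frames_coords[f_idx])
        frames.append(PointCloud(np.array([xyz for _, xyz in rows])))
    tid = trajectory_id or Path(path).stem
    return Trajectory(tid, tuple(frames), frame_interval=frame_interval)


def read_trajectory(path: str | Path, format: str = "auto") -> Trajectory:
    """Dispatch on ``format`` in {pdb_multimodel, xyz_table, auto}."""
    if format == "auto":
        format = "pdb_multimodel" if str(path).endswith(".pdb") else "xyz_table"
    if format == "pdb_multimodel":
        return read_pdb_multimodel(path)
    if format == "xyz_table":
        return read_xyz_table(path)
    raise ParseError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# stage artifacts
# ---------------------------------------------------------------------------


def write_diagrams_csv(
    cycles_by_snapshot: dict[str, list[PersistentCycle]], path: str | Path
) -> None:
    rows = [
        {
            "snapshot_id": sid,
            "birth": c.birth,
            "death": c.death,
            "optimal_volume_size": c.optimal_volume_size,
        }
        for sid, cycles in cycles_by_snapshot.items()
        for c in cycles
    ]
    pd.DataFrame(
        rows, columns=["snapshot_id", "birth", "death", "optimal_volume_size"]
    ).to_csv(path, index=False)


def write_cycles_json(
    cycles_by_snapshot: dict[str, list[PersistentCycle]], path: str | Path
) -> None:
    """JSON: snapshot → list of {birth, death, edges}; indices are 0-based."""
    payload = {
        "indexing": "0-based",
        "snapshots": {
            sid: [
                {
                    "birth": c.birth,
                    "death": c.death,
                    "edges": sorted([list(e) for e in c.cycle]),
                }
                for c in cycles
            ]
            for sid, cycles in cycles_by_snapshot.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_cycles_json(path: str | Path) -> dict[str, list[PersistentCycle]]:
    with open(path) as fh:
        payload = json.load(fh)
    out: dict[str, list[PersistentCycle]] = {}
    for sid, cycles in payload["snapshots"].items():
        out[sid] = [
            PersistentCycle(
                birth=c["birth"],
                death=c["death"],
                cycle=frozenset(tuple(e) for e in c["edges"]),
                optimal_volume_size=0,
            )
            for c in cycles
        ]
    return out


def write_feature_matrix_csv(matrix: FeatureMatrix, path: str | Path) -> None:
    """Rows = snapshots, columns s_i_j with 1-based residue numbers.

    A sidecar ``<path>.meta.csv`` maps each snapshot to its trajectory and
    frame where that metadata exists.
    """
    cols = [f"s_{i + 1}_{j + 1}" for i, j in edge_pairs(matrix.n_residues)]
    df = pd.DataFrame(matrix.values.T, columns=cols)
    df.insert(0, "snapshot_id", matrix.snapshot_ids)
    df.to_csv(path, index=False)
    if matrix.trajectory_ids:
        meta = pd.DataFrame(
            {
                "snapshot_id": matrix.snapshot_ids,
                "trajectory_id": matrix.trajectory_ids,
                "frame_index": matrix.frame_indices,
            }
        )
        meta.to_csv(f"{path}.meta.csv", index=False)


def read_feature_matrix_csv(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    snap_ids = tuple(df.pop("snapshot_id").astype(str))
    n = df.shape[1]
    # invert N = R(R-1)/2
    r = int(round((1 + np.sqrt(1 + 8 * n)) / 2))
    if r * (r - 1) // 2 != n:
        raise ParseError(f"{path}: {n} feature columns is not R(R-1)/2 for any R")
    meta_path = Path(f"{path}.meta.csv")
    traj_ids: tuple[str, ...] = ()
    frame_idx: tuple[int, ...] = ()
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        traj_ids = tuple(meta["trajectory_id"].astype(str))
        frame_idx = tuple(int(v) for v in meta["frame_index"])
    return FeatureMatrix(
        values=df.to_numpy(dtype=float).T,
        n_residues=r,
        snapshot_ids=snap_ids,
        trajectory_ids=traj_ids,
        frame_indices=frame_idx,
    )
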