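"""End-to-end orchestration: simulate → preprocess → PH → vectorize → NMF → flow.

The pipeline is a thin, deterministic composition of the stage modules.
Every stage writes its artifact in the documented on-disk format so stages
can be re-run independently, and a manifest records per-stage counts that
are cross-checked at each boundary (snapshots entering persistent homology
must equal feature-matrix columns, and so on).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .errors import InvalidArgumentError
from .factorize import FactorModel, cophenetic_rank_selection, nmf_fit
from .flowfield import ReducedTrajectory, bin_flow, classify_paths, ensemble_velocities
from .homology import diagram_for_snapshot
from .preprocess import filter_trajectories
from .structures import PointCloud, Trajectory
from .synthetic import (
    CONTACT_SETS,
    CONTACT_THRESHOLD,
    ChainSpec,
    append_frozen_tail,
    make_native,
    plan_a,
    plan_b,
    simulate_folding_trajectory,
    simulate_nonfolding_trajectory,
)
from .vectorize import FeatureMatrix, bag_of_simplices, edge_index, stack_features

logger = logging.getLogger("tdafold")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "component_for_contact_set"]

read_trajectory = tio.read_trajectory  # re-exported pipeline entry point


@dataclass
class RunConfig:
    """Flat run configuration; every field has a logged default."""

    out_dir: str = "tdafold_run"
    # synthetic ensemble
    n_fold_a: int = 10
    n_fold_b: int = 10
    n_nonfolding: int = 10
    n_frozen_tails: int = 5
    frozen_tail_frames: int = 5
    n_frames: int = 60
    noise_sigma: float = 0.25
    native_seed: int = 0
    # preprocess
    rmsd_cutoff: float = 1.0
    # homology
    jitter_seed: int = 0
    ph_max_birth: float = 20.0  # Å; discard boundary-artifact loops born beyond this
    # NMF
    nmf_rank: int = 4
    nmf_seed: int = 0
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    rank_selection: bool = False
    ranks: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    n_runs: int = 30
    n_subsample: int = 10000
    # flow field
    flow_bins: int = 20
    flow_min_count: int = 100
    path_threshold: float | None = None
    global_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        if "ranks" in raw:
            raw["ranks"] = tuple(raw["ranks"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["ranks"] = list(self.ranks)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class RunManifest:
    """Per-stage record counts, timings and the config snapshot."""

    config: dict
    counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    software_version: str = ""

    def check_consistency(self) -> None:
        c = self.counts
        if "snapshots" in c and "feature_columns" in c:
            if c["snapshots"] != c["feature_columns"]:
                raise AssertionError(
                    f"snapshots into PH ({c['snapshots']}) != feature columns "
                    f"({c['feature_columns']})"
                )
        if "feature_columns" in c and "score_columns" in c:
            if c["feature_columns"] != c["score_columns"]:
                raise AssertionError("feature columns != NMF score columns")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "counts": self.counts,
                    "timings_s": self.timings_s,
                    "software_version": self.software_version,
                },
                fh,
                indent=2,
            )


def component_for_contact_set(
    H: np.ndarray, V: FeatureMatrix, pairs: tuple[tuple[int, int], ...]
) -> int:
    """NMF component most correlated with a contact set's edge weights.

    Mirrors the basis-interpretation step of the analysis: the summed
    bag-of-simplices weights of the set's edges form a per-snapshot series,
    and the component whose score row correlates best with it is the one
    "reporting on" those contacts.
    """
    target = _contact_target(V, pairs)
    best, best_corr = 0, -np.inf
    for comp in range(H.shape[0]):
        corr = _safe_corr(H[comp], target)
        if corr > best_corr:
            best, best_corr = comp, corr
    return best


def components_for_contact_sets(
    H: np.ndarray,
    V: FeatureMatrix,
    contact_sets: dict[int, tuple[tuple[int, int], ...]],
) -> dict[int, int]:
    """Jointly assign one distinct NMF component to each contact set.

    Uses the optimal one-to-one matching maximizing the total score-weight
    correlation, so two sets can never collapse onto a single component.
    """
    from scipy.optimize import linear_sum_assignment

    set_ids = sorted(contact_sets)
    corr = np.zeros((len(set_ids), H.shape[0]))
    for r, cid in enumerate(set_ids):
        target = _contact_target(V, contact_sets[cid])
        for comp in range(H.shape[0]):
            corr[r, comp] = _safe_corr(H[comp], target)
    rows, cols = linear_sum_assignment(-corr)
    return {set_ids[r]: int(c) for r, c in zip(rows, cols)}


def _contact_target(
    V: FeatureMatrix, pairs: tuple[tuple[int, int], ...]
) -> np.ndarray:
    idx = [edge_index(i, j, V.n_residues) for i, j in pairs]
    target = V.values[idx].sum(axis=0)
    if np.ptp(target) == 0:
        raise InvalidArgumentError("contact-set edges carry no weight anywhere")
    return target


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _generate_ensemble(cfg: RunConfig) -> tuple[list[Trajectory], PointCloud]:
    spec = ChainSpec()
    native = make_native(spec, seed=cfg.native_seed)
    ensemble: list[Trajectory] = []
    seed0 = cfg.global_seed * 10_000
    for k in range(cfg.n_fold_a):
        ensemble.append(
            simulate_folding_trajectory(
                native,
                plan_a(),
                n_frames=cfg.n_frames,
                noise_sigma=cfg.noise_sigma,
                seed=seed0 + k,
                spec=spec,
                trajectory_id=f"fold_A_{k:03d}",
            )
        )
    for k in range(cfg.n_fold_b):
        ensemble.append(
            simulate_folding_trajectory(
                native,
                plan_b(),
                n_frames=cfg.n_frames,
                noise_sigma=cfg.noise_sigma,
                seed=seed0 + 1000 + k,
                spec=spec,
                trajectory_id=f"fold_B_{k:03d}",
            )
        )
    for k in range(cfg.n_nonfolding):
        ensemble.append(
            simulate_nonfolding_trajectory(
                n_residues=spec.n_residues,
                n_frames=cfg.n_frames,
                seed=seed0 + 2000 + k,
                native=native,
                trajectory_id=f"coil_{k:03d}",
            )
        )
    for k in range(min(cfg.n_frozen_tails, len(ensemble))):
        ensemble[k] = append_frozen_tail(ensemble[k], cfg.frozen_tail_frames)
    return ensemble, native


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, writing every intermediate artifact.

    Identical config and seeds produce identical manifest counts.  A stage
    failure aborts with the stage name in the exception message.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), software_version=__version__)
    manifest.config["ranks"] = list(config.ranks)

    def _stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    # --- simulate -----------------------------------------------------
    t0 = _stage("simulate")
    ensemble, native = _generate_ensemble(config)
    for traj in ensemble:
        tio.write_xyz_table(traj, out / f"{traj.trajectory_id}.xyz")
    tio.write_xyz_table(
        Trajectory("native", (native,)), out / "native.xyz"
    )
    manifest.counts["trajectories_in"] = len(ensemble)
    manifest.timings_s["simulate"] = round(time.perf_counter() - t0, 3)

    # --- preprocess ---------------------------------------------------
    t0 = _stage("preprocess")
    kept, report = filter_trajectories(ensemble, native, cutoff=config.rmsd_cutoff)
    report.to_frame().to_csv(out / "filter_report.csv", index=False)
    manifest.counts["trajectories_kept"] = len(kept)
    manifest.counts["degenerate_frames_removed"] = int(sum(report.frames_removed))
    manifest.timings_s["preprocess"] = round(time.perf_counter() - t0, 3)
    if not kept:
        logger.warning("no trajectories kept; stopping after preprocess")
        manifest.write(out / "manifest.json")
        return manifest

    # --- persistent homology + vectorization --------------------------
    t0 = _stage("persistent_homology")
    vectors = []
    traj_ids: list[str] = []
    frame_indices: list[int] = []
    cycles_by_snapshot = {}
    for traj in kept:
        for f_idx, frame in enumerate(traj.frames):
            sid = f"{traj.trajectory_id}:{f_idx}"
            try:
                cycles = diagram_for_snapshot(
                    frame,
                    jitter_seed=config.jitter_seed,
                    max_birth=config.ph_max_birth,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage persistent_homology failed on snapshot {sid}"
                ) from exc
            cycles_by_snapshot[sid] = cycles
            vectors.append(bag_of_simplices(cycles, traj.n_residues, sid))
            traj_ids.append(traj.trajectory_id)
            frame_indices.append(f_idx)
    tio.write_diagrams_csv(cycles_by_snapshot, out / "diagrams.csv")
    tio.write_cycles_json(cycles_by_snapshot, out / "cycles.json")
    manifest.counts["snapshots"] = len(vectors)
    manifest.counts["cycles"] = int(
        sum(len(c) for c in cycles_by_snapshot.values())
    )
    manifest.timings_s["persistent_homology"] = round(time.perf_counter() - t0, 3)

    t0 = _stage("vectorize")
    matrix = stack_features(vectors)
    matrix = FeatureMatrix(
        values=matrix.values,
        n_residues=matrix.n_residues,
        snapshot_ids=matrix.snapshot_ids,
        trajectory_ids=tuple(traj_ids),
        frame_indices=tuple(frame_indices),
    )
    tio.write_feature_matrix_csv(matrix, out / "features.csv")
    manifest.counts["feature_columns"] = matrix.n_snapshots
    manifest.timings_s["vectorize"] = round(time.perf_counter() - t0, 3)

    # --- NMF ----------------------------------------------------------
    t0 = _stage("nmf")
    rank = config.nmf_rank
    if config.rank_selection:
        rank_report = cophenetic_rank_selection(
            matrix,
            list(config.ranks),
            n_runs=config.n_runs,
            n_subsample=config.n_subsample,
            seed=config.nmf_seed,
        )
        rank = rank_report.selected_rank_cophenetic or rank
        rows = [
            {"rank": L, "cophenetic": rank_report.cophenetic.get(L)}
            for L in rank_report.ranks
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "rank_report.csv", index=False)
        manifest.counts["selected_rank"] = rank
    model = nmf_fit(
        matrix,
        rank,
        seed=config.nmf_seed,
        max_iter=config.nmf_max_iter,
        tol=config.nmf_tol,
    )
    np.savetxt(out / "W.csv", model.W, delimiter=",")
    np.savetxt(out / "H.csv", model.H, delimiter=",")
    manifest.counts["nmf_rank"] = rank
    manifest.counts["score_columns"] = model.H.shape[1]
    manifest.timings_s["nmf"] = round(time.perf_counter() - t0, 3)

    # --- flow field and path classification ---------------------------
    t0 = _stage("flow")
    reduced = _reduced_trajectories(model, matrix)
    assignment = components_for_contact_sets(model.H, matrix, CONTACT_SETS)
    comp1, comp2 = assignment[1], assignment[2]
    threshold = config.path_threshold
    if threshold is None:
        # half the characteristic activated score of the two components:
        # well above the near-zero unfolded noise floor, well below the
        # plateau a formed loop produces
        pool = np.concatenate([model.H[comp1], model.H[comp2]])
        threshold = 0.5 * float(np.quantile(pool, 0.95))
    points = ensemble_velocities(reduced)
    field2d = bin_flow(
        points,
        axes=(comp1, comp2),
        bins_per_axis=config.flow_bins,
        min_count=config.flow_min_count,
    )
    field2d.to_frame().to_csv(out / "flowfield.csv", index=False)
    labels = classify_paths(reduced, comp1, comp2, threshold)
    labels.to_csv(out / "path_labels.csv", index=False)
    manifest.counts["component_contact_set_1"] = comp1
    manifest.counts["component_contact_set_2"] = comp2
    manifest.counts["path_labels"] = {
        k: int(v) for k, v in labels["label"].value_counts().items()
    }
    manifest.timings_s["flow"] = round(time.perf_counter() - t0, 3)

    manifest.check_consistency()
    manifest.write(out / "manifest.json")
    return manifest


def _reduced_trajectories(
    model: FactorModel, matrix: FeatureMatrix
) -> list[ReducedTrajectory]:
    """Split H columns back into per-trajectory score sequences."""
    if not matrix.trajectory_ids:
        raise InvalidArgumentError("feature matrix lacks trajectory metadata")
    order: dict[str, list[int]] = {}
    for col, tid in enumerate(matrix.trajectory_ids):
        order.setdefault(tid, []).append(col)
    reduced = []
    for tid, cols in order.items():
        cols_sorted = sorted(cols, key=lambda c: matrix.frame_indices[c])
        reduced.append(ReducedTrajectory(tid, model.H[:, cols_sorted].T))
    return reduced
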