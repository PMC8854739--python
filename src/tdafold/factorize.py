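"""Non-negative matrix factorization of the feature matrix with rank selection.

The N x M feature matrix V (rows = residue-pair features, columns =
snapshots) is approximated as V ~ W H with W (N x L) and H (L x M)
non-negative, minimizing the Frobenius objective ||V - WH||.  After the
fit, each basis column w_j is rescaled to unit Euclidean norm (with the
matching H row scaled inversely, leaving W H unchanged), which pins down
the diagonal scale ambiguity of NMF and gives the "NMF scores" h_ji the
units of the features (Angstrom).

Two standard rank-selection procedures are provided:

* RSS inflection (Hutchins-style): fit each candidate rank on a column
  subsample and look for the rank where the residual-sum-of-squares curve
  turns from steep decline to plateau (maximal positive second difference).
  When the curve declines essentially linearly, no rank can be determined
  and the report says so rather than guessing.
* Cophenetic correlation (Brunet-style consensus clustering): repeat the
  fit from many random initializations, assign each sample to its
  largest-coefficient basis, build the consensus co-clustering matrix, and
  score each rank by the cophenetic correlation between the consensus
  distances and their average-linkage dendrogram.  The selected rank
  maximizes the coefficient (smallest rank on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .errors import DegenerateFactorError, InvalidArgumentError
from .vectorize import FeatureMatrix

__all__ = [
    "FactorModel",
    "RankReport",
    "nmf_fit",
    "normalize_factors",
    "rank_selection_rss",
    "cophenetic_rank_selection",
    "transform",
]

_EPS = 1e-12


def _as_matrix(V: FeatureMatrix | np.ndarray) -> np.ndarray:
    arr = V.values if isinstance(V, FeatureMatrix) else np.asarray(V, dtype=float)
    if arr.ndim != 2:
        raise InvalidArgumentError("V must be a 2-D matrix")
    if np.any(arr < 0):
        raise InvalidArgumentError("V must be non-negative")
    return arr


@dataclass
class FactorModel:
    """Fitted NMF factors with unit-norm basis columns.

    ``W`` is N x L with each column of unit Euclidean norm; ``H`` is L x M.
    ``objective_history`` records ||V - WH||_F at every multiplicative
    update (non-increasing by construction of the updates).
    """

    W: np.ndarray
    H: np.ndarray
    rank: int
    objective: float
    objective_history: np.ndarray
    seed: int
    n_iter: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


def _init_factors(
    shape: tuple[int, int], rank: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n, m = shape
    scale = 1.0
    w = rng.random((n, rank)) + _EPS
    h = rng.random((rank, m)) + _EPS
    return scale * w, scale * h


def nmf_fit(
    V: FeatureMatrix | np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> FactorModel:
    """Multiplicative-update NMF minimizing the Frobenius objective.

    Starts from a seeded random non-negative initialization scaled to the
    data magnitude; stops when the relative objective change falls below
    ``tol`` or after ``max_iter`` updates.  Factors are normalized so each
    basis column has unit Euclidean norm.
    """
    arr = _as_matrix(V)
    n, m = arr.shape
    if not (1 <= rank <= min(n, m)):
        raise InvalidArgumentError(f"rank must lie in [1, {min(n, m)}], got {rank}")
    rng = np.random.default_rng(seed)
    w, h = _init_factors((n, m), rank, rng)
    # scale the random start to the data magnitude so early updates are sane
    data_scale = np.sqrt(max(arr.mean(), _EPS) / rank)
    w *= data_scale
    h *= data_scale

    history = []
    obj = np.linalg.norm(arr - w @ h)
    history.append(obj)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        h *= (w.T @ arr) / (w.T @ w @ h + _EPS)
        w *= (arr @ h.T) / (w @ (h @ h.T) + _EPS)
        new_obj = np.linalg.norm(arr - w @ h)
        history.append(new_obj)
        if abs(obj - new_obj) <= tol * max(obj, _EPS):
            obj = new_obj
            converged = True
            break
        obj = new_obj

    w, h = normalize_factors(w, h)
    return FactorModel(
        W=w,
        H=h,
        rank=rank,
        objective=float(obj),
        objective_history=np.asarray(history),
        seed=seed,
        n_iter=it,
        converged=converged,
    )


def normalize_factors(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each basis column to unit norm, H rows inversely; WH unchanged."""
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    norms = np.linalg.norm(W, axis=0)
    zero = np.where(norms <= 0)[0]
    if zero.size:
        raise DegenerateFactorError(
            f"basis column(s) {zero.tolist()} are all-zero and cannot be normalized"
        )
    return W / norms, H * norms[:, None]


@dataclass
class RankReport:
    """Per-rank diagnostics from one or both rank-selection procedures."""

    ranks: tuple[int, ...]
    rss: dict[int, float] = field(default_factory=dict)
    cophenetic: dict[int, float] = field(default_factory=dict)
    n_subsample: int = 0
    n_runs: int = 0
    seed: int = 0
    selected_rank_rss: int | None = None
    selected_rank_cophenetic: int | None = None


def _subsample_columns(
    arr: np.ndarray, n_subsample: int, rng: np.random.Generator
) -> np.ndarray:
    m = arr.shape[1]
    if n_subsample >= m:
        if n_subsample > m:
            warnings.warn(
                f"n_subsample={n_subsample} exceeds {m} columns; using all",
                stacklevel=3,
            )
        return arr
    cols = rng.choice(m, size=n_subsample, replace=False)
    return arr[:, np.sort(cols)]


def rank_selection_rss(
    V: FeatureMatrix | np.ndarray,
    ranks: list[int],
    n_subsample: int = 10000,
    seed: int = 0,
    ratio_min: float = 5.0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> RankReport:
    """RSS-versus-rank curve on a column subsample, with inflection pick.

    RSS(L) = ||V_sub - W H||_F^2.  The inflection is located through the
    per-rank drops D(L) = RSS(L-1) - RSS(L): the selected rank maximizes
    the ratio D(L) / D(L+1), the last large drop before the curve turns
    into a plateau.  If no ratio exceeds ``ratio_min`` the curve declines
    essentially linearly and no rank is selected (``selected_rank_rss``
    stays None) — a legitimate outcome, not an error.
    """
    arr = _as_matrix(V)
    ranks = sorted(ranks)
    if any(r > min(arr.shape[0], n_subsample) for r in ranks):
        raise InvalidArgumentError("ranks must be <= min(N, n_subsample)")
    rng = np.random.default_rng(seed)
    sub = _subsample_columns(arr, n_subsample, rng)
    report = RankReport(
        ranks=tuple(ranks), n_subsample=sub.shape[1], seed=seed
    )
    for L in ranks:
        model = nmf_fit(sub, L, seed=seed + L, max_iter=max_iter, tol=tol)
        report.rss[L] = float(model.objective**2)

    rss = np.array([report.rss[L] for L in ranks])
    if len(ranks) >= 3:
        drops = rss[:-1] - rss[1:]
        floor = 1e-12 * max(rss[0], _EPS)
        ratios = drops[:-1] / np.maximum(drops[1:], floor)
        best = int(np.argmax(ratios))
        if ratios[best] > ratio_min:
            report.selected_rank_rss = ranks[best + 1]
    return report


def cophenetic_rank_selection(
    V: FeatureMatrix | np.ndarray,
    ranks: list[int],
    n_runs: int = 30,
    n_subsample: int = 10000,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> RankReport:
    """Consensus-clustering stability of each rank (cophenetic coefficient).

    For each rank, ``n_runs`` fits from distinct seeds each assign every
    sample to its largest-coefficient basis (lowest index on ties); the
    M x M consensus matrix holds the fraction of runs in which two samples
    co-cluster.  The cophenetic correlation compares the 1 - consensus
    distances with the cophenetic distances of their average-linkage
    dendrogram; a perfectly reproducible clustering scores 1.  Selected
    rank = argmax, smallest rank on ties.
    """
    if n_runs < 2:
        raise InvalidArgumentError("n_runs must be >= 2")
    arr = _as_matrix(V)
    ranks = sorted(ranks)
    rng = np.random.default_rng(seed)
    sub = _subsample_columns(arr, n_subsample, rng)
    m = sub.shape[1]
    report = RankReport(
        ranks=tuple(ranks), n_subsample=m, n_runs=n_runs, seed=seed
    )
    for L in ranks:
        consensus = np.zeros((m, m))
        for run in range(n_runs):
            run_seed = int((seed * 1_000_003 + L * 1009 + run) % 2**31)
            model = nmf_fit(sub, L, seed=run_seed, max_iter=max_iter, tol=tol)
            labels = np.argmax(model.H, axis=0)
            used = np.unique(labels)
            if used.size < L:
                warnings.warn(
                    f"rank {L}, run {run}: {L - used.size} basis column(s) "
                    "attracted no samples",
                    stacklevel=2,
                )
            consensus += labels[:, None] == labels[None, :]
        consensus /= n_runs
        dist = squareform(1.0 - consensus, checks=False)
        if np.ptp(dist) < 1e-12:
            # all samples always co-cluster (or never): perfectly stable
            report.cophenetic[L] = 1.0
            continue
        Z = linkage(dist, method="average")
        coeff, _ = cophenet(Z, dist)
        report.cophenetic[L] = float(coeff)
    best = max(report.cophenetic, key=lambda L: (report.cophenetic[L], -L))
    report.selected_rank_cophenetic = int(best)
    return report


def transform(
    model: FactorModel,
    V_new: FeatureMatrix | np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> np.ndarray:
    """Project new columns onto the fitted basis (H-only multiplicative NNLS).

    Returns the non-negative score matrix H_new (L x M_new) minimizing
    ||V_new - W H_new|| with W fixed.
    """
    arr = _as_matrix(V_new)
    if arr.shape[0] != model.W.shape[0]:
        raise InvalidArgumentError(
            f"V_new has {arr.shape[0]} rows, basis expects {model.W.shape[0]}"
        )
    w = model.W
    h = np.maximum(w.T @ arr, _EPS)
    wtw = w.T @ w
    wtv = w.T @ arr
    obj = np.linalg.norm(arr - w @ h)
    for _ in range(max_iter):
        h *= wtv / (wtw @ h + _EPS)
        new_obj = np.linalg.norm(arr - w @ h)
        if abs(obj - new_obj) <= tol * max(obj, _EPS):
            break
        obj = new_obj
    return h
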