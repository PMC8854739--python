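"""Degree-1 persistent homology of Cα point clouds with volume-optimal cycles.

The filtration is the alpha filtration: simplices of the Delaunay complex of
the point cloud enter at the smallest ball radius r (Angstrom, *radii*, not
squared radii) at which they belong to the alpha complex.  Growing r from 0
to infinity, every 1-dimensional cycle (loop) appears at some birth radius b
and is filled in at a death radius d; the pair (b, d) together with a
representative loop C characterizes the feature.  The representative used
here is the *volume-optimal cycle*: the boundary of a minimal set of
triangles filling the hole, which localizes the loop on specific residue
pairs and so distinguishes structurally different loops with similar (b, d).

Degenerate inputs: point clouds of affine rank 2 (e.g. a planar polygon used
as an analytic test case) are projected onto their best-fit plane and
triangulated in 2D; collinear clouds are rejected.  A deterministic seeded
jitter of 1e-9 A breaks exact cosphericity before triangulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.spatial import Delaunay, QhullError

from .errors import DegenerateInputError, SolverError
from .structures import PointCloud, as_point_cloud

__all__ = [
    "Filtration",
    "PersistencePair",
    "PH1Diagram",
    "PersistentCycle",
    "build_alpha_filtration",
    "compute_ph1",
    "volume_optimal_cycle",
    "diagram_for_snapshot",
]

_JITTER_SCALE = 1e-9  # Angstrom; breaks exact degeneracies, below any physical scale
_GABRIEL_TOL = 1e-12


# ---------------------------------------------------------------------------
# filtration construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Filtration:
    """Alpha filtration of one point cloud.

    Simplices are tuples of sorted 0-based residue indices; values are the
    entry radii in Angstrom.  ``ambient_rank`` is 3 for generic clouds and 2
    for planar ones (triangulated in their best-fit plane; ``tetrahedra`` is
    then empty).
    """

    n_points: int
    ambient_rank: int
    edges: tuple[tuple[int, int], ...]
    edge_values: np.ndarray
    triangles: tuple[tuple[int, int, int], ...]
    triangle_values: np.ndarray
    tetrahedra: tuple[tuple[int, int, int, int], ...]
    tetrahedron_values: np.ndarray
    jitter_seed: int

    def edge_value(self, edge: tuple[int, int]) -> float:
        return float(self.edge_values[self._edge_index[edge]])

    @property
    def _edge_index(self) -> dict[tuple[int, int], int]:
        idx = getattr(self, "_edge_index_cache", None)
        if idx is None:
            idx = {e: i for i, e in enumerate(self.edges)}
            object.__setattr__(self, "_edge_index_cache", idx)
        return idx

    def check_face_ordering(self, tol: float = 1e-9) -> None:
        """Assert that every face enters no later than each of its cofaces."""
        ev = self._edge_index
        tv = {t: v for t, v in zip(self.triangles, self.triangle_values)}
        for tri, val in tv.items():
            for e in _faces(tri):
                if self.edge_values[ev[e]] > val + tol:
                    raise AssertionError(f"edge {e} enters after triangle {tri}")
        for tet, val in zip(self.tetrahedra, self.tetrahedron_values):
            for t in _faces(tet):
                if tv[t] > val + tol:
                    raise AssertionError(f"triangle {t} enters after tetrahedron {tet}")


def _faces(simplex: tuple[int, ...]) -> list[tuple[int, ...]]:
    k = len(simplex)
    return [tuple(simplex[:i] + simplex[i + 1 :]) for i in range(k)]


def _circumsphere(points: np.ndarray) -> float:
    """Radius of the smallest sphere through all rows of ``points``.

    For a k-simplex this is the circumradius of its vertices within their
    affine hull (half the length for an edge, the circumcircle radius for a
    triangle, the circumsphere radius for a tetrahedron).
    """
    _, r = _circumcenter_radius(points)
    return r


def _circumcenter_radius(points: np.ndarray) -> tuple[np.ndarray, float]:
    p0 = points[0]
    a = points[1:] - p0
    gram = 2.0 * (a @ a.T)
    rhs = np.einsum("ij,ij->i", a, a)
    # lstsq instead of solve: a sliver simplex has a near-singular system and
    # a correspondingly enormous circumradius, which is the right limit here
    y = np.linalg.lstsq(gram, rhs, rcond=None)[0]
    center_rel = a.T @ y
    if not np.all(np.isfinite(center_rel)):
        raise DegenerateInputError("degenerate simplex in triangulation")
    return p0 + center_rel, float(np.linalg.norm(center_rel))


def build_alpha_filtration(
    cloud: PointCloud | np.ndarray, jitter_seed: int = 0
) -> Filtration:
    """Alpha filtration of the Delaunay complex of a Cα point cloud.

    A simplex's filtration value is the smallest ball radius at which it
    belongs to the alpha complex: its circumradius if its circumball is empty
    of other points (Gabriel), otherwise the smallest value among its
    cofaces.  Values are computed top-down from the maximal simplices, which
    makes the face-ordering invariant hold by construction.
    """
    cloud = as_point_cloud(cloud)
    pts = np.asarray(cloud.coords, dtype=float)
    n = pts.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {n}")

    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = max(float(svals[0]), 1.0)
    rank = int(np.sum(svals > 1e-7 * scale))
    if rank < 2:
        raise DegenerateInputError("points are collinear; no 1-cycles can exist")

    rng = np.random.default_rng(jitter_seed)
    if rank == 2 or n == 3:
        # planar cloud: triangulate in the best-fit plane
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        work = centered @ vt[:2].T
        work = work + rng.normal(scale=_JITTER_SCALE, size=work.shape)
        ambient_rank = 2
    else:
        work = pts + rng.normal(scale=_JITTER_SCALE, size=pts.shape)
        ambient_rank = 3

    try:
        tri = Delaunay(work)
    except QhullError as exc:
        raise DegenerateInputError(f"Delaunay triangulation failed: {exc}") from exc

    tops = [tuple(int(v) for v in sorted(s)) for s in tri.simplices]

    # enumerate faces and coface links
    by_dim: dict[int, dict[tuple[int, ...], float]] = {1: {}, 2: {}}
    cofaces: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
    top_dim = ambient_rank
    by_dim[top_dim] = {}
    for s in tops:
        by_dim[top_dim].setdefault(s, -1.0)
    for dim in range(top_dim, 1, -1):
        for s in by_dim[dim]:
            for f in _faces(s):
                by_dim[dim - 1].setdefault(f, -1.0)
                cofaces.setdefault(f, []).append(s)

    # top simplices enter at their circumradius
    for s in by_dim[top_dim]:
        by_dim[top_dim][s] = _circumsphere(work[list(s)])

    # lower simplices: circumradius if Gabriel, else min over coface values
    for dim in range(top_dim - 1, 0, -1):
        for s in by_dim[dim]:
            center, r = _circumcenter_radius(work[list(s)])
            d2 = np.einsum("ij,ij->i", work - center, work - center)
            d2[list(s)] = np.inf
            if np.min(d2) > r * r - _GABRIEL_TOL:
                by_dim[dim][s] = r
            else:
                by_dim[dim][s] = min(by_dim[dim + 1][c] for c in cofaces[s])

    edges = tuple(sorted(by_dim[1]))
    triangles = tuple(sorted(by_dim[2]))
    tetrahedra = tuple(sorted(by_dim.get(3, {}))) if top_dim == 3 else ()
    return Filtration(
        n_points=n,
        ambient_rank=ambient_rank,
        edges=edges,
        edge_values=np.array([by_dim[1][e] for e in edges]),
        triangles=triangles,
        triangle_values=np.array([by_dim[2][t] for t in triangles]),
        tetrahedra=tetrahedra,
        tetrahedron_values=np.array(
            [by_dim[3][t] for t in tetrahedra] if tetrahedra else []
        ),
        jitter_seed=jitter_seed,
    )


# ---------------------------------------------------------------------------
# persistence of degree 1
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PersistencePair:
    birth: float
    death: float
    birth_edge: tuple[int, int]
    death_triangle: tuple[int, int, int]

    @property
    def lifetime(self) -> float:
        return self.death - self.birth


@dataclass(frozen=True)
class PH1Diagram:
    """Finite degree-1 pairs plus any infinite-persistence class births."""

    pairs: tuple[PersistencePair, ...]
    infinite_births: tuple[tuple[float, tuple[int, int]], ...] = ()

    def __iter__(self) -> Iterator[PersistencePair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i: int) -> PersistencePair:
        return self.pairs[i]


def _filtration_order(
    simplices: Sequence[tuple[int, ...]], values: np.ndarray
) -> list[int]:
    """Indices sorted by (value, vertex tuple); ties resolved reproducibly."""
    return sorted(range(len(simplices)), key=lambda i: (values[i], simplices[i]))


def compute_ph1(filtration: Filtration) -> PH1Diagram:
    """Degree-1 persistence pairs by Z2 boundary-matrix reduction.

    Triangle columns (in filtration order, over edge rows in filtration
    order) are reduced with a pivot lookup; each surviving pivot pairs the
    creating edge (birth) with the killing triangle (death).  Zero-lifetime
    pairs (b == d) are discarded.  Edges that create a 1-cycle but are never
    paired are returned as infinite-persistence births; a full Delaunay
    complex is contractible, so none are expected here.
    """
    edges, evals = filtration.edges, filtration.edge_values
    tris, tvals = filtration.triangles, filtration.triangle_values

    edge_order = _filtration_order(edges, evals)
    edge_rank = {edges[i]: r for r, i in enumerate(edge_order)}
    tri_order = _filtration_order(tris, tvals)

    # columns as python-int bitmasks over edge ranks; pivot = highest set bit
    pivot_owner: dict[int, int] = {}  # edge rank -> reduced column (bitmask)
    pivot_tri: dict[int, int] = {}  # edge rank -> triangle index
    pairs: list[PersistencePair] = []
    for ti in tri_order:
        col = 0
        for e in _faces(tris[ti]):
            col ^= 1 << edge_rank[e]
        while col:
            low = col.bit_length() - 1
            other = pivot_owner.get(low)
            if other is None:
                break
            col ^= other
        if col:
            low = col.bit_length() - 1
            pivot_owner[low] = col
            pivot_tri[low] = ti
            b_edge = edges[edge_order[low]]
            b, d = float(evals[edge_order[low]]), float(tvals[ti])
            if d > b:
                pairs.append(PersistencePair(b, d, b_edge, tris[ti]))

    # creator edges (those not killing a connected component) never paired
    # with a triangle carry infinite persistence
    vert_pivot: dict[int, int] = {}
    killer_edges: set[int] = set()
    for r, i in enumerate(edge_order):
        col = (1 << edges[i][0]) | (1 << edges[i][1])
        while col:
            low = col.bit_length() - 1
            other = vert_pivot.get(low)
            if other is None:
                break
            col ^= other
        if col:
            vert_pivot[col.bit_length() - 1] = col
            killer_edges.add(r)
    infinite = tuple(
        (float(evals[edge_order[r]]), edges[edge_order[r]])
        for r in range(len(edges))
        if r not in killer_edges and r not in pivot_owner
    )

    pairs.sort(key=lambda p: (p.birth, p.death, p.birth_edge))
    return PH1Diagram(pairs=tuple(pairs), infinite_births=infinite)


# ---------------------------------------------------------------------------
# volume-optimal cycles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PersistentCycle:
    """One degree-1 feature: birth, death and its volume-optimal cycle.

    ``cycle`` is the Z2 boundary of a minimal triangle set filling the hole,
    as a frozenset of 0-based residue-index pairs (i, j), i < j.
    """

    birth: float
    death: float
    cycle: frozenset[tuple[int, int]]
    optimal_volume_size: int

    @property
    def lifetime(self) -> float:
        return self.death - self.birth


def _validate_cycle(
    edges: frozenset[tuple[int, int]], filtration: Filtration, birth: float
) -> None:
    degree: dict[int, int] = {}
    for i, j in edges:
        degree[i] = degree.get(i, 0) + 1
        degree[j] = degree.get(j, 0) + 1
    if any(d % 2 for d in degree.values()):
        raise SolverError("optimal-volume boundary is not a Z2 cycle")
    for e in edges:
        if filtration.edge_value(e) > birth + 1e-9:
            raise SolverError(f"cycle edge {e} enters after the birth radius")


def volume_optimal_cycle(
    filtration: Filtration,
    pair: PersistencePair,
    exhaustive_limit: int = 18,
) -> PersistentCycle:
    """Minimal triangle set filling the hole of one persistence pair.

    Finds a set Omega of triangles of minimal cardinality such that the
    death triangle belongs to Omega, every member enters at radius <= d, and
    the Z2 boundary of Omega uses only edges that exist at the birth radius
    b.  Returns that boundary C and |Omega|.  Triangles with value <= b can
    only touch already-allowed edges, so restricting candidates to values in
    (b, d] loses no optimum.

    The search is exact throughout: a provable single-triangle shortcut,
    exhaustive ascending-cardinality search when at most ``exhaustive_limit``
    candidates exist, and otherwise 0/1 integer programming (HiGHS) with Z2
    edge-parity encoded through even-slack variables.  Ties in |Omega| are
    broken by the lexicographically smallest tuple of candidate ranks, where
    candidates are ranked by (value, vertex tuple); the tie-break is applied
    identically in both exact paths.
    """
    b, d = pair.birth, pair.death
    tris, tvals = filtration.triangles, filtration.triangle_values
    cand_idx = [i for i in range(len(tris)) if b < tvals[i] <= d]
    cand_idx.sort(key=lambda i: (tvals[i], tris[i]))
    try:
        death_pos = cand_idx.index(tris.index(pair.death_triangle))
    except ValueError as exc:
        raise SolverError("death triangle not among candidates") from exc

    # bitmask of *forbidden* edges (value > b) per candidate, plus full masks
    rel_edges: dict[tuple[int, int], int] = {}
    full_edges: dict[tuple[int, int], int] = {}
    forb_masks: list[int] = []
    full_masks: list[int] = []
    for i in cand_idx:
        fm = 0
        am = 0
        for e in _faces(tris[i]):
            bit_all = full_edges.setdefault(e, len(full_edges))
            am ^= 1 << bit_all
            if filtration.edge_value(e) > b + 1e-12:
                bit = rel_edges.setdefault(e, len(rel_edges))
                fm ^= 1 << bit
        forb_masks.append(fm)
        full_masks.append(am)

    death_forb = forb_masks[death_pos]
    if death_forb == 0:
        chosen = [death_pos]
    else:
        # a minimal volume never contains triangles outside the death
        # triangle's component of the forbidden-edge-sharing graph (any
        # disconnected cluster with even boundary could be dropped), so the
        # search space can be pruned before solving
        keep = _death_component(forb_masks, death_pos)
        sub_masks = [forb_masks[p] for p in keep]
        sub_death = keep.index(death_pos)
        if len(keep) <= exhaustive_limit:
            sub_chosen = _exhaustive_volume(sub_masks, sub_death)
        else:
            n_forb = max(m.bit_length() for m in sub_masks)
            sub_chosen = _milp_volume(sub_masks, sub_death, n_forb)
        chosen = [keep[p] for p in sub_chosen]

    boundary = 0
    for p in chosen:
        boundary ^= full_masks[p]
    inv_full = {v: k for k, v in full_edges.items()}
    cycle = frozenset(inv_full[bit] for bit in range(len(full_edges)) if boundary >> bit & 1)
    _validate_cycle(cycle, filtration, b)
    return PersistentCycle(
        birth=b, death=d, cycle=cycle, optimal_volume_size=len(chosen)
    )


def _death_component(forb_masks: list[int], death_pos: int) -> list[int]:
    """Candidates reachable from the death triangle via shared forbidden edges."""
    seen = {death_pos}
    frontier = [death_pos]
    while frontier:
        acc = 0
        for p in frontier:
            acc |= forb_masks[p]
        frontier = [
            p for p in range(len(forb_masks)) if p not in seen and forb_masks[p] & acc
        ]
        seen.update(frontier)
    return sorted(seen)


def _exhaustive_volume(forb_masks: list[int], death_pos: int) -> list[int]:
    """Ascending-cardinality exhaustive search; exact for small candidate sets."""
    others = [p for p in range(len(forb_masks)) if p != death_pos]
    target = forb_masks[death_pos]
    for extra in range(0, len(others) + 1):
        best: tuple[int, ...] | None = None
        for combo in itertools.combinations(others, extra):
            acc = target
            for p in combo:
                acc ^= forb_masks[p]
            if acc == 0:
                key = tuple(sorted((death_pos, *combo)))
                if best is None or key < best:
                    best = key
        if best is not None:
            return list(best)
    raise SolverError("no triangle set fills the hole (infeasible pair)")


def _milp_volume(forb_masks: list[int], death_pos: int, n_forb: int) -> list[int]:
    """Exact 0/1 program: min |Omega| s.t. forbidden-edge parity is even."""
    n_t = len(forb_masks)
    rows = np.zeros((n_forb, n_t + n_forb))
    for p, mask in enumerate(forb_masks):
        for bit in range(n_forb):
            if mask >> bit & 1:
                rows[bit, p] = 1.0
    rows[:, n_t:] = -2.0 * np.eye(n_forb)
    # unit cost plus a sub-unit rank perturbation for a deterministic tie-break
    eta = 1.0 / (2.0 * n_t * n_t + 2.0)
    cost = np.concatenate([1.0 + eta * np.arange(n_t), np.zeros(n_forb)])
    lb = np.zeros(n_t + n_forb)
    ub = np.concatenate([np.ones(n_t), np.full(n_forb, n_t // 2 + 1.0)])
    lb[death_pos] = 1.0
    res = milp(
        cost,
        constraints=LinearConstraint(rows, 0.0, 0.0),
        integrality=np.ones(n_t + n_forb),
        bounds=Bounds(lb, ub),
    )
    if res.status != 0 or res.x is None:
        raise SolverError(f"volume optimization failed: {res.message}")
    return [p for p in range(n_t) if res.x[p] > 0.5]


def diagram_for_snapshot(
    cloud: PointCloud | np.ndarray,
    jitter_seed: int = 0,
    max_birth: float | None = None,
) -> list[PersistentCycle]:
    """All degree-1 features of one snapshot with volume-optimal cycles.

    Composition of :func:`build_alpha_filtration`, :func:`compute_ph1` and
    :func:`volume_optimal_cycle`; deterministic given ``jitter_seed``.

    ``max_birth`` (Å), when set, discards pairs born at larger radii.  A
    loop whose shortest closing edges exceed tens of Å spans empty space
    around a near-degenerate (e.g. almost straight) conformation rather
    than molecular structure; such boundary artifacts can carry enormous
    lifetimes and would otherwise dominate every downstream weight.
    """
    filtration = build_alpha_filtration(cloud, jitter_seed=jitter_seed)
    diagram = compute_ph1(filtration)
    pairs = [
        p for p in diagram if max_birth is None or p.birth <= max_birth
    ]
    cycles = [volume_optimal_cycle(filtration, pair) for pair in pairs]
    cycles.sort(key=lambda c: (c.birth, c.death, sorted(c.cycle)))
    return cycles
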