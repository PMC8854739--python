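"""Independent brute-force oracles used only by the tests.

These deliberately share no code path with the production implementations:
persistence comes from a single full boundary-matrix reduction without
pivot lookups or clearing, the optimal volume from exhaustive subset
enumeration over ALL candidate triangles, and the superposition RMSD from
direct numeric minimization over rotation space.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tdafold.homology import Filtration


def naive_ph1_pairs(filtration: Filtration) -> list[tuple[float, float]]:
    """Degree-1 (b, d) pairs by plain left-to-right full-matrix reduction."""
    simplices: list[tuple[tuple[int, ...], float]] = []
    for v in range(filtration.n_points):
        simplices.append(((v,), 0.0))
    for e, val in zip(filtration.edges, filtration.edge_values):
        simplices.append((e, float(val)))
    for t, val in zip(filtration.triangles, filtration.triangle_values):
        simplices.append((t, float(val)))
    for s, val in zip(filtration.tetrahedra, filtration.tetrahedron_values):
        simplices.append((s, float(val)))
    simplices.sort(key=lambda sv: (sv[1], len(sv[0]), sv[0]))
    index = {s: i for i, (s, _) in enumerate(simplices)}

    columns: list[set[int]] = []
    for s, _ in simplices:
        if len(s) == 1:
            columns.append(set())
        else:
            faces = [tuple(s[:i] + s[i + 1 :]) for i in range(len(s))]
            columns.append({index[f] for f in faces})

    lows: dict[int, int] = {}
    pairs = []
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            if low not in lows:
                break
            col ^= columns[lows[low]]
        if col:
            low = max(col)
            lows[low] = j
            if len(simplices[low][0]) == 2:  # an edge row: a 1-cycle dies here
                b = simplices[low][1]
                d = simplices[j][1]
                if d > b:
                    pairs.append((b, d))
    return sorted(pairs)


def exhaustive_volume(
    filtration: Filtration, pair
) -> tuple[int, frozenset[tuple[int, int]]]:
    """Minimum triangle count filling a pair's hole, by subset enumeration."""
    b, d = pair.birth, pair.death
    tris = [
        t
        for t, v in zip(filtration.triangles, filtration.triangle_values)
        if b < v <= d
    ]
    death = pair.death_triangle
    others = [t for t in tris if t != death]

    def boundary(subset):
        edges: set[tuple[int, int]] = set()
        for t in subset:
            for i in range(3):
                e = tuple(sorted(t[:i] + t[i + 1 :]))
                edges ^= {e}
        return edges

    for extra in range(len(others) + 1):
        for combo in itertools.combinations(others, extra):
            subset = (death, *combo)
            bd = boundary(subset)
            if all(filtration.edge_value(e) <= b + 1e-9 for e in bd):
                return len(subset), frozenset(bd)
    raise AssertionError("no filling found; invalid pair")


def rmsd_by_minimization(P: np.ndarray, Q: np.ndarray, n_starts: int = 24) -> float:
    """Superposition RMSD by numeric minimization over rotation vectors."""
    p = P - P.mean(axis=0)
    q = Q - Q.mean(axis=0)

    def cost(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((p @ rot.T - q) ** 2).sum() / len(p))

    rng = np.random.default_rng(0)
    best = np.inf
    starts = [np.zeros(3)] + [
        rng.uniform(-np.pi, np.pi, 3) for _ in range(n_starts - 1)
    ]
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)
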