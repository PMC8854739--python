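import math

import numpy as np
import pytest

from tdafold.errors import DegenerateInputError
from tdafold.homology import (
    build_alpha_filtration,
    compute_ph1,
    diagram_for_snapshot,
    volume_optimal_cycle,
)

from _oracles import exhaustive_volume, naive_ph1_pairs

EQUILATERAL = np.array([[0.0, 0, 0], [2, 0, 0], [1, math.sqrt(3), 0]])

# six planar points reproducing the schematic in which a quadrilateral hole
# can be filled by two triangles or, through an extra outside vertex, three
SIX_POINT = np.array(
    [
        [-2.0, -1.6, 0.0],
        [0.0, 0.0, 0.0],
        [3.1, 0.2, 0.0],
        [4.6, 1.9, 0.0],
        [3.0, 3.4, 0.0],
        [-0.2, 3.2, 0.0],
    ]
)


class TestAlphaFiltration:
    def test_regular_tetrahedron_edges_enter_at_half_length(self):
        pts = np.array([[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
        edge = 2 * math.sqrt(2)
        filtration = build_alpha_filtration(pts)
        assert np.allclose(filtration.edge_values, edge / 2, atol=1e-6)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateInputError):
            build_alpha_filtration(line)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            build_alpha_filtration(np.array([[0.0, 0, 0], [1, 0, 0]]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_face_ordering_invariant(self, seed):
        pts = np.random.default_rng(seed).normal(scale=4.0, size=(20, 3))
        build_alpha_filtration(pts).check_face_ordering()


class TestComputePH1:
    def test_equilateral_triangle_single_pair(self):
        diagram = compute_ph1(build_alpha_filtration(EQUILATERAL))
        assert len(diagram) == 1
        pair = diagram[0]
        assert pair.birth == pytest.approx(1.0, abs=1e-6)
        assert pair.death == pytest.approx(2 / math.sqrt(3), abs=1e-6)

    def test_two_distant_triangles_two_pairs(self):
        pts = np.vstack([EQUILATERAL, EQUILATERAL + [100.0, 0, 0]])
        diagram = compute_ph1(build_alpha_filtration(pts))
        assert len(diagram) == 2
        for pair in diagram:
            assert pair.birth == pytest.approx(1.0, abs=1e-6)
            assert pair.death == pytest.approx(2 / math.sqrt(3), abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_reduction_oracle(self, seed):
        pts = np.random.default_rng(seed).normal(scale=3.0, size=(8, 3))
        filtration = build_alpha_filtration(pts)
        ours = sorted((p.birth, p.death) for p in compute_ph1(filtration))
        oracle = naive_ph1_pairs(filtration)
        assert len(ours) == len(oracle)
        assert np.allclose(np.array(ours), np.array(oracle), atol=1e-12)

    def test_no_infinite_classes_in_full_complex(self):
        pts = np.random.default_rng(5).normal(scale=3.0, size=(15, 3))
        diagram = compute_ph1(build_alpha_filtration(pts))
        assert diagram.infinite_births == ()

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(scale=3.0, size=(12, 3))
        perm = rng.permutation(12)
        d1 = sorted((p.birth, p.death) for p in compute_ph1(build_alpha_filtration(pts)))
        d2 = sorted(
            (p.birth, p.death) for p in compute_ph1(build_alpha_filtration(pts[perm]))
        )
        assert np.allclose(np.array(d1), np.array(d2), atol=1e-7)


class TestVolumeOptimalCycle:
    def test_single_triangle_hole(self):
        filtration = build_alpha_filtration(EQUILATERAL)
        (pair,) = compute_ph1(filtration).pairs
        cycle = volume_optimal_cycle(filtration, pair)
        assert cycle.optimal_volume_size == 1
        assert cycle.cycle == frozenset({(0, 1), (0, 2), (1, 2)})

    def test_pentagon_boundary_matches_exhaustive_search(self):
        ang = np.array([0.1, 1.4, 2.6, 3.9, 5.2])
        pent = np.column_stack([3 * np.cos(ang), 3 * np.sin(ang), np.zeros(5)])
        filtration = build_alpha_filtration(pent)
        diagram = compute_ph1(filtration)
        pair = max(diagram, key=lambda p: p.lifetime)
        cycle = volume_optimal_cycle(filtration, pair)
        n_oracle, boundary_oracle = exhaustive_volume(filtration, pair)
        assert cycle.optimal_volume_size == n_oracle == 3
        assert cycle.cycle == boundary_oracle

    def test_six_point_hole_filled_by_two_triangles_not_three(self):
        filtration = build_alpha_filtration(SIX_POINT)
        diagram = compute_ph1(filtration)
        pair = max(diagram, key=lambda p: p.lifetime)
        cycle = volume_optimal_cycle(filtration, pair)
        assert cycle.optimal_volume_size == 2
        # the three-triangle alternative exists in the complex
        assert (2, 3, 4) in filtration.triangles

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search_on_random_clouds(self, seed):
        pts = np.random.default_rng(seed).normal(scale=3.0, size=(9, 3))
        filtration = build_alpha_filtration(pts)
        for pair in compute_ph1(filtration):
            n_candidates = int(
                np.sum(
                    (np.asarray(filtration.triangle_values) > pair.birth)
                    & (np.asarray(filtration.triangle_values) <= pair.death)
                )
            )
            if n_candidates > 20:
                continue
            cycle = volume_optimal_cycle(filtration, pair)
            n_oracle, _ = exhaustive_volume(filtration, pair)
            assert cycle.optimal_volume_size == n_oracle

    @pytest.mark.parametrize("seed", [0, 4])
    def test_cycles_are_valid_z2_cycles_at_birth(self, seed):
        pts = np.random.default_rng(seed).normal(scale=4.0, size=(25, 3))
        filtration = build_alpha_filtration(pts)
        for cyc in diagram_for_snapshot(pts, jitter_seed=seed):
            degree: dict[int, int] = {}
            for i, j in cyc.cycle:
                degree[i] = degree.get(i, 0) + 1
                degree[j] = degree.get(j, 0) + 1
            assert all(v % 2 == 0 for v in degree.values())
            for e in cyc.cycle:
                assert filtration.edge_value(e) <= cyc.birth + 1e-9


class TestDiagramForSnapshot:
    def test_near_line_coil_has_no_long_lived_cycles(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack(
            [np.arange(20) * 3.8, rng.normal(scale=0.3, size=20), rng.normal(scale=0.3, size=20)]
        )
        cycles = diagram_for_snapshot(pts)
        assert all(c.lifetime < 0.5 for c in cycles)

    def test_native_bundle_has_prominent_loops(self, native):
        cycles = diagram_for_snapshot(native)
        assert len(cycles) >= 1
        assert max(c.lifetime for c in cycles) > 0.3

    def test_deterministic_given_jitter_seed(self, native):
        c1 = diagram_for_snapshot(native, jitter_seed=9)
        c2 = diagram_for_snapshot(native, jitter_seed=9)
        assert [(a.birth, a.death, a.cycle) for a in c1] == [
            (a.birth, a.death, a.cycle) for a in c2
        ]

    def test_stability_under_small_perturbation(self, native):
        base = sorted((p.birth, p.death) for p in
                      compute_ph1(build_alpha_filtration(native)))
        rng = np.random.default_rng(1)
        pert = native.coords + rng.uniform(-1e-4, 1e-4, size=native.coords.shape)
        moved = sorted((p.birth, p.death) for p in
                       compute_ph1(build_alpha_filtration(pert)))
        # matched pairs move by O(epsilon); allow a generous numerical band
        assert len(base) == len(moved)
        assert np.allclose(np.array(base), np.array(moved), atol=1e-2)
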