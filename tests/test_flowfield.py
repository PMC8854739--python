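import numpy as np
import pandas as pd
import pytest

from tdafold.errors import InvalidArgumentError
from tdafold.flowfield import (
    ReducedTrajectory,
    bin_flow,
    classify_paths,
    density_histogram,
    ensemble_velocities,
    frame_velocities,
    velocity_histogram,
)


def rt(scores, tid="t"):
    return ReducedTrajectory(tid, np.asarray(scores, float))


class TestFrameVelocities:
    def test_finite_differences(self):
        points = frame_velocities(rt([[0, 0], [1, 0], [2, 0]]))
        assert len(points) == 2
        assert np.allclose(points[0][0], [0, 0]) and np.allclose(points[0][1], [1, 0])
        assert np.allclose(points[1][0], [1, 0]) and np.allclose(points[1][1], [1, 0])

    def test_constant_scores_zero_velocity(self):
        points = frame_velocities(rt([[2, 3]] * 5))
        assert all(np.allclose(v, 0) for _, v in points)

    def test_single_frame_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert frame_velocities(rt([[1, 1]])) == []

    def test_no_velocity_spans_trajectory_boundaries(self):
        ens = [rt(np.random.default_rng(0).random((7, 2)), "a"),
               rt(np.random.default_rng(1).random((4, 2)), "b")]
        points = ensemble_velocities(ens)
        assert len(points) == (7 - 1) + (4 - 1)


class TestBinFlow:
    def test_constant_drift_recovered_exactly(self):
        rng = np.random.default_rng(0)
        pos = rng.random((5000, 2)) * 10
        points = [(p, np.array([0.5, 0.0])) for p in pos]
        field = bin_flow(points, axes=(0, 1), bins_per_axis=5, min_count=10)
        reported = field.mean_velocity[~np.isnan(field.mean_velocity[..., 0])]
        assert reported.size > 0
        assert np.allclose(
            field.mean_velocity[field.counts > 10], [0.5, 0.0], atol=1e-9
        )

    def test_min_count_threshold_is_strict(self):
        # one cell with exactly 100 samples suppressed, one with 101 reported
        points = [(np.array([0.1, 0.1]), np.array([1.0, 0.0]))] * 100
        points += [(np.array([0.9, 0.9]), np.array([1.0, 0.0]))] * 101
        field = bin_flow(points, axes=(0, 1), bins_per_axis=2, min_count=100)
        assert np.isnan(field.mean_velocity[0, 0, 0])
        assert field.mean_velocity[1, 1, 0] == pytest.approx(1.0)

    def test_opposing_populations_average_to_zero(self):
        points = [(np.array([0.5, 0.5]), np.array([+1.0, 0.0]))] * 60
        points += [(np.array([0.5, 0.5]), np.array([-1.0, 0.0]))] * 60
        field = bin_flow(points, axes=(0, 1), bins_per_axis=2, min_count=10)
        cell = field.mean_velocity[~np.isnan(field.mean_velocity[..., 0])]
        assert np.allclose(cell, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_groupby_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.random((2000, 3)) * 4
        vel = rng.normal(size=(2000, 3))
        points = [(p, v) for p, v in zip(pos, vel)]
        field = bin_flow(points, axes=(0, 2), bins_per_axis=4, min_count=0)
        # brute-force pandas groupby average over the same digitization
        codes = []
        for k, ax in enumerate((0, 2)):
            e = field.bin_edges[k]
            c = np.clip(np.searchsorted(e, pos[:, ax], side="right") - 1, 0, 3)
            codes.append(c)
        df = pd.DataFrame({"i": codes[0], "j": codes[1],
                           "vx": vel[:, 0], "vz": vel[:, 2]})
        grouped = df.groupby(["i", "j"]).mean()
        for (i, j), row in grouped.iterrows():
            assert field.mean_velocity[i, j, 0] == pytest.approx(row["vx"], abs=1e-12)
            assert field.mean_velocity[i, j, 1] == pytest.approx(row["vz"], abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bin_flow([], axes=(0, 1))


class TestVelocityHistogram:
    def test_all_points_inside_conserves_mass(self):
        rng = np.random.default_rng(0)
        points = [(rng.random(2), rng.normal(size=2)) for _ in range(500)]
        hist, _, _ = velocity_histogram(
            points, axes=(0, 1), region=((-1, 2), (-1, 2)), bins=10
        )
        assert hist.sum() == 500

    def test_two_planted_velocity_modes_recovered(self):
        rng = np.random.default_rng(3)
        points = []
        for mode in (np.array([0.0, 0.0]), np.array([-13.0, 8.0])):
            for _ in range(400):
                points.append((rng.random(2), mode + rng.normal(scale=0.8, size=2)))
        hist, ex, ey = velocity_histogram(
            points, axes=(0, 1), region=((-1, 2), (-1, 2)), bins=24
        )
        # the two occupied regions should each contain a local maximum near
        # the planted mode, within one bin
        for mode in ((0.0, 0.0), (-13.0, 8.0)):
            ix = np.searchsorted(ex, mode[0]) - 1
            iy = np.searchsorted(ey, mode[1]) - 1
            window = hist[max(ix - 1, 0) : ix + 2, max(iy - 1, 0) : iy + 2]
            assert window.max() >= 0.5 * hist.max() or window.max() > 30

    def test_region_outside_data_is_empty_with_warning(self):
        points = [(np.zeros(2), np.zeros(2))] * 10
        with pytest.warns(UserWarning):
            hist, _, _ = velocity_histogram(
                points, axes=(0, 1), region=((5, 6), (5, 6))
            )
        assert hist.sum() == 0


class TestDensityHistogram:
    def test_counts_conserved(self):
        pos = np.random.default_rng(0).random((321, 3))
        counts, _ = density_histogram(pos, axes=(0, 1), bins=7)
        assert counts.sum() == 321

    def test_point_mass_occupies_single_cell(self):
        pos = np.tile([1.0, 2.0, 3.0], (50, 1))
        counts, _ = density_histogram(pos, axes=(0, 2), bins=5)
        assert (counts > 0).sum() == 1

    def test_uniform_points_near_uniform_counts(self):
        from scipy.stats import chisquare

        rng = np.random.default_rng(1)
        pos = rng.random((20000, 2))
        counts, _ = density_histogram(pos, axes=(0, 1), bins=4)
        assert chisquare(counts.ravel()).pvalue > 0.01


class TestClassifyPaths:
    def test_threshold_crossing_order_sets_label(self):
        early_first = rt([[0, 0], [5, 0], [5, 5]], "a")
        early_second = rt([[0, 0], [0, 5], [5, 5]], "b")
        df = classify_paths([early_first, early_second], 0, 1, threshold=1.0)
        assert list(df["label"]) == ["A", "B"]

    def test_never_crossing_is_unresolved(self):
        df = classify_paths([rt([[0.1, 0.1]] * 5, "flat")], 0, 1, threshold=1.0)
        assert df["label"].iloc[0] == "unresolved"

    def test_swapping_components_swaps_labels(self):
        trajs = [rt([[0, 0], [5, 0], [5, 5]], "a"), rt([[0, 0], [0, 5], [5, 5]], "b")]
        fwd = classify_paths(trajs, 0, 1, threshold=1.0)
        rev = classify_paths(trajs, 1, 0, threshold=1.0)
        swap = {"A": "B", "B": "A"}
        assert [swap[x] for x in fwd["label"]] == list(rev["label"])

    def test_positive_threshold_required(self):
        with pytest.raises(InvalidArgumentError):
            classify_paths([], 0, 1, threshold=0.0)
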