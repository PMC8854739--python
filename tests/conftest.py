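import numpy as np
import pytest

from tdafold.synthetic import (
    ChainSpec,
    make_native,
    plan_a,
    plan_b,
    simulate_folding_trajectory,
    simulate_nonfolding_trajectory,
)


@pytest.fixture(scope="session")
def native():
    return make_native(ChainSpec(), seed=0)


@pytest.fixture(scope="session")
def folding_traj(native):
    return simulate_folding_trajectory(native, plan_a(), n_frames=40, seed=1)


@pytest.fixture(scope="session")
def noiseless_traj(native):
    return simulate_folding_trajectory(
        native, plan_a(), n_frames=40, noise_sigma=0.0, seed=1
    )


@pytest.fixture(scope="session")
def small_ensemble(native):
    """20 folding (10 per plan) + 10 non-folding trajectories, short frames."""
    ens = [
        simulate_folding_trajectory(
            native,
            plan_a() if i % 2 == 0 else plan_b(),
            n_frames=25,
            seed=i,
            trajectory_id=f"fold_{i:02d}",
        )
        for i in range(20)
    ]
    ens += [
        simulate_nonfolding_trajectory(
            n_frames=15, seed=200 + i, native=native, trajectory_id=f"coil_{i:02d}"
        )
        for i in range(10)
    ]
    return ens


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
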