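import numpy as np
import pytest

import ventrl
from ventrl.reward_engine import RewardConfig
from ventrl.trajectory_builder import ActionGrid

# fixed hazard intercept close to the calibrated default: most tests do not
# exercise the mortality calibration itself, so they skip the pilot runs
H0_FIXED = -5.34


@pytest.fixture(scope="session")
def grid():
    return ActionGrid()


@pytest.fixture(scope="session")
def sim_config_small():
    return ventrl.SimConfig(n_patients=60, max_horizon=48, seed=11,
                            hazard_intercept=H0_FIXED, n_aux_features=4)


@pytest.fixture(scope="session")
def cohort(sim_config_small):
    return ventrl.simulate_cohort(sim_config_small)


@pytest.fixture(scope="session")
def trajectories(cohort):
    events, outcomes = cohort
    return ventrl.build_trajectories(events, outcomes)


@pytest.fixture(scope="session")
def normalized_split(trajectories):
    train, test = ventrl.split_train_test(trajectories, 0.7, seed=5)
    stats = ventrl.fit_normalization(train)
    return ventrl.normalize(train, stats), ventrl.normalize(test, stats), stats


@pytest.fixture(scope="session")
def behaviour_policy(normalized_split, grid):
    train, _, _ = normalized_split
    X = np.vstack([t.states for t in train])
    A = np.concatenate([t.actions for t in train])
    return ventrl.knn_behaviour_policy(X, A, k=25, alpha_s=0.5,
                                       n_actions=grid.n_actions)


@pytest.fixture(scope="session")
def trained_model(normalized_split):
    train, _, _ = normalized_split
    rc = RewardConfig()
    rewards = [ventrl.shape_trajectory_rewards(t, rc)[0] for t in train]
    spec = ventrl.QNetworkSpec(n_hidden_layers=3, width=32)
    cfg = ventrl.TrainConfig(n_updates=500, seed=3)
    return ventrl.train_q(train, rewards, spec, cfg, reward_version="v3")
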