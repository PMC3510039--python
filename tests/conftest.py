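import numpy as np
import pytest

import teamflux as tf


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic overflow scenario (seed-fixed)."""
    return tf.make_scenario()


@pytest.fixture(scope="session")
def team_traj(scenario):
    """Penalized run at the scenario default (Type 2, theta = 65)."""
    return tf.run_team(scenario.model, scenario.expression_ts, scenario.compendium,
                       scenario.od_series, scenario.media, scenario.config)


@pytest.fixture(scope="session")
def dfba_traj(scenario):
    """Growth-maximizing baseline on the same inputs."""
    return tf.run_dfba(scenario.model, scenario.od_series, scenario.media,
                       scenario.config)


@pytest.fixture(scope="session")
def sweep_coarse(scenario):
    """Theta sweep over 1..99 (step 1), Type 2."""
    return tf.sweep_thresholds(
        scenario.model, scenario.expression_ts, scenario.compendium,
        scenario.od_series, scenario.media, scenario.config,
        theta_grid=np.arange(1.0, 100.0))


@pytest.fixture(scope="session")
def sweep_fine(scenario):
    """The same sweep on a x2-refined grid (step 0.5)."""
    return tf.sweep_thresholds(
        scenario.model, scenario.expression_ts, scenario.compendium,
        scenario.od_series, scenario.media, scenario.config,
        theta_grid=np.arange(1.0, 99.5, 0.5))


def make_chain_model(penalized=False):
    """Minimal 3-reaction chain: EX_a <-> , T: a -> b, BM: 2 b -> (override-kept).

    The biomass reaction touches one metabolite, so an explicit exchange
    override pins the exchange set to EX_a.
    """
    S = np.array([
        [-1.0, -1.0, 0.0],   # a
        [0.0, 1.0, -2.0],    # b
    ])
    return tf.StoichiometricModel(
        metabolite_ids=["a", "b"],
        reaction_ids=["EX_a", "T", "BM"],
        S=S,
        lb0=np.array([-10.0, 0.0, 0.0]),
        ub0=np.array([10.0, 10.0, 10.0]),
        biomass_reaction=2,
        gpr={1: tf.parse_gpr("gT")} if penalized else {},
        exchange_override={"EX_a"},
    )


@pytest.fixture
def chain_model():
    return make_chain_model()
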