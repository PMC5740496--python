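import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from stressgrn import normalize as norm
from stressgrn import synthetic as syn

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    """Default 20-TF ground-truth network (five hubs, two delayed
    repressors, incoherent FFLs planted)."""
    return syn.make_ground_truth(syn.arabidopsis_config(), seed=11)


@pytest.fixture(scope="session")
def sim_config():
    return syn.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def wt_stress_counts(truth, sim_config):
    """Wild-type stress/control probe counts over the full time grid."""
    grid = sim_config.time_grid_h
    traj = {
        ("wt", "mannitol"): syn.simulate_dynamics(
            truth, stimulus=syn.Stimulus(), grid=grid),
        ("wt", "control"): syn.simulate_dynamics(truth, grid=grid),
    }
    return syn.simulate_nanostring(
        traj, syn.stress_design(sim_config), sim_config, seed=11)


@pytest.fixture(scope="session")
def wt_expr(wt_stress_counts):
    return norm.normalize_housekeeping(wt_stress_counts)


def make_three_node_ffl(w_xy=20.0, w_xz=0.8, w_yz=-0.9,
                        basal=1.0, decay=2.0, decay_y=0.2):
    """Hand-built incoherent feed-forward loop X→Y→Z ⊣, X→Z for
    dynamics tests.  The repressor Y turns over slowly (small decay), so
    the inhibitory arm engages with a lag — the ingredient that makes
    the loop produce a pulse at Z."""
    nodes = ["X", "Y", "Z"]
    adj = pd.DataFrame(0.0, index=nodes, columns=nodes)
    adj.loc["X", "Y"] = w_xy
    adj.loc["X", "Z"] = w_xz
    adj.loc["Y", "Z"] = w_yz
    return syn.GroundTruthNetwork(
        nodes=nodes, adjacency=adj,
        onset_delay=pd.Series(0.5, index=nodes),
        hub_flag=pd.Series([True, False, False], index=nodes),
        basal=pd.Series(basal, index=nodes),
        decay=pd.Series({"X": decay, "Y": decay_y, "Z": decay}),
        onset_group=pd.Series(1, index=nodes),
        max_lfc=pd.Series(6.0, index=nodes),
    )


@pytest.fixture
def ffl_network():
    return make_three_node_ffl()


def expression_from_values(values: pd.DataFrame,
                           meta: pd.DataFrame) -> norm.ExpressionTable:
    """Wrap a hand-built log2 value matrix as an ExpressionTable."""
    return norm.ExpressionTable(values=values, meta=meta,
                                size_factors=pd.Series(
                                    1.0, index=values.columns))
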