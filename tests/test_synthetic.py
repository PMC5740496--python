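"""Generator contracts: determinism, planted structure, noise moments."""

import numpy as np
import pandas as pd
import pytest

from stressgrn import synthetic as syn
from stressgrn.normalize import DEFAULT_HOUSEKEEPING


class TestGroundTruth:
    def test_incoherent_ffl_planted(self, truth):
        ffls = truth.incoherent_ffls()
        assert ffls, "default network must contain an incoherent FFL"
        for x, y, z in ffls:
            a = truth.adjacency
            assert np.sign(a.loc[x, z]) != \
                np.sign(a.loc[x, y]) * np.sign(a.loc[y, z])

    def test_hub_count_and_no_self_edges(self, truth):
        assert truth.hub_flag.sum() == 5
        assert (np.diag(truth.adjacency.values) == 0).all()

    def test_repressor_weights_negative_and_delayed(self, truth):
        for r in syn.DEFAULT_REPRESSORS:
            out = truth.adjacency.loc[r]
            assert (out[out != 0] < 0).all()
            # the inhibitory arm lags the fast activator hubs that
            # drive the feed-forward input
            fast_hub_delay = truth.onset_delay[
                [h for h in syn.DEFAULT_HUBS
                 if truth.onset_group[h] <= 2]]
            assert truth.onset_delay[r] > fast_hub_delay.max()

    def test_same_seed_identical(self):
        cfg = syn.arabidopsis_config()
        a = syn.make_ground_truth(cfg, 5)
        b = syn.make_ground_truth(cfg, 5)
        pd.testing.assert_frame_equal(a.adjacency, b.adjacency)
        pd.testing.assert_series_equal(a.onset_delay, b.onset_delay)

    def test_zero_repressors_all_coherent(self):
        cfg = syn.arabidopsis_config(repressors=(),
                                     require_incoherent_ffl=False)
        net = syn.make_ground_truth(cfg, 5)
        assert (net.adjacency.values >= 0).all()
        assert not net.incoherent_ffls()

    def test_impossible_motif_request(self):
        cfg = syn.arabidopsis_config(repressors=())
        with pytest.raises(syn.ConfigurationError):
            syn.make_ground_truth(cfg, 5)

    def test_config_validation(self):
        with pytest.raises(syn.ConfigurationError):
            syn.SimulationConfig(time_grid_h=(2.0, 1.0))
        with pytest.raises(syn.ConfigurationError):
            syn.SimulationConfig(n_repeats=1)
        with pytest.raises(syn.ConfigurationError):
            syn.SimulationConfig(stress_area_multiplier=2.5)


class TestDynamics:
    def test_unregulated_fixed_point(self, ffl_network):
        """A node with no regulators started at basal/decay stays there."""
        traj = syn.simulate_dynamics(ffl_network, grid=[0, 4])
        assert np.allclose(traj.values["X"],
                           ffl_network.steady_state["X"], rtol=1e-9)

    def test_step_response_closed_form(self):
        """Unregulated node under a delayed step of amplitude A follows
        basal/d + (A/d)(1 - exp(-d(t-lag)))."""
        cfg = syn.NetworkConfig(
            n_nodes=3, n_hubs=0, hub_out_prob=0, background_edge_prob=0,
            repressors=(), require_incoherent_ffl=False)
        net = syn.make_ground_truth(cfg, 1)
        traj = syn.simulate_dynamics(net, stimulus=syn.Stimulus(),
                                     grid=[0, 8])
        for node in net.nodes:
            d = net.decay[node]
            lag = net.onset_delay[node]
            amp = net.basal[node] * (2 ** net.max_lfc[node] - 1)
            t = traj.times
            expected = net.basal[node] / d + np.where(
                t >= lag, (amp / d) * (1 - np.exp(-d * np.maximum(t - lag, 0))),
                0.0)
            assert np.allclose(traj.values[node].values, expected, rtol=1e-3)

    def test_clamp_contract(self, ffl_network):
        clamp = syn.Perturbation("X", level=12.0)
        traj = syn.simulate_dynamics(ffl_network, perturbation=clamp,
                                     grid=[0, 6])
        assert np.allclose(traj.values["X"].values[1:], 12.0)

    def test_sampling_outside_span_errors(self, ffl_network):
        traj = syn.simulate_dynamics(ffl_network, grid=[0, 2])
        with pytest.raises(ValueError):
            traj.at(3.0)

    def test_onset_crossings_at_configured_times(self, truth):
        """Noiseless log2FC first exceeds 1 at the four onset times,
        recovering the four planted groups exactly."""
        grid = (0.33, 0.67, 1.0, 2.0, 4.0)
        fc = syn.noiseless_log2fc(truth, grid)
        for gene in truth.nodes:
            series = fc[gene]
            first = next(t for t in grid if series[t] > 1.0)
            expected = syn.ONSET_TIMES_H[truth.onset_group[gene] - 1]
            assert first == expected, gene


class TestNanostring:
    def test_nb_mean_matches_configured(self, ffl_network):
        """Zero-dispersion limit, unit size factors: the empirical mean
        of 10,000 draws matches the deterministic mean within 2%."""
        cfg = syn.SimulationConfig(seed=0, nb_dispersion=0.0,
                                   size_factor_log2_sd=0.0,
                                   batch_log2_sd=0.0)
        traj = {("wt", "control"):
                syn.simulate_dynamics(ffl_network, grid=[0, 1])}
        design = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(10_000)],
            "line": "wt", "treatment": "control", "time_h": 1.0,
            "repeat": 1,
        })
        table = syn.simulate_nanostring(traj, design, cfg, seed=3)
        mu = cfg.count_gain * traj[("wt", "control")].at(1.0)
        for node in ffl_network.nodes:
            emp = table.counts.loc[node].mean()
            assert abs(emp - mu[node]) / mu[node] < 0.02

    def test_housekeeping_condition_independent(self, wt_stress_counts):
        """Housekeeping expected counts do not depend on treatment:
        arm means differ only by sampling noise and shared factors."""
        meta = wt_stress_counts.meta
        hk = wt_stress_counts.counts.loc[list(DEFAULT_HOUSEKEEPING)]
        # compare size-factor-free construction: ratio of arm means per
        # repeat stays within NB noise of 1
        for rep in meta["repeat"].unique():
            m = meta[meta["repeat"] == rep]
            a = hk[m.index[m["treatment"] == "mannitol"]].mean(axis=1)
            b = hk[m.index[m["treatment"] == "control"]].mean(axis=1)
            assert np.allclose(np.log2(a / b), 0.0, atol=0.6)

    def test_identical_seed_identical_table(self, ffl_network):
        cfg = syn.SimulationConfig(seed=0)
        traj = {("wt", "control"):
                syn.simulate_dynamics(ffl_network, grid=[0, 1])}
        design = pd.DataFrame({"sample_id": ["a", "b"], "line": "wt",
                               "treatment": "control", "time_h": 1.0,
                               "repeat": [1, 2]})
        t1 = syn.simulate_nanostring(traj, design, cfg, seed=9)
        t2 = syn.simulate_nanostring(traj, design, cfg, seed=9)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)


class TestTEA:
    def test_zero_weight_mean_ratio_near_one(self, truth):
        # pick a non-edge
        a = truth.adjacency
        eff, prom = next((i, j) for i in truth.nodes for j in truth.nodes
                         if i != j and a.loc[i, j] == 0)
        cfg = syn.SimulationConfig(seed=0)
        means = []
        for s in range(30):
            ms = syn.simulate_tea(truth, (eff,), prom, 4, cfg, seed=s)
            eff_ms = [m for m in ms if m.effectors]
            ctl_ms = {m.experiment: m.activities.mean()
                      for m in ms if not m.effectors}
            ratios = [m.activities.mean() / ctl_ms[m.experiment]
                      for m in eff_ms]
            means.append(np.log2(np.mean(ratios)))
        assert abs(np.mean(means)) < 0.1

    def test_positive_weight_ratio_above_one(self, truth):
        a = truth.adjacency
        eff, prom = max(((i, j) for i in truth.nodes for j in truth.nodes
                         if a.loc[i, j] > 0), key=lambda e: a.loc[e])
        cfg = syn.SimulationConfig(seed=0)
        above = 0
        for s in range(100):
            ms = syn.simulate_tea(truth, (eff,), prom, 4, cfg, seed=s)
            ctl = {m.experiment: m.activities.mean()
                   for m in ms if not m.effectors}
            ratios = [m.activities.mean() / ctl[m.experiment]
                      for m in ms if m.effectors]
            above += np.mean(ratios) > 1
        assert above >= 95

    def test_emergent_pair_rule(self, truth):
        """Both singles configured to 0 weight, pair weight > 0: the
        singles stay near 1 and the pair construct activates."""
        a = truth.adjacency
        prom = "ERF6"
        nulls = [n for n in truth.nodes
                 if n != prom and a.loc[n, prom] == 0][:2]
        pair_w = {(frozenset(nulls), prom): 2.0}
        cfg = syn.SimulationConfig(seed=0)

        def mean_ratio(effectors, seed):
            ms = syn.simulate_tea(truth, effectors, prom, 4, cfg, seed,
                                  pair_weights=pair_w)
            ctl = {m.experiment: m.activities.mean()
                   for m in ms if not m.effectors}
            return np.mean([m.activities.mean() / ctl[m.experiment]
                            for m in ms if m.effectors])

        singles = [np.log2(mean_ratio((n,), s))
                   for n in nulls for s in range(10)]
        pairs = [np.log2(mean_ratio(tuple(nulls), s)) for s in range(10)]
        assert abs(np.mean(singles)) < 0.2
        assert np.mean(pairs) > 1.0

    def test_unknown_node_errors(self, truth):
        cfg = syn.SimulationConfig(seed=0)
        with pytest.raises(syn.ConfigurationError):
            syn.simulate_tea(truth, ("NOPE",), "ERF6", 4, cfg, 0)
        with pytest.raises(syn.ConfigurationError):
            syn.simulate_tea(truth, ("ERF6",), "NOPE", 4, cfg, 0)


class TestPhenotypes:
    def test_wild_type_stress_reduction_near_30pct(self):
        cfg = syn.SimulationConfig(seed=0)
        plants, _ = syn.simulate_phenotypes(cfg, {"wt": (1.0, 1.0)}, seed=2)
        wt = plants[plants["genotype"] == "wt"]
        red = 1 - wt[wt["treatment"] == "mannitol"]["rosette_mm2"].mean() \
            / wt[wt["treatment"] == "control"]["rosette_mm2"].mean()
        # 30 plants per arm, log2 sd 0.3 -> generous simulation CI
        assert 0.15 < red < 0.45

    def test_identical_multipliers_relative_reduction_one(self):
        from stressgrn.phenotype import relative_reduction
        cfg = syn.SimulationConfig(seed=0)
        rels = []
        for s in range(20):
            plants, _ = syn.simulate_phenotypes(
                cfg, {"wt": (1.0, 1.0), "twin": (1.0, 1.0)}, seed=s)
            rels.append(relative_reduction(
                plants[plants["genotype"] == "twin"],
                plants[plants["genotype"] == "wt"]))
        assert abs(np.mean(rels) - 1.0) < 0.15

    def test_zero_interaction_additive_construction(self):
        cfg = syn.SimulationConfig(
            seed=0, interaction_coefficients={("A", "B"): 0.0},
            n_plants_cross=40, area_log2_sd=0.05, repeat_log2_sd=0.0)
        _, crosses = syn.simulate_phenotypes(
            cfg, {"wt": (1.0, 1.0)}, seed=3,
            cross_effects={"A": -1.0, "B": -0.5})
        m = crosses.groupby(["p1", "p2"])["rosette_mm2"].apply(
            lambda s: np.log2(s).mean())
        dev = m[(1, 1)] - m[(1, 0)] - m[(0, 1)] + m[(0, 0)]
        se = 0.05 * 2 / np.sqrt(40 * 3)
        assert abs(dev) < 3 * se

    def test_missing_reference_genotype_errors(self):
        cfg = syn.SimulationConfig(seed=0)
        with pytest.raises(syn.ConfigurationError):
            syn.simulate_phenotypes(cfg, {"mutant": (1.0, 1.0)}, seed=0)

    def test_leaf_areas_sum_to_rosette(self):
        cfg = syn.SimulationConfig(seed=0)
        plants, _ = syn.simulate_phenotypes(cfg, {"wt": (1.0, 1.0)}, seed=4)
        leaf_cols = [c for c in plants.columns if c.startswith("leaf_")]
        total = plants[leaf_cols].sum(axis=1)
        assert np.allclose(total, plants["rosette_mm2"], rtol=1e-9)
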