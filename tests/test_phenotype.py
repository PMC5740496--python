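"""Growth statistics, sensitivity normalization, additivity test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stressgrn import phenotype as phen
from stressgrn import synthetic as syn


def plants_from_means(means, n=8, sd=0.0, seed=0, repeats=(1,)):
    """Plant table with log2 means per (genotype, treatment)."""
    rng = np.random.default_rng(seed)
    rows = []
    for (geno, trt), mu in means.items():
        for rep in repeats:
            for i in range(n):
                rows.append({"genotype": geno, "treatment": trt,
                             "repeat": rep,
                             "rosette_mm2": 2.0 ** rng.normal(mu, sd)
                             if sd else 2.0 ** mu})
    return pd.DataFrame(rows)


def cross_table(mu_ref, a1, a2, gamma, n=8, sd=0.0, seed=0, repeats=(1, 2)):
    rng = np.random.default_rng(seed)
    rows = []
    for rep in repeats:
        for p1, p2, eff in ((0, 0, 0.0), (1, 0, a1), (0, 1, a2),
                            (1, 1, a1 + a2 + gamma)):
            for i in range(n):
                mu = mu_ref + eff
                rows.append({"genotype": f"c{p1}{p2}", "p1": p1, "p2": p2,
                             "repeat": rep,
                             "rosette_mm2": 2.0 ** rng.normal(mu, sd)
                             if sd else 2.0 ** mu})
    return pd.DataFrame(rows)


class TestRelativeReduction:
    def test_worked_example_sixty_vs_thirty(self):
        """Line reduction 60 %, wild type 30 % -> relative reduction 2."""
        wt = plants_from_means({("wt", "control"): np.log2(100),
                                ("wt", "mannitol"): np.log2(70)})
        line = plants_from_means({("m", "control"): np.log2(100),
                                  ("m", "mannitol"): np.log2(40)})
        assert np.isclose(phen.relative_reduction(line, wt), 2.0)

    def test_line_identical_to_wild_type_gives_one(self):
        wt = plants_from_means({("wt", "control"): np.log2(100),
                                ("wt", "mannitol"): np.log2(70)})
        assert np.isclose(phen.relative_reduction(wt, wt), 1.0)

    def test_milder_line(self):
        wt = plants_from_means({("wt", "control"): np.log2(100),
                                ("wt", "mannitol"): np.log2(70)})
        line = plants_from_means({("m", "control"): np.log2(100),
                                  ("m", "mannitol"): np.log2(79)})
        assert np.isclose(phen.relative_reduction(line, wt), 0.7)

    def test_rescaling_invariance(self):
        wt = plants_from_means({("wt", "control"): np.log2(100),
                                ("wt", "mannitol"): np.log2(70)})
        line = plants_from_means({("m", "control"): np.log2(50),
                                  ("m", "mannitol"): np.log2(20)})
        scaled = line.assign(rosette_mm2=line["rosette_mm2"] * 7.5)
        assert np.isclose(phen.relative_reduction(line, wt),
                          phen.relative_reduction(scaled, wt))

    def test_nonpositive_wild_type_reduction_errors(self):
        wt = plants_from_means({("wt", "control"): np.log2(70),
                                ("wt", "mannitol"): np.log2(100)})
        with pytest.raises(ValueError):
            phen.relative_reduction(wt, wt)


class TestRosetteGrowthTest:
    def test_balanced_noiseless_effect_exact(self):
        means = {("wt", "control"): np.log2(100),
                 ("wt", "mannitol"): np.log2(70),
                 ("m", "control"): np.log2(112),
                 ("m", "mannitol"): np.log2(78.4)}
        # tiny noise to keep the residual variance nonzero
        rec = plants_from_means(means, sd=1e-6, repeats=(1, 2))
        res = phen.rosette_growth_test(rec, "m")
        assert np.isclose(res["line_effect_control_pct"], 12.0, atol=1e-3)
        assert np.isclose(res["line_effect_stress_pct"], 12.0, atol=1e-3)

    def test_null_interaction_calibration(self):
        """Identical distributions: the genotype x treatment interaction
        is non-significant in >= 94% of 300 null runs at alpha 0.05."""
        means = {("wt", "control"): np.log2(100),
                 ("wt", "mannitol"): np.log2(70),
                 ("m", "control"): np.log2(100),
                 ("m", "mannitol"): np.log2(70)}
        hits = 0
        for s in range(300):
            rec = plants_from_means(means, n=10, sd=0.3, seed=s,
                                    repeats=(1, 2, 3))
            res = phen.rosette_growth_test(rec, "m")
            hits += res["interaction_p"] >= 0.05
        assert hits / 300 >= 0.94

    def test_power_for_12pct_effect(self):
        """+12% genotype effect, n = 10 x 3 repeats, default noise:
        positive estimate in >= 95% of seeded runs."""
        cfg = syn.SimulationConfig(seed=0)
        pos = 0
        n_runs = 60
        for s in range(n_runs):
            plants, _ = syn.simulate_phenotypes(
                cfg, {"wt": (1.0, 1.0), "erf8": (1.12, 1.12)}, seed=s)
            res = phen.rosette_growth_test(plants, "erf8")
            pos += res["line_effect_control_pct"] > 0
        assert pos / n_runs >= 0.95

    def test_tukey_p_within_bounds(self):
        rec = plants_from_means(
            {("wt", "control"): np.log2(100),
             ("wt", "mannitol"): np.log2(70),
             ("m", "control"): np.log2(90),
             ("m", "mannitol"): np.log2(60)}, sd=0.2, repeats=(1, 2))
        res = phen.rosette_growth_test(rec, "m")
        assert res["pairwise"]["p_tukey"].between(0, 1).all()
        assert len(res["pairwise"]) == 6

    def test_empty_cell_errors(self):
        rec = plants_from_means({("wt", "control"): 6.0,
                                 ("wt", "mannitol"): 6.0,
                                 ("m", "control"): 6.0})
        with pytest.raises(ValueError, match="mannitol"):
            phen.rosette_growth_test(rec, "m")


class TestLeafSeries:
    def leaf_records(self, effect_young=1.0, seed=0, n=8):
        cfg = syn.SimulationConfig(seed=0, n_plants=n)
        leaf_eff = None
        if effect_young != 1.0:
            leaf_eff = {"m": {8: effect_young, 9: effect_young,
                              10: effect_young}}
        plants, _ = syn.simulate_phenotypes(
            cfg, {"wt": (1.0, 1.0), "m": (1.0, 1.0)}, seed=seed,
            leaf_effects=leaf_eff)
        return plants

    def test_null_no_leaf_flagged_mostly(self):
        flagged = 0
        runs = 40
        for s in range(runs):
            rec = self.leaf_records(seed=s)
            out = phen.leaf_series_compare(rec, "m", n_mc=2000, seed=s,
                                           treatment="control")
            flagged += (out["p_adj"] < 0.05).any()
        assert flagged / runs <= 0.2

    def test_planted_young_leaf_effect_recovered(self):
        """Effect planted on the three youngest leaves: flagged leaves
        concentrate there (the young-leaf mutant pattern)."""
        ok = 0
        runs = 25
        for s in range(runs):
            rec = self.leaf_records(effect_young=0.55, seed=s)
            out = phen.leaf_series_compare(rec, "m", n_mc=2000, seed=s,
                                           treatment="control")
            hits = set(out[out["p_adj"] < 0.05]["leaf"])
            young = {"leaf_9_mm2", "leaf_10_mm2", "leaf_8_mm2"}
            ok += bool(hits) and hits <= young
        assert ok / runs >= 0.9

    def test_adjusted_p_at_least_raw(self):
        rec = self.leaf_records(effect_young=0.7, seed=1)
        out = phen.leaf_series_compare(rec, "m", n_mc=2000, seed=1)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestCellularDecomposition:
    def test_unit_arithmetic(self):
        cells = np.full(100, 1600.0)
        res = phen.cellular_decomposition(40.0, cells)
        assert np.isclose(res["cell_number"], 25_000)

    def test_identical_leaves_ratio_one(self):
        cells = np.full(50, 1200.0)
        cmp = phen.compare_cellular(cells, 30.0, cells, 30.0)
        assert np.isclose(cmp["cell_number_ratio"], 1.0)

    def test_halving_cell_area_doubles_number(self):
        cells = np.full(60, 1600.0)
        a = phen.cellular_decomposition(40.0, cells)
        b = phen.cellular_decomposition(40.0, cells / 2)
        assert np.isclose(b["cell_number"], 2 * a["cell_number"])

    def test_unit_mismatch_errors(self):
        with pytest.raises(ValueError, match="unit"):
            phen.cellular_decomposition(40.0, np.full(60, 1600.0),
                                        leaf_unit="mm2", cell_unit="mm4")

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError):
            phen.cellular_decomposition(40.0, np.full(10, 1600.0))


class TestInteractionTest:
    def test_exact_additivity_coefficient_zero(self):
        rec = cross_table(np.log2(100), -1.0, -0.5, 0.0, sd=1e-6)
        res = phen.interaction_test(rec)
        assert abs(res.coefficient) < 1e-4
        assert res.classification == "additive"

    def test_coefficient_equals_cell_mean_contrast(self):
        rec = cross_table(np.log2(100), -1.0, -0.5, 0.4, sd=0.2, seed=3)
        res = phen.interaction_test(rec)
        m = rec.groupby(["p1", "p2"])["rosette_mm2"].apply(
            lambda s: np.log2(s).mean())
        contrast = m[(1, 1)] - m[(1, 0)] - m[(0, 1)] + m[(0, 0)]
        assert np.isclose(res.coefficient, contrast, atol=1e-10)

    def test_positive_coefficient_recovery(self):
        """Planted +0.5 log2 interaction, n = 8 x 3 repeats: classified
        synergistic in >= 90% of runs, mean estimate within 3 SE."""
        cfg = syn.SimulationConfig(
            seed=0, interaction_coefficients={("A", "B"): 0.5})
        est, hits = [], 0
        runs = 100
        for s in range(runs):
            _, crosses = syn.simulate_phenotypes(
                cfg, {"wt": (1.0, 1.0)}, seed=s,
                cross_effects={"A": -1.0, "B": -0.5})
            res = phen.interaction_test(crosses)
            est.append(res.coefficient)
            hits += res.classification == "synergistic"
        se = np.std(est, ddof=1) / np.sqrt(runs)
        assert abs(np.mean(est) - 0.5) < 3 * se
        assert hits / runs >= 0.90

    def test_null_false_positive_rate(self):
        cfg = syn.SimulationConfig(
            seed=0, interaction_coefficients={("A", "B"): 0.0})
        fp = 0
        runs = 200
        for s in range(runs):
            _, crosses = syn.simulate_phenotypes(
                cfg, {"wt": (1.0, 1.0)}, seed=s,
                cross_effects={"A": -1.0, "B": -0.5})
            fp += phen.interaction_test(crosses).classification != "additive"
        assert fp / runs <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / runs)

    def test_missing_cell_errors(self):
        rec = cross_table(6.0, -1.0, -0.5, 0.0)
        rec = rec[~((rec["p1"] == 1) & (rec["p2"] == 1))]
        with pytest.raises(ValueError):
            phen.interaction_test(rec)


class TestExpectedDoubleReduction:
    def test_worked_example_half_half(self):
        assert phen.expected_double_reduction(0.5, 0.5) == 0.75

    def test_identity_element(self):
        assert phen.expected_double_reduction(0.0, 0.4) == 0.4

    def test_arithmetic(self):
        assert np.isclose(phen.expected_double_reduction(0.3, 0.6), 0.72)

    @given(st.floats(0, 0.99), st.floats(0, 0.99))
    def test_symmetric(self, r1, r2):
        assert np.isclose(phen.expected_double_reduction(r1, r2),
                          phen.expected_double_reduction(r2, r1))

    @given(st.floats(0, 0.9), st.floats(0, 0.9), st.floats(0, 0.09))
    def test_monotone(self, r1, r2, eps):
        assert phen.expected_double_reduction(r1 + eps, r2) >= \
            phen.expected_double_reduction(r1, r2)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            phen.expected_double_reduction(1.0, 0.5)
        with pytest.raises(ValueError):
            phen.expected_double_reduction(-0.1, 0.5)
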