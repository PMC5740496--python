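#!/usr/bin/env python
"""Generate the study's synthetic datasets with known ground truth.

Writes, under results/data/:
  ground_truth.json     signed 20-TF network, onset delays, hub flags
  wt_stress_counts.tsv  wild-type stress/control probe counts (3 repeats)
  gof_counts.tsv        inducible-overexpression screen counts
  phenotypes.tsv        per-plant rosette and leaf areas
  crosses.tsv           double/single-cross rosette areas
"""

from pathlib import Path

import numpy as np

from stressgrn import normalize as norm
from stressgrn import synthetic as syn

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sim = syn.SimulationConfig(seed=SEED)
    truth = syn.make_ground_truth(syn.arabidopsis_config(), SEED)
    truth.to_json(OUT / "ground_truth.json")
    print(f"ground truth: {len(truth.nodes)} TFs, "
          f"{len(truth.edges())} signed edges, "
          f"{int(truth.hub_flag.sum())} hubs, "
          f"{len(truth.incoherent_ffls())} incoherent FFLs")

    # wild-type stress time course
    grid = sim.time_grid_h
    traj = {
        ("wt", "mannitol"): syn.simulate_dynamics(
            truth, stimulus=syn.Stimulus(), grid=grid),
        ("wt", "control"): syn.simulate_dynamics(truth, grid=grid),
    }
    counts = syn.simulate_nanostring(traj, syn.stress_design(sim), sim, SEED)
    norm.write_count_table(counts, OUT / "wt_stress_counts.tsv")
    print(f"wild-type counts: {len(counts.genes)} probes x "
          f"{len(counts.samples)} samples")

    # GOF screen on the strong-weight recovery network
    from stressgrn.studies import strong_effect_config
    gof_truth = syn.make_ground_truth(strong_effect_config(), SEED)
    gof_truth.to_json(OUT / "gof_ground_truth.json")
    times = (1.0, 2.0, 4.0, 8.0, 24.0)
    gof_traj = {("GFP-GR", "dex"): syn.simulate_dynamics(gof_truth,
                                                         grid=times)}
    lines = [n + "-GR" for n in gof_truth.nodes]
    for ln in lines:
        reg = ln.removesuffix("-GR")
        clamp = syn.Perturbation(reg, 32 * gof_truth.steady_state[reg])
        gof_traj[(ln, "dex")] = syn.simulate_dynamics(
            gof_truth, perturbation=clamp, grid=times)
    gof_counts = syn.simulate_nanostring(
        gof_traj, syn.gof_design(sim, lines, times=times), sim, SEED + 1)
    norm.write_count_table(gof_counts, OUT / "gof_counts.tsv")
    print(f"GOF screen counts: {len(lines)} lines + control, "
          f"{len(gof_counts.samples)} samples")

    # phenotypes: wild type plus a panel of effect lines, and the
    # core-hub double crosses with planted interactions
    effects = {
        "wt": (1.0, 1.0),
        "erf8": (1.12, 1.12),          # larger rosette, wt-like sensitivity
        "wrky15": (1.0, 1.25),         # more tolerant (smaller reduction)
        "ERF9-GR": (0.70, 0.55),       # dwarfed and hypersensitive
    }
    gammas = {("ERF6-GR", "ERF8-GR"): 0.5,    # synergistic
              ("ERF59-GR", "ERF98-GR"): 0.0,  # additive
              ("ERF59-GR", "ERF9-GR"): -0.6}  # negative
    sim_ph = syn.SimulationConfig(seed=SEED,
                                  interaction_coefficients=gammas)
    plants, crosses = syn.simulate_phenotypes(
        sim_ph, effects, SEED,
        cross_effects={"ERF6-GR": -1.2, "ERF8-GR": -0.1, "ERF59-GR": 0.3,
                       "ERF98-GR": -0.25, "ERF9-GR": -0.9})
    plants.drop(columns=["cell_areas_um2"]).to_csv(
        OUT / "phenotypes.tsv", sep="\t", index=False)
    crosses.to_csv(OUT / "crosses.tsv", sep="\t", index=False)
    print(f"phenotypes: {len(plants)} plants over {len(effects)} genotypes; "
          f"{crosses['cross'].nunique()} double crosses")


if __name__ == "__main__":
    main()
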