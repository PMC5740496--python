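"""End-to-end simulation studies over the inference pipeline.

Each function generates data with the synthetic module, runs the
corresponding analysis layer, and scores the result against the
generator's ground truth.  They are the building blocks of the
analysis scripts and of the reproducibility checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kinetics as kin
from . import network as net
from . import normalize as norm
from . import phenotype as phen
from . import synthetic as syn
from . import tea


def onset_recovery(seed: int = 11) -> dict:
    """Noiseless kinetics → onset groups vs the planted groups."""
    truth = syn.make_ground_truth(syn.arabidopsis_config(), seed)
    grid = (0.33, 0.67, 1.0, 2.0, 4.0)
    fc = syn.noiseless_log2fc(truth, grid)
    rows = [{"gene": g, "time_h": t, "log2fc": fc.loc[t, g], "se": 0.0,
             "p": 0.0, "q": 0.0, "n_repeats": 3}
            for g in truth.nodes for t in grid]
    groups = kin.classify_onset(pd.DataFrame(rows))
    errors = sum(int(groups.loc[g, "group"] != truth.onset_group[g])
                 for g in truth.nodes)
    return {"n_genes": len(truth.nodes), "errors": errors,
            "groups": groups, "truth": truth.onset_group}


def strong_effect_config() -> syn.NetworkConfig:
    """Network configuration for the edge-recovery study: sparser than
    the default but with strong regulatory weights, so that every true
    edge produces a clearly detectable perturbation response."""
    return syn.arabidopsis_config(
        weight_scale=3.0, activation_cap=None,
        hub_out_prob=0.4, background_edge_prob=0.02)


def edge_recovery(seed: int = 2,
                  times=(1.0, 2.0, 4.0, 8.0, 24.0),
                  eval_times=(1.0, 2.0, 4.0),
                  fdr: float = 0.1) -> dict:
    """Full GOF screen on a strong-weight network: clamp every TF,
    simulate counts, fit the contrast models, call edges, and score
    precision/recall against the planted adjacency at 1–4 h."""
    sim = syn.SimulationConfig(seed=seed)
    truth = syn.make_ground_truth(strong_effect_config(), seed)
    traj = {("GFP-GR", "dex"): syn.simulate_dynamics(truth, grid=times)}
    lines = [n + "-GR" for n in truth.nodes]
    for ln in lines:
        reg = ln.removesuffix("-GR")
        clamp = syn.Perturbation(reg, 32 * truth.steady_state[reg])
        traj[(ln, "dex")] = syn.simulate_dynamics(
            truth, perturbation=clamp, grid=times)
    counts = syn.simulate_nanostring(
        traj, syn.gof_design(sim, lines, times=times), sim, seed)
    expr = norm.normalize_housekeeping(counts)
    frames = []
    for ln in lines:
        reg = ln.removesuffix("-GR")
        frames.append(net.fit_line_time_model(
            expr, ln, "GFP-GR", times, regulator=reg,
            targets=[g for g in expr.values.index
                     if g not in norm.DEFAULT_HOUSEKEEPING]))
    estimates = pd.concat(frames, ignore_index=True)
    dyn = net.call_edges(estimates, fdr_threshold=fdr)
    early = dyn.edges[dyn.edges["time_h"].isin(eval_times)]
    called = set(map(tuple,
                     early[["regulator", "target"]].drop_duplicates().values))
    true_edges = set(map(tuple, truth.edges()[["source", "target"]].values))
    tp = len(called & true_edges)
    return {
        "truth": truth, "estimates": estimates, "network": dyn,
        "n_true": len(true_edges), "n_called": len(called), "n_tp": tp,
        "precision": tp / len(called) if called else float("nan"),
        "recall": tp / len(true_edges),
    }


def edge_recovery_pooled(seeds=(1, 2, 3), **kwargs) -> dict:
    """Edge recovery pooled over a fixed seed set: precision and recall
    computed on the union of true/called edges across replicates."""
    tp = called = true_n = 0
    for s in seeds:
        r = edge_recovery(seed=s, **kwargs)
        tp += r["n_tp"]
        called += r["n_called"]
        true_n += r["n_true"]
    return {"precision": tp / called, "recall": tp / true_n,
            "n_true": true_n, "n_called": called, "seeds": tuple(seeds)}


def null_contrast_calibration(seed: int = 7, n_genes: int = 500,
                              alpha: float = 0.05) -> dict:
    """Type-I rate of the line-vs-control contrasts under the null.

    ``n_genes`` independent null genes (control vs relabelled control,
    repeat effects present) are fitted jointly; the raw-p rejection
    rate should sit at the nominal level.
    """
    rng = np.random.default_rng(seed)
    times = (1.0, 2.0, 4.0)
    cols, meta_rows = [], {}
    vals = np.empty((n_genes, 2 * len(times) * 3))
    k = 0
    for ln in ("null-GR", "GFP-GR"):
        for t in times:
            for r in (1, 2, 3):
                sid = f"{ln}_{t}_{r}"
                cols.append(sid)
                meta_rows[sid] = {"line": ln, "treatment": "dex",
                                  "time_h": t, "repeat": r}
                vals[:, k] = rng.normal(5.0 + 0.1 * r, 0.4, size=n_genes)
                k += 1
    values = pd.DataFrame(vals, columns=cols,
                          index=[f"g{i}" for i in range(n_genes)])
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    expr = norm.ExpressionTable(values=values, meta=meta,
                                size_factors=pd.Series(1.0, index=cols))
    est = net.fit_line_time_model(expr, "null-GR", "GFP-GR", times)
    rate = float((est["p"] < alpha).mean())
    return {"rate": rate, "alpha": alpha, "n_runs": n_genes,
            "mc_error": float(np.sqrt(alpha * (1 - alpha) / n_genes))}


def tea_confirmation(seed: int = 3, n_edges: int = 25) -> dict:
    """Simulate a TEA campaign over called union edges and confirm."""
    sim = syn.SimulationConfig(seed=seed)
    truth = syn.make_ground_truth(syn.arabidopsis_config(), seed)
    edges = truth.edges().iloc[:n_edges]
    raw = syn.simulate_tea_campaign(truth, edges, sim, seed)
    ratios = tea.relative_luminescence(raw)
    em = tea.experiment_mean_ratios(ratios)
    calls = {}
    for (e1, e2, prom), sub in em.groupby(
            ["effector1", "effector2", "promoter"]):
        calls[(e1, prom)] = tea.call_single_regulation(
            sub["ratio"].values, effectors=(e1,), promoter=prom)
    union = edges.rename(columns={"weight": "log2fc"}).assign(
        first_time_h=1.0, q=0.05)
    table, summary = tea.confirm_edges(union, calls)
    confirmed = table[table["confirmation"] == "single"]
    agree = sum(int(r["sign"] == np.sign(
        truth.adjacency.loc[r["source"], r["target"]]))
        for _, r in confirmed.iterrows())
    return {"summary": summary, "table": table,
            "sign_agreement": agree / len(confirmed) if len(confirmed)
            else float("nan")}


def interaction_recovery(seed: int = 5, n_runs: int = 200,
                         gamma: float = 0.5, alpha: float = 0.05) -> dict:
    """Parameter recovery for the log2 interaction coefficient."""
    cfg = syn.SimulationConfig(
        seed=seed, interaction_coefficients={("A", "B"): gamma})
    estimates, correct = [], 0
    for r in range(n_runs):
        _, crosses = syn.simulate_phenotypes(
            cfg, {"wt": (1.0, 1.0)}, seed=seed * 100_003 + r,
            cross_effects={"A": -1.0, "B": -0.5})
        res = phen.interaction_test(crosses, alpha=alpha)
        estimates.append(res.coefficient)
        correct += res.classification == (
            "synergistic" if gamma > 0 else
            "negative" if gamma < 0 else "additive")
    est = np.asarray(estimates)
    return {
        "gamma": gamma, "n_runs": n_runs,
        "mean_estimate": float(est.mean()),
        "se_of_mean": float(est.std(ddof=1) / np.sqrt(n_runs)),
        "correct_rate": correct / n_runs,
    }


def wild_type_stress_study(seed: int = 11) -> dict:
    """Wild-type stress time course end-to-end: counts → normalization
    → per-time t-tests → onset groups, with the estimated rosette-area
    reduction from the phenotype generator."""
    sim = syn.SimulationConfig(seed=seed)
    truth = syn.make_ground_truth(syn.arabidopsis_config(), seed)
    grid = sim.time_grid_h
    traj = {
        ("wt", "mannitol"): syn.simulate_dynamics(
            truth, stimulus=syn.Stimulus(), grid=grid),
        ("wt", "control"): syn.simulate_dynamics(truth, grid=grid),
    }
    counts = syn.simulate_nanostring(
        traj, syn.stress_design(sim), sim, seed)
    expr = norm.normalize_housekeeping(counts)
    stats = kin.timecourse_differential(expr)
    stats = stats[~stats["gene"].isin(norm.DEFAULT_HOUSEKEEPING)]
    groups = kin.classify_onset(stats)
    plants, _ = syn.simulate_phenotypes(sim, {"wt": (1.0, 1.0)}, seed)
    wt = plants[plants["genotype"] == "wt"]
    reduction = 1 - wt[wt["treatment"] == "mannitol"]["rosette_mm2"].mean() \
        / wt[wt["treatment"] == "control"]["rosette_mm2"].mean()
    errors = sum(int(groups.loc[g, "group"] != truth.onset_group[g])
                 for g in truth.nodes)
    return {"truth": truth, "stats": stats, "groups": groups,
            "onset_errors": errors,
            "n_significant_1h": kin.count_significant(stats, 1.0, 0.05),
            "wt_reduction": float(reduction)}
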