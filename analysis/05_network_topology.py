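#!/usr/bin/env python
"""Core hubs and signed motifs of the confirmed network.

Reads results/confirmed_network.tsv, selects the core by greedy
out-degree coverage, enumerates feed-forward loops (flagging incoherent
ones) and short feedback cycles, summarizes regulatory redundancy, and
writes results/motifs.tsv and results/core.tsv.
"""

from pathlib import Path

import pandas as pd

from stressgrn import topology as topo

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "confirmed_network.tsv", sep="\t")
    confirmed = table[table["confirmation"] != "none"]
    g = topo.signed_network(confirmed)

    core, cov = topo.select_core(g, coverage=0.85)
    pd.DataFrame({"hub": core}).to_csv(ROOT / "core.tsv", sep="\t",
                                       index=False)
    print(f"confirmed network: {g.number_of_nodes()} nodes, "
          f"{g.number_of_edges()} edges")
    print(f"core at 85% out-edge coverage: {', '.join(core)} "
          f"(attained {cov:.0%})")

    ffls = topo.find_feedforward_loops(g)
    cycles = topo.find_feedback_cycles(g, max_len=4)
    motifs = pd.concat([
        ffls.assign(motif="ffl"),
        cycles.assign(motif="cycle")], ignore_index=True)
    motifs.to_csv(ROOT / "motifs.tsv", sep="\t", index=False)
    n_inc = int((~ffls["coherent"]).sum()) if len(ffls) else 0
    print(f"{len(ffls)} feed-forward loops ({n_inc} incoherent); "
          f"{len(cycles)} feedback cycles "
          f"({int(cycles['negative_feedback'].sum()) if len(cycles) else 0}"
          f" negative)")

    red = topo.redundancy_metrics(g)
    print(f"{red['n_multi_regulated']} targets have >= 2 upstream "
          f"regulators; top shared-target pair: "
          f"{max(red['shared_targets'].items(), key=lambda kv: kv[1]) if red['shared_targets'] else 'none'}")


if __name__ == "__main__":
    main()
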