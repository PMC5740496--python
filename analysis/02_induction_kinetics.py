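#!/usr/bin/env python
"""Wild-type stress time course: differential tests and onset groups.

Reads results/data/wt_stress_counts.tsv, normalizes against the five
housekeeping genes, runs per-gene-per-time t-tests (BH-adjusted within
each time point), classifies onset groups and late-response scenarios,
and writes results/kinetics.tsv.
"""

from pathlib import Path

import pandas as pd

from stressgrn import kinetics as kin
from stressgrn import normalize as norm

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = norm.read_count_table(ROOT / "data" / "wt_stress_counts.tsv")
    expr = norm.normalize_housekeeping(table)
    stats = kin.timecourse_differential(expr, paired=True)
    stats = stats[~stats["gene"].isin(norm.DEFAULT_HOUSEKEEPING)]

    onset = kin.classify_onset(stats)
    late = kin.classify_late_behavior(stats)
    merged = (stats.merge(onset, on="gene").merge(late, on="gene"))
    merged.to_csv(ROOT / "kinetics.tsv", sep="\t", index=False)

    n1h = kin.count_significant(stats, 1.0, alpha=0.05)
    print(f"{n1h} of 20 TFs significantly upregulated at 1 h (q < 0.05)")
    counts = onset["group"].value_counts().sort_index()
    print("onset groups (first sampled time with log2FC > 1):")
    for grp, n in counts.items():
        genes = ", ".join(sorted(onset.index[onset["group"] == grp]))
        print(f"  group {grp}: {n} genes — {genes}")
    print("late behaviour:", dict(late["scenario"].value_counts()))


if __name__ == "__main__":
    main()
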