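"""Wild-type stress time-course statistics and induction classifiers.

Per gene and time point, stress and control samples are compared with a
two-sided Student's t-test on log2-normalized expression, adjusted for
multiple testing with the Benjamini–Hochberg FDR procedure.  Genes are
then classified by the first sampled time their stress log2 fold change
exceeds a threshold (onset groups) and by their late-time behaviour
(decline / rebound / sustained).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import ExpressionTable

__all__ = [
    "timecourse_differential",
    "classify_onset",
    "classify_late_behavior",
    "count_significant",
    "DEFAULT_ONSET_BOUNDARIES",
    "DEFAULT_LATE_TIMES",
]

DEFAULT_ONSET_BOUNDARIES = (0.67, 1.0, 2.0, 4.0)
DEFAULT_LATE_TIMES = (12.0, 16.0, 24.0, 48.0)


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def timecourse_differential(expr: ExpressionTable,
                            stress: str = "mannitol",
                            control: str = "control",
                            paired: bool = True,
                            fdr_family: str = "per_time",
                            ) -> pd.DataFrame:
    """Per gene × time t-test of stress vs control log2 expression.

    ``paired=True`` pairs samples by repeat (the repeats are independent
    experiments; stress and control arms within one repeat share its
    batch).  ``fdr_family`` controls the Benjamini–Hochberg family:
    ``"per_time"`` adjusts across genes within each time point,
    ``"global"`` across all gene × time tests.

    Returns a table with one row per gene × time: log2fc, se, p, q, n.
    A gene × time cell with zero variance and zero difference gets
    p = 1 (no evidence, not a numerical accident).
    """
    meta = expr.meta
    times = sorted(meta.loc[meta["treatment"] == stress, "time_h"].unique())
    rows = []
    for t in times:
        at_t = meta["time_h"] == t
        s_meta = meta[at_t & (meta["treatment"] == stress)]
        c_meta = meta[at_t & (meta["treatment"] == control)]
        if len(s_meta) < 2 or len(c_meta) < 2:
            raise ValueError(
                f"need >=2 repeats per arm at t={t} h "
                f"(got {len(s_meta)} stress, {len(c_meta)} control)")
        if paired:
            common = sorted(set(s_meta["repeat"]) & set(c_meta["repeat"]))
            if len(common) < 2:
                raise ValueError(f"<2 paired repeats at t={t} h")
            s_cols = [s_meta.index[s_meta["repeat"] == r][0] for r in common]
            c_cols = [c_meta.index[c_meta["repeat"] == r][0] for r in common]
            diffs = expr.values[s_cols].values - expr.values[c_cols].values
            n = len(common)
            mean = diffs.mean(axis=1)
            sd = diffs.std(axis=1, ddof=1)
            se = sd / np.sqrt(n)
            df = n - 1
        else:
            s_cols, c_cols = list(s_meta.index), list(c_meta.index)
            a = expr.values[s_cols].values
            b = expr.values[c_cols].values
            n = min(a.shape[1], b.shape[1])
            mean = a.mean(axis=1) - b.mean(axis=1)
            va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
            se = np.sqrt(va / a.shape[1] + vb / b.shape[1])
            df = a.shape[1] + b.shape[1] - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
        p = 2 * stats.t.sf(np.abs(tstat), df)
        p = np.where((se == 0) & (mean == 0), 1.0, p)
        p = np.where((se == 0) & (mean != 0), 0.0, p)
        for g, m, s_, pv in zip(expr.values.index, mean, se, p):
            rows.append({"gene": g, "time_h": float(t), "log2fc": m,
                         "se": s_, "p": pv, "n_repeats": int(n)})
    out = pd.DataFrame(rows)
    if fdr_family == "per_time":
        out["q"] = out.groupby("time_h")["p"].transform(
            lambda s: _bh(s.values))
    elif fdr_family == "global":
        out["q"] = _bh(out["p"].values)
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return out


def classify_onset(stats_table: pd.DataFrame,
                   threshold: float = 1.0,
                   boundary_times: Sequence[float] = DEFAULT_ONSET_BOUNDARIES,
                   ) -> pd.DataFrame:
    """Group genes by the first sampled time log2FC strictly exceeds
    the threshold.

    The group index is the rank of the onset time within
    ``boundary_times``; a first crossing between two boundaries is
    assigned to the later boundary's group (boundaries are the last
    sampled times of their groups).  Genes that never cross within the
    last boundary get group "none".  Values after the first crossing
    are ignored.
    """
    boundaries = sorted(boundary_times)
    last = boundaries[-1]
    times = sorted(t for t in stats_table["time_h"].unique() if t <= last)
    missing = [b for b in boundaries if b not in times]
    if missing:
        raise ValueError(f"missing boundary time point(s): {missing}")
    rows = []
    for gene, sub in stats_table.groupby("gene"):
        sub = sub.set_index("time_h").sort_index()
        gaps = [t for t in times if t not in sub.index]
        if gaps:
            raise ValueError(f"gene {gene!r} missing time point(s): {gaps}")
        onset = None
        for t in times:
            if sub.loc[t, "log2fc"] > threshold:
                onset = t
                break
        if onset is None:
            rows.append({"gene": gene, "onset_time_h": np.nan,
                         "group": "none"})
        else:
            grp = next(i + 1 for i, b in enumerate(boundaries) if onset <= b)
            rows.append({"gene": gene, "onset_time_h": boundaries[grp - 1],
                         "group": grp})
    return pd.DataFrame(rows).set_index("gene")


def classify_late_behavior(stats_table: pd.DataFrame,
                           late_times: Sequence[float] = DEFAULT_LATE_TIMES,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Late-response scenario per gene over the tail of the time course.

    decline — no longer significantly upregulated at the last time;
    rebound — still significant, and the late log2FC series has a
    strict interior local minimum (dips, then rises again);
    sustained — still significant without an interior dip (ties count
    as sustained).
    """
    late = sorted(late_times)
    rows = []
    for gene, sub in stats_table.groupby("gene"):
        sub = sub.set_index("time_h").sort_index()
        gaps = [t for t in late if t not in sub.index]
        if gaps:
            raise ValueError(f"gene {gene!r} missing late time(s): {gaps}")
        q_last = sub.loc[late[-1], "q"]
        lfc_last = sub.loc[late[-1], "log2fc"]
        if q_last >= alpha or lfc_last <= 0:
            scenario = "decline"
        else:
            y = sub.loc[late, "log2fc"].values
            has_min = any(y[i] < y[i - 1] and y[i] < y[i + 1]
                          for i in range(1, len(y) - 1))
            scenario = "rebound" if has_min else "sustained"
        rows.append({"gene": gene, "scenario": scenario})
    return pd.DataFrame(rows).set_index("gene")


def count_significant(stats_table: pd.DataFrame, time: float,
                      alpha: float = 0.05) -> int:
    """Number of genes significantly upregulated (q < alpha, log2FC > 0)
    at one time point."""
    at_t = stats_table[stats_table["time_h"] == time]
    if at_t.empty:
        raise ValueError(f"no records at time {time} h")
    return int(((at_t["q"] < alpha) & (at_t["log2fc"] > 0)).sum())
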