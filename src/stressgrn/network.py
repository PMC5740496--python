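"""Edge calling from inducible-overexpression time courses.

Each gain-of-function (GOF) line is compared with the control line on
log2-normalized expression: per target gene, a linear model with fixed
effects line, time, line×time and the experimental repeat as a
categorical block, followed by Wald contrasts line − control at every
time point.  A target significantly differentially expressed
(FDR < 0.1) in a regulator's line at a time point becomes a directed,
provisionally signed edge regulator → target at that time.

With three repeats the repeat-level variance is barely estimable as a
random effect, so the block enters as a fixed effect; in balanced
designs the contrast estimates equal the differences of cell means
either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import ExpressionTable

__all__ = [
    "DynamicNetwork",
    "fit_line_time_model",
    "call_edges",
    "affected_fraction",
    "union_edges",
]


@dataclass
class DynamicNetwork:
    """Per-time-point signed edge sets.

    ``edges`` columns: regulator, target, time_h, log2fc, q, sign.
    """

    edges: pd.DataFrame
    fdr_threshold: float

    def __post_init__(self) -> None:
        if len(self.edges) and \
                (self.edges["regulator"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")

    def at(self, time_h: float) -> pd.DataFrame:
        return self.edges[self.edges["time_h"] == time_h]

    @property
    def times(self) -> list[float]:
        return sorted(self.edges["time_h"].unique())


def _design(meta: pd.DataFrame, line: str, control_line: str,
            times: Sequence[float]) -> tuple[np.ndarray, list, dict]:
    """Fixed-effect design: intercept, line, time dummies, line×time,
    repeat block.  Returns (X, sample index, contrast vectors per time)."""
    sel = meta[meta["line"].isin([line, control_line])
               & meta["time_h"].isin(times)]
    for ln in (line, control_line):
        for t in times:
            cell = sel[(sel["line"] == ln) & (sel["time_h"] == t)]
            if cell.empty:
                raise ValueError(
                    f"empty design cell: line={ln!r}, time={t} h")
            if len(cell) < 2:
                raise ValueError(
                    f"need >=2 repeats in cell line={ln!r}, time={t} h")
    times = sorted(times)
    repeats = sorted(sel["repeat"].unique())
    is_line = (sel["line"] == line).values.astype(float)
    cols = [np.ones(len(sel)), is_line]
    names = ["intercept", "line"]
    for t in times[1:]:
        ind = (sel["time_h"] == t).values.astype(float)
        cols.append(ind)
        names.append(f"time_{t}")
    for t in times[1:]:
        ind = ((sel["time_h"] == t).values.astype(float)) * is_line
        cols.append(ind)
        names.append(f"line:time_{t}")
    for r in repeats[1:]:
        cols.append((sel["repeat"] == r).values.astype(float))
        names.append(f"repeat_{r}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (missing cells or "
                         "confounded repeat structure)")
    p = X.shape[1]
    contrasts = {}
    for t in times:
        c = np.zeros(p)
        c[names.index("line")] = 1.0
        if t != times[0]:
            c[names.index(f"line:time_{t}")] = 1.0
        contrasts[t] = c
    return X, list(sel.index), contrasts


def fit_line_time_model(expr: ExpressionTable, line: str, control_line: str,
                        times: Sequence[float],
                        regulator: str | None = None,
                        targets: Sequence[str] | None = None) -> pd.DataFrame:
    """Wald contrasts line − control at each time, per target gene.

    All target genes share one design matrix, so the fits are solved
    jointly.  ``regulator`` (the TF overexpressed in ``line``) is
    excluded from the target family — its own probe mostly reads the
    transgene.  Benjamini–Hochberg adjustment runs over the whole
    per-line family (all targets × all times).
    """
    X, samples, contrasts = _design(expr.meta, line, control_line, times)
    if targets is None:
        targets = [g for g in expr.values.index if g != regulator]
    else:
        targets = [g for g in targets if g != regulator]
    Y = expr.values.loc[targets, samples].values.T  # samples × genes
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df

    rows = []
    for t, c in contrasts.items():
        est = c @ beta
        var_factor = float(c @ XtX_inv @ c)
        se = np.sqrt(sigma2 * var_factor)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
        p = 2 * stats.t.sf(np.abs(tstat), df)
        p = np.where((se == 0) & (est == 0), 1.0, p)
        for g, e_, s_, pv in zip(targets, est, se, p):
            rows.append({"regulator": regulator or line, "line": line,
                         "target": g, "time_h": float(t),
                         "estimate": e_, "se": s_, "p": pv})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].values, method="fdr_bh")[1]
    return out


def call_edges(estimates: pd.DataFrame,
               fdr_threshold: float = 0.1) -> DynamicNetwork:
    """Directed edge regulator → target at time t iff q < threshold.

    The provisional sign is the sign of the contrast estimate; the
    overexpressed TF never appears as its own target.
    """
    sig = estimates[(estimates["q"] < fdr_threshold)
                    & (estimates["regulator"] != estimates["target"])]
    edges = pd.DataFrame({
        "regulator": sig["regulator"].values,
        "target": sig["target"].values,
        "time_h": sig["time_h"].values,
        "log2fc": sig["estimate"].values,
        "q": sig["q"].values,
        "sign": np.sign(sig["estimate"].values).astype(int),
    })
    return DynamicNetwork(edges=edges.reset_index(drop=True),
                          fdr_threshold=fdr_threshold)


def affected_fraction(estimates: pd.DataFrame,
                      lfc_threshold: float = 1.0) -> pd.Series:
    """Per regulator, the fraction of target TFs whose absolute contrast
    exceeds the threshold at any sampled time."""
    def frac(sub: pd.DataFrame) -> float:
        peak = sub.groupby("target")["estimate"].apply(
            lambda s: np.abs(s).max())
        return float((peak > lfc_threshold).mean())
    return estimates.groupby("regulator").apply(frac, include_groups=False)


def union_edges(dyn_net: DynamicNetwork,
                times: Sequence[float]) -> pd.DataFrame:
    """Union of the per-time edge sets over ``times``, deduplicated by
    (regulator, target); the provisional sign (and log2FC) come from the
    earliest significant time point."""
    missing = [t for t in times if t not in dyn_net.times]
    if missing and len(dyn_net.edges):
        pass  # a time with zero edges is a valid empty set
    sub = dyn_net.edges[dyn_net.edges["time_h"].isin(times)]
    sub = sub.sort_values("time_h", kind="stable")
    first = sub.drop_duplicates(subset=["regulator", "target"], keep="first")
    out = first.rename(columns={"regulator": "source"})[
        ["source", "target", "time_h", "log2fc", "q", "sign"]]
    return out.reset_index(drop=True).rename(
        columns={"time_h": "first_time_h"})
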