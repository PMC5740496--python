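"""Plant growth statistics and the genetic-interaction test.

Rosette areas are analysed on the log2 scale (multiplicative biology,
variance stabilization): two-way models with genotype, treatment, their
interaction and the experimental repeat as a block; pairwise cell-mean
comparisons use the studentized-range (Tukey) distribution on the
residual mean square.  Stress sensitivity is summarized as the relative
reduction — a line's stress-induced area reduction divided by the wild
type's, wild type ≡ 1.  For genetic crosses, additivity on the log2
scale, E{log2 RA_dc} = E{log2 RA_sc1} + E{log2 RA_sc2} − E{log2 ref},
is tested through the interaction coefficient of a P1·P2 dummy
regression; a significant positive (negative) coefficient is a
synergistic (negative) interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InteractionResult",
    "rosette_growth_test",
    "relative_reduction",
    "leaf_series_compare",
    "cellular_decomposition",
    "interaction_test",
    "expected_double_reduction",
]

UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class InteractionResult:
    coefficient: float          # log2 deviation from additivity
    se: float
    p_value: float
    classification: str         # additive | synergistic | negative

    def __post_init__(self) -> None:
        ok = (self.classification == "additive"
              or (self.classification == "synergistic"
                  and self.coefficient > 0)
              or (self.classification == "negative"
                  and self.coefficient < 0))
        if not ok:
            raise ValueError("classification inconsistent with coefficient")


def _ols(X: np.ndarray, y: np.ndarray):
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    return beta, XtX_inv, sigma2, df


def _block_dummies(repeat: pd.Series) -> tuple[np.ndarray, list]:
    reps = sorted(repeat.unique())
    cols = [(repeat == r).values.astype(float) for r in reps[1:]]
    return (np.column_stack(cols) if cols
            else np.empty((len(repeat), 0))), reps


def rosette_growth_test(records: pd.DataFrame, line: str,
                        wild_type: str = "wt") -> dict:
    """Two-way genotype × treatment model on log2 rosette area.

    Fixed factors genotype, treatment and their interaction; repeat as
    a categorical block.  Reports the line effect per treatment as a
    percent area change versus the wild type, the interaction term, and
    all pairwise cell-mean comparisons with Tukey studentized-range
    adjusted p-values.
    """
    sub = records[records["genotype"].isin([line, wild_type])].copy()
    cells = {}
    for g in (wild_type, line):
        for t in ("control", "mannitol"):
            cell = sub[(sub["genotype"] == g) & (sub["treatment"] == t)]
            if cell.empty:
                raise ValueError(f"empty cell: genotype={g!r}, treatment={t!r}")
            cells[(g, t)] = cell
    y = np.log2(sub["rosette_mm2"].values)
    is_line = (sub["genotype"] == line).values.astype(float)
    is_stress = (sub["treatment"] == "mannitol").values.astype(float)
    blocks, _ = _block_dummies(sub["repeat"])
    X = np.column_stack([np.ones(len(sub)), is_line, is_stress,
                         is_line * is_stress, blocks])
    beta, XtX_inv, sigma2, df = _ols(X, y)

    def coef_test(i: int) -> tuple[float, float, float]:
        se = np.sqrt(sigma2 * XtX_inv[i, i])
        t = beta[i] / se
        return beta[i], se, 2 * stats.t.sf(abs(t), df)

    line_c, _, p_line_c = coef_test(1)
    inter, se_i, p_inter = coef_test(3)

    # Tukey pairwise comparisons on block-adjusted cell means
    keys = [(g, t) for g in (wild_type, line) for t in ("control", "mannitol")]
    means = {}
    ns = {}
    for k in keys:
        mask = ((sub["genotype"] == k[0])
                & (sub["treatment"] == k[1])).values
        means[k] = float(np.mean(y[mask] - blocks[mask] @ beta[4:]))
        ns[k] = int(mask.sum())
    pairwise = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            d = means[a] - means[b]
            se = np.sqrt(sigma2 / 2 * (1 / ns[a] + 1 / ns[b]))
            q = abs(d) / se
            p = float(stats.studentized_range.sf(q, len(keys), df))
            pairwise.append({"cell_a": a, "cell_b": b, "diff_log2": d,
                             "p_tukey": min(max(p, 0.0), 1.0)})
    return {
        "line_effect_control_pct": 100 * (2.0 ** line_c - 1),
        "line_effect_stress_pct": 100 * (2.0 ** (line_c + inter) - 1),
        "line_p_control": p_line_c,
        "interaction_log2": inter,
        "interaction_se": se_i,
        "interaction_p": p_inter,
        "pairwise": pd.DataFrame(pairwise),
        "cell_means_log2": means,
    }


def relative_reduction(line_records: pd.DataFrame,
                       wt_records: pd.DataFrame) -> float:
    """Stress-induced relative area reduction versus wild type.

    (1 − mean(line, stress)/mean(line, control)) divided by the same
    quantity in the wild type; the wild type is 1 by construction, a
    hypersensitive line exceeds 1.
    """
    def reduction(rec: pd.DataFrame) -> float:
        parts = {}
        for t in ("control", "mannitol"):
            cell = rec[rec["treatment"] == t]
            if cell.empty:
                raise ValueError(f"no {t} records")
            parts[t] = cell["rosette_mm2"].mean()
        return 1.0 - parts["mannitol"] / parts["control"]

    wt_red = reduction(wt_records)
    if wt_red <= 0:
        raise ValueError("wild-type reduction <= 0: relative reduction "
                         "undefined")
    return reduction(line_records) / wt_red


def leaf_series_compare(records: pd.DataFrame, lines, wild_type: str = "wt",
                        n_mc: int = 20000, seed: int = 7,
                        treatment: str | None = None) -> pd.DataFrame:
    """Per-leaf genotype contrasts versus wild type with a Monte-Carlo
    max-|t| (Dunnett-type) family-wise adjustment across genotypes.

    Per leaf position, log2 leaf area is modelled with genotype and the
    repeat block; every line is contrasted against the wild type.  The
    null distribution of the maximum |t| over the line contrasts is
    sampled (multivariate normal with the contrasts' correlation,
    scaled by a shared chi distribution), seeded for reproducibility.
    Leaves missing in one genotype are skipped with a warning column.
    """
    if isinstance(lines, str):
        lines = [lines]
    sub = records[records["genotype"].isin(list(lines) + [wild_type])]
    if treatment is not None:
        sub = sub[sub["treatment"] == treatment]
    leaf_cols = [c for c in records.columns
                 if c.startswith("leaf_") and c.endswith("_mm2")]
    rng = np.random.default_rng(seed)
    rows = []
    for leaf in leaf_cols:
        avail = sub[sub[leaf].notna() & (sub[leaf] > 0)]
        present = set(avail["genotype"])
        use_lines = [ln for ln in lines if ln in present]
        if wild_type not in present or not use_lines:
            continue
        y = np.log2(avail[leaf].values)
        blocks, _ = _block_dummies(avail["repeat"])
        geno_cols = [(avail["genotype"] == ln).values.astype(float)
                     for ln in use_lines]
        X = np.column_stack([np.ones(len(avail))] + geno_cols + [blocks])
        beta, XtX_inv, sigma2, df = _ols(X, y)
        C = np.zeros((len(use_lines), X.shape[1]))
        for i in range(len(use_lines)):
            C[i, 1 + i] = 1.0
        cov = C @ XtX_inv @ C.T
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        est = C @ beta
        se = np.sqrt(sigma2) * sd
        tstat = est / se
        p_raw = 2 * stats.t.sf(np.abs(tstat), df)
        # null max-|t|: shared residual scale across the contrasts
        z = rng.multivariate_normal(np.zeros(len(use_lines)), corr,
                                    size=n_mc, method="cholesky")
        s = np.sqrt(rng.chisquare(df, size=n_mc) / df)
        max_t = np.abs(z / s[:, None]).max(axis=1)
        for i, ln in enumerate(use_lines):
            p_adj = float((max_t >= abs(tstat[i])).mean())
            rows.append({"leaf": leaf, "line": ln, "estimate_log2": est[i],
                         "se": se[i], "t": tstat[i], "p": p_raw[i],
                         "p_adj": max(p_adj, float(p_raw[i])),
                         "skipped_lines": ",".join(
                             sorted(set(lines) - set(use_lines)))})
    return pd.DataFrame(rows)


def cellular_decomposition(leaf_area: float, cell_area_sample,
                           leaf_unit: str = "mm2",
                           cell_unit: str = "um2") -> dict:
    """Decompose a leaf area into pavement-cell number × mean cell area.

    Estimated cell number = leaf area ÷ mean sampled cell area, after
    converting the leaf area to the cell-area unit.  Requires ≥30
    sampled cells for a stable mean.
    """
    cells = np.asarray(cell_area_sample, float)
    if cells.size < 30:
        raise ValueError("need >=30 sampled cells")
    if (cells <= 0).any() or leaf_area <= 0:
        raise ValueError("areas must be positive")
    if leaf_unit == "mm2" and cell_unit == "um2":
        leaf_um2 = leaf_area * UM2_PER_MM2
    elif leaf_unit == cell_unit:
        leaf_um2 = leaf_area
    else:
        raise ValueError(
            f"unit mismatch ({leaf_unit} vs {cell_unit}) without a known "
            "conversion")
    mean_cell = float(cells.mean())
    return {"mean_cell_area": mean_cell,
            "cell_number": leaf_um2 / mean_cell}


def compare_cellular(samples_a, leaf_a: float, samples_b, leaf_b: float,
                     **units) -> dict:
    """Genotype comparison of cell size and estimated cell number on the
    log scale (Welch t-test on log cell areas; number ratio from the
    decomposition)."""
    da = cellular_decomposition(leaf_a, samples_a, **units)
    db = cellular_decomposition(leaf_b, samples_b, **units)
    t = stats.ttest_ind(np.log(np.asarray(samples_a, float)),
                        np.log(np.asarray(samples_b, float)),
                        equal_var=False)
    return {
        "cell_area_ratio": da["mean_cell_area"] / db["mean_cell_area"],
        "cell_area_p": float(t.pvalue),
        "cell_number_ratio": da["cell_number"] / db["cell_number"],
    }


def interaction_test(cross_records: pd.DataFrame,
                     alpha: float = 0.05) -> InteractionResult:
    """Log2-additivity test for a double cross.

    OLS on log2 rosette area with terms P1, P2, P1·P2 and the repeat
    block.  Under additivity the P1·P2 coefficient is zero; with the
    dummy parameterization it directly estimates
    E{log2 RA_dc} − E{log2 RA_sc1} − E{log2 RA_sc2} + E{log2 ref}.
    """
    for p1, p2 in ((0, 0), (0, 1), (1, 0), (1, 1)):
        cell = cross_records[(cross_records["p1"] == p1)
                             & (cross_records["p2"] == p2)]
        if len(cell) < 2:
            raise ValueError(f"design cell P1={p1}, P2={p2} needs >=2 plants")
    y = np.log2(cross_records["rosette_mm2"].values)
    p1 = cross_records["p1"].values.astype(float)
    p2 = cross_records["p2"].values.astype(float)
    blocks, _ = _block_dummies(cross_records["repeat"])
    X = np.column_stack([np.ones(len(y)), p1, p2, p1 * p2, blocks])
    beta, XtX_inv, sigma2, df = _ols(X, y)
    se = float(np.sqrt(sigma2 * XtX_inv[3, 3]))
    t = beta[3] / se
    p = float(2 * stats.t.sf(abs(t), df))
    if p < alpha and beta[3] > 0:
        cls = "synergistic"
    elif p < alpha and beta[3] < 0:
        cls = "negative"
    else:
        cls = "additive"
    return InteractionResult(float(beta[3]), se, p, cls)


def expected_double_reduction(r1: float, r2: float) -> float:
    """Expected stress reduction of a double cross under additivity:
    surviving fractions multiply, so 1 − (1−r1)(1−r2)."""
    for r in (r1, r2):
        if not 0 <= r < 1:
            raise ValueError("reductions must lie in [0, 1)")
    return 1.0 - (1.0 - r1) * (1.0 - r2)
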