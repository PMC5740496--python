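"""Count-table handling, housekeeping normalization, fold changes, ΔΔCt.

Probe-count platforms report absolute molecule counts per sample; the
amount of input RNA varies, so counts are made comparable by scaling
each sample with a size factor derived from a fixed panel of
housekeeping genes assumed constant across conditions.  All downstream
statistics run on log2-normalized values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_HOUSEKEEPING",
    "CountTable",
    "ExpressionTable",
    "CountTableError",
    "read_count_table",
    "write_count_table",
    "normalize_housekeeping",
    "log2_fold_change",
    "ddct",
]

# The five Arabidopsis housekeeping genes of the probe panel (AGI ids).
DEFAULT_HOUSEKEEPING = (
    "AT1G13320", "AT2G32170", "AT2G28390", "AT5G15710", "AT4G24550",
)

REQUIRED_META = ("line", "treatment", "time_h", "repeat")

VALID_TREATMENTS = {"control", "mannitol", "dex"}


class CountTableError(ValueError):
    pass


@dataclass
class CountTable:
    """Gene × sample counts plus per-sample metadata.

    ``counts``: genes as rows, samples as columns, non-negative ints.
    ``meta``: indexed by sample id with columns line, treatment,
    time_h, repeat.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise CountTableError(f"duplicate gene id: {dup!r}")
        if (self.counts.values < 0).any():
            raise CountTableError("negative counts")
        missing = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing:
            raise CountTableError("missing metadata: " + ", ".join(missing))
        if set(self.counts.columns) != set(self.meta.index):
            raise CountTableError("sample ids of counts and metadata differ")
        if self.meta[list(REQUIRED_META)].isna().any().any():
            bad = self.meta.index[
                self.meta[list(REQUIRED_META)].isna().any(axis=1)][0]
            raise CountTableError(f"incomplete metadata for sample {bad!r}")
        bad_trt = set(self.meta["treatment"]) - VALID_TREATMENTS
        if bad_trt:
            raise CountTableError(f"unknown treatment(s): {sorted(bad_trt)}")
        self.meta = self.meta.loc[self.counts.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, mask: pd.Series) -> "CountTable":
        keep = self.meta.index[mask.loc[self.meta.index]]
        return CountTable(self.counts[keep], self.meta.loc[keep])


@dataclass
class ExpressionTable:
    """log2-normalized expression with its normalization audit trail."""

    values: pd.DataFrame            # genes × samples, log2 scale
    meta: pd.DataFrame
    size_factors: pd.Series = field(default=None)
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise CountTableError("non-finite normalized values")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise CountTableError("size factors must be positive")


def write_count_table(table: CountTable, path) -> None:
    """Single-file TSV: '#meta' comment lines carry the sample metadata,
    then a gene_id-first count matrix."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# stressgrn count table\n")
        fh.write("# #meta lines: sample_id, " + ", ".join(REQUIRED_META) + "\n")
        for s, row in table.meta.iterrows():
            fields = [str(row[c]) for c in REQUIRED_META]
            fh.write("\t".join(["#meta", str(s)] + fields) + "\n")
        fh.write("\t".join(["gene_id"] + table.samples) + "\n")
        for g in table.genes:
            vals = table.counts.loc[g].astype(int).astype(str)
            fh.write("\t".join([g] + list(vals)) + "\n")


def read_count_table(path) -> CountTable:
    """Inverse of :func:`write_count_table`; validates counts and
    metadata and names the offending row/column on failure."""
    meta_rows = {}
    data_lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#meta\t"):
                parts = line.split("\t")
                if len(parts) != 2 + len(REQUIRED_META):
                    raise CountTableError(f"malformed #meta line: {line!r}")
                meta_rows[parts[1]] = dict(zip(REQUIRED_META, parts[2:]))
            elif line.startswith("#") or not line.strip():
                continue
            else:
                data_lines.append(line.split("\t"))
    if not data_lines:
        raise CountTableError("no count rows found")
    header, *rows = data_lines
    samples = header[1:]
    df = pd.DataFrame([r[1:] for r in rows],
                      index=[r[0] for r in rows], columns=samples)
    try:
        df = df.astype(int)
    except ValueError:
        for g in df.index:
            for s in df.columns:
                try:
                    int(df.loc[g, s])
                except ValueError:
                    raise CountTableError(
                        f"non-integer count {df.loc[g, s]!r} in row {g!r}, "
                        f"column {s!r}") from None
    if not meta_rows:
        raise CountTableError("missing metadata: no #meta lines")
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample_id"
    meta["time_h"] = meta["time_h"].astype(float)
    meta["repeat"] = meta["repeat"].astype(int)
    return CountTable(df, meta)


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def normalize_housekeeping(table: CountTable,
                           hk_ids=DEFAULT_HOUSEKEEPING,
                           pseudocount: float = 0.5) -> ExpressionTable:
    """log2 expression after housekeeping size-factor normalization.

    Per sample, the size factor is the geometric mean of its
    housekeeping counts divided by the grand geometric mean of those
    per-sample values, so factors multiply to one.  Housekeeping genes
    with a zero count in a sample are dropped from that sample's
    geometric mean; a sample where all housekeeping counts are zero is
    an unusable sample and raises.
    """
    hk_ids = [g for g in hk_ids]
    missing = [g for g in hk_ids if g not in table.counts.index]
    if missing:
        raise CountTableError(
            "housekeeping genes absent from table: " + ", ".join(missing))
    hk = table.counts.loc[hk_ids]
    per_sample = {}
    for s in table.samples:
        vals = hk[s].values.astype(float)
        vals = vals[vals > 0]
        if vals.size == 0:
            raise CountTableError(
                f"all housekeeping counts are zero in sample {s!r}")
        per_sample[s] = _geomean(vals)
    gm = pd.Series(per_sample)
    size_factors = gm / np.exp(np.mean(np.log(gm.values)))
    values = np.log2(
        (table.counts.astype(float) + pseudocount).div(size_factors, axis=1))
    return ExpressionTable(values=values, meta=table.meta.copy(),
                           size_factors=size_factors,
                           pseudocount=pseudocount)


def log2_fold_change(expr: ExpressionTable,
                     group_a, group_b) -> pd.Series:
    """Per-gene mean(log2 a) − mean(log2 b).

    With a balanced paired design this equals the mean of the
    per-repeat differences, so no separate paired estimator is needed.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("empty sample group")
    if set(group_a) & set(group_b):
        raise ValueError("sample groups overlap")
    return (expr.values[group_a].mean(axis=1)
            - expr.values[group_b].mean(axis=1))


def ddct(ct_table: pd.DataFrame, hk_ids,
         control_wells, treatment_wells) -> pd.DataFrame:
    """qPCR ΔΔCt: dCt = Ct(gene) − mean Ct(housekeeping) per well;
    ddCt = mean dCt(control) − mean dCt(treatment); fold = 2^ddCt.

    Assumes 100 % amplification efficiency (one cycle = one doubling).
    """
    hk_ids = [g for g in hk_ids]
    control_wells, treatment_wells = list(control_wells), list(treatment_wells)
    missing = [g for g in hk_ids if g not in ct_table.index]
    if missing:
        raise ValueError("housekeeping Ct missing: " + ", ".join(missing))
    for w in control_wells + treatment_wells:
        if w not in ct_table.columns:
            raise ValueError(f"missing well {w!r}")
        if ct_table.loc[hk_ids, w].isna().any():
            raise ValueError(f"missing housekeeping Ct in well {w!r}")
    if (ct_table.values <= 0).any():
        raise ValueError("Ct values must be positive")
    hk_mean = ct_table.loc[hk_ids].mean(axis=0)
    dct = ct_table.sub(hk_mean, axis=1)
    genes = [g for g in ct_table.index if g not in hk_ids]
    ddct_vals = (dct.loc[genes, control_wells].mean(axis=1)
                 - dct.loc[genes, treatment_wells].mean(axis=1))
    return pd.DataFrame({"ddct": ddct_vals, "fold_change": 2.0 ** ddct_vals})
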