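"""Transient expression assay (TEA) analysis.

Protoplasts are co-transformed with an effector construct (35S::TF, or
two of them) and a promoter-luciferase reporter (pTF::fLUC).  Raw
luminescence is expressed relative to a neutral control construct
(35S::GUS) within the same experiment batch; regulation is called from
a one-sample t-test of the experiment-mean log2 ratios against zero.
Pairwise co-transformations are classified into combinatorial
scenarios, and the TEA verdicts confirm and sign the edges called from
the in-planta perturbation data (the assay isolates the TF from the
plant context, so its sign overrides the in-planta provisional sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegulationCall",
    "PairScenario",
    "relative_luminescence",
    "experiment_mean_ratios",
    "call_single_regulation",
    "classify_pair_effect",
    "confirm_edges",
]

PAIR_CONFIRMING_SCENARIOS = {"enhancement", "emergent", "attenuation"}


@dataclass(frozen=True)
class RegulationCall:
    effectors: tuple[str, ...]
    promoter: str
    verdict: str                 # activation | repression | none
    mean_log2_ratio: float
    p_value: float

    def __post_init__(self) -> None:
        if self.verdict == "activation" and self.mean_log2_ratio <= 0 or \
           self.verdict == "repression" and self.mean_log2_ratio >= 0:
            raise ValueError("verdict inconsistent with ratio sign")


@dataclass(frozen=True)
class PairScenario:
    pair: tuple[str, str]
    promoter: str
    scenario: str


def relative_luminescence(raw: pd.DataFrame,
                          control_effector: str = "GUS") -> pd.DataFrame:
    """Replicate activity ÷ mean neutral-control activity of its batch.

    ``raw`` columns: effector1, effector2 (blank for singles), promoter,
    experiment, replicate, activity.  Batch = (promoter, experiment):
    every reporter has its own control set per experiment.
    """
    req = {"effector1", "promoter", "experiment", "replicate", "activity"}
    missing = req - set(raw.columns)
    if missing:
        raise ValueError(f"raw TEA table missing columns: {sorted(missing)}")
    if (raw["activity"] <= 0).any():
        raise ValueError("activities must be positive")
    ctrl = raw[raw["effector1"] == control_effector]
    ctrl_mean = ctrl.groupby(["promoter", "experiment"])["activity"].mean()
    out = raw[raw["effector1"] != control_effector].copy()
    keys = list(zip(out["promoter"], out["experiment"]))
    absent = sorted({k for k in keys if k not in ctrl_mean.index})
    if absent:
        raise ValueError(
            f"missing batch control for (promoter, experiment): {absent}")
    out["ratio"] = out["activity"].values / ctrl_mean.loc[keys].values
    return out


def experiment_mean_ratios(ratios: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates to one mean ratio per construct × experiment."""
    eff2 = ratios["effector2"].fillna("") if "effector2" in ratios \
        else pd.Series("", index=ratios.index)
    g = ratios.assign(effector2=eff2).groupby(
        ["effector1", "effector2", "promoter", "experiment"])
    return g["ratio"].mean().reset_index()


def call_single_regulation(experiment_ratios,
                           alpha: float = 0.05,
                           effectors: tuple[str, ...] = (),
                           promoter: str = "") -> RegulationCall:
    """Verdict from independent-experiment mean ratios.

    One-sample two-sided t-test of log2(mean ratio per experiment)
    against 0; activation/repression by the sign of the mean if
    p < alpha, otherwise none.
    """
    vals = np.asarray(experiment_ratios, float)
    if vals.size < 3:
        raise ValueError("need >=3 independent experiment means")
    logs = np.log2(vals)
    mean = float(logs.mean())
    if np.allclose(logs, logs[0]):
        p = 1.0 if mean == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(logs, 0.0).pvalue)
    if p < alpha:
        verdict = "activation" if mean > 0 else "repression"
    else:
        verdict = "none"
    return RegulationCall(tuple(effectors), promoter, verdict, mean, p)


def _direction(call: RegulationCall) -> int:
    return 0 if call.verdict == "none" else int(np.sign(call.mean_log2_ratio))


def classify_pair_effect(call_a: RegulationCall, call_b: RegulationCall,
                         pair_call: RegulationCall,
                         margin: float = 0.5) -> PairScenario:
    """Classify the joint effect of two effectors on one promoter.

    Decision tree on the verdicts and log2 mean ratios (margin on the
    log2 scale, default 0.5 ≈ 1.4-fold), symmetric in (A, B):

    * emergent — neither single regulates, the pair does;
    * enhancement — a single regulates, the pair acts in the same
      direction and is stronger by at least the margin;
    * elimination — a single regulates but the pair does not;
    * dominance — the singles disagree (or one is silent) and the pair
      sits within the margin of the stronger single;
    * attenuation — the pair acts in the stronger single's direction
      but lies strictly between the two singles, at least the margin
      away from each;
    * additive — anything else.
    """
    if not (call_a.promoter == call_b.promoter == pair_call.promoter):
        raise ValueError("calls refer to different promoters")
    da, db, dp = _direction(call_a), _direction(call_b), _direction(pair_call)
    ma, mb, mp = (call_a.mean_log2_ratio, call_b.mean_log2_ratio,
                  pair_call.mean_log2_ratio)
    pair = (call_a.effectors[0], call_b.effectors[0])

    # stronger single by |log2 ratio| among the active ones; the tie
    # break (larger signed mean) keeps the rule symmetric in (A, B)
    if da and (not db or abs(ma) > abs(mb)
               or (abs(ma) == abs(mb) and ma >= mb)):
        strong_d, strong_m = da, ma
    else:
        strong_d, strong_m = db, mb

    if da == 0 and db == 0:
        scenario = "emergent" if dp != 0 else "additive"
    elif dp == 0:
        scenario = "elimination"
    elif (da == 0) != (db == 0) and dp == strong_d and \
            abs(mp) >= abs(strong_m) + margin:
        scenario = "enhancement"
    elif (da * db <= 0) and abs(mp - strong_m) <= margin:
        scenario = "dominance"
    elif dp == strong_d and \
            min(ma, mb) + margin <= mp <= max(ma, mb) - margin:
        scenario = "attenuation"
    else:
        scenario = "additive"
    return PairScenario(pair, call_a.promoter, scenario)


def confirm_edges(union_edges: pd.DataFrame,
                  single_calls: dict[tuple[str, str], RegulationCall],
                  pair_calls: list[PairScenario] | None = None,
                  ) -> tuple[pd.DataFrame, dict]:
    """Confirm and sign the in-planta edges with the TEA verdicts.

    An edge (source → target) is confirmed-single when the single-
    effector TEA on the target promoter regulates (verdict ≠ none); its
    final sign is the TEA sign, overriding the in-planta provisional
    sign.  An edge without single confirmation becomes confirmed-pair
    when its source participates in an enhancement / emergent /
    attenuation pairwise scenario on that promoter.  Edges with no TEA
    record at all are flagged untested.

    Returns (confirmed network table, summary counts).
    """
    pair_calls = pair_calls or []
    rows = []
    for _, e in union_edges.iterrows():
        src, tgt = e["source"], e["target"]
        rec = single_calls.get((src, tgt))
        confirmation, sign, tested = "none", int(e["sign"]), rec is not None
        if rec is not None and rec.verdict != "none":
            confirmation = "single"
            sign = 1 if rec.verdict == "activation" else -1
        elif tested:
            for ps in pair_calls:
                if ps.promoter == tgt and src in ps.pair \
                        and ps.scenario in PAIR_CONFIRMING_SCENARIOS:
                    confirmation = "pair"
                    break
        rows.append({"source": src, "target": tgt, "sign": sign,
                     "provisional_sign": int(e["sign"]),
                     "confirmation": confirmation, "tested": tested})
    table = pd.DataFrame(rows)
    summary = {
        "tested": int(table["tested"].sum()),
        "untested": int((~table["tested"]).sum()),
        "confirmed_single": int((table["confirmation"] == "single").sum()),
        "confirmed_pair": int((table["confirmation"] == "pair").sum()),
    }
    summary["confirmed_total"] = (summary["confirmed_single"]
                                  + summary["confirmed_pair"])
    return table, summary
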