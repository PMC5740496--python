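"""Synthetic data with known ground truth for the stress-GRN pipeline.

This module emulates the experimental layers of a mild-osmotic-stress
perturbation study in Arabidopsis leaves:

* a signed, hub-dominated transcription-factor network in which delayed
  repressors close incoherent feed-forward loops over the stress input;
* deterministic transcription kinetics (saturating Hill regulation with
  first-order decay) producing the sequential onset of four induction
  groups, crossing log2(FC) = 1 at ~40 min, 1 h, 2 h and 4 h;
* probe-count (NanoString-style) readout: negative-binomial counts with
  per-sample size factors, repeat-level batch effects and five
  condition-independent housekeeping genes;
* transient expression assays (TEA): luminescence ratios relative to a
  neutral control construct, with configurable pairwise-effector rules;
* plant phenotypes: log-normal rosette and leaf areas with multiplicative
  genotype, treatment and repeat effects, pavement-cell samples, and
  genetic crosses with a log2-scale interaction coefficient.

Every output is a pure function of (config, seed).  Independent random
sub-streams are derived per dataset, so generating one dataset never
shifts the draws of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .normalize import DEFAULT_HOUSEKEEPING, CountTable

__all__ = [
    "NetworkConfig",
    "SimulationConfig",
    "GroundTruthNetwork",
    "Stimulus",
    "Perturbation",
    "Trajectories",
    "TEAMeasurement",
    "ConfigurationError",
    "IntegrationError",
    "DEFAULT_TF_GROUPS",
    "DEFAULT_HUBS",
    "DEFAULT_REPRESSORS",
    "ONSET_TIMES_H",
    "arabidopsis_config",
    "make_ground_truth",
    "simulate_dynamics",
    "simulate_nanostring",
    "simulate_tea",
    "simulate_tea_campaign",
    "simulate_phenotypes",
]


class ConfigurationError(ValueError):
    """Raised for impossible generator configurations."""


class IntegrationError(RuntimeError):
    """Raised when the kinetic integrator produces invalid states."""


# The 20 stress-responsive TFs, grouped by induction onset: the sampled
# time at which the stress log2 fold change first exceeds 1.
ONSET_TIMES_H = (0.67, 1.0, 2.0, 4.0)

DEFAULT_TF_GROUPS: dict[str, int] = {
    # group 1 — threshold crossed at 40 min
    "ERF5": 1, "ERF6": 1, "ERF11": 1, "ERF98": 1, "WRKY40": 1, "STZ": 1,
    "ZAT6": 1,
    # group 2 — 1 h
    "ERF1": 2, "ERF2": 2, "WRKY30": 2, "WRKY33": 2, "MYB51": 2,
    # group 3 — 2 h (includes the delayed repressors ERF8 and ERF9)
    "WRKY6": 3, "WRKY15": 3, "WRKY28": 3, "WRKY48": 3, "ERF59": 3,
    "ERF8": 3, "ERF9": 3,
    # group 4 — 4 h
    "RAP2.6L": 4,
}

DEFAULT_HUBS = ("ERF6", "ERF8", "ERF9", "ERF59", "ERF98")
DEFAULT_REPRESSORS = ("ERF8", "ERF9")

# Peak induction amplitude per onset group, on the log2 fold-change
# scale (group 1 strongest, group 3 weakest, the late activator high).
_GROUP_MAX_LFC = {1: 6.0, 2: 4.0, 3: 3.0, 4: 5.0}

_DEFAULT_GRID = (0.33, 0.67, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0, 48.0)


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible child stream for one dataset."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) % (2**31),
                               spawn_key=(zlib.crc32(label.encode()),))
    )


@dataclass(frozen=True)
class NetworkConfig:
    """Topology and kinetic parameters of the ground-truth network."""

    n_nodes: int = 20
    n_hubs: int = 5
    node_names: tuple[str, ...] | None = None
    hubs: tuple[str, ...] | None = None
    repressors: tuple[str, ...] = ()
    onset_groups: Mapping[str, int] | None = None
    hub_out_prob: float = 0.55
    background_edge_prob: float = 0.04
    weight_scale: float = 1.0
    basal: float = 1.0
    decay: float = 2.0
    require_incoherent_ffl: bool = True
    # per-target caps on summed incoming weight, as multiples of basal;
    # None disables the cap (used for strong-effect recovery studies)
    activation_cap: float | None = 0.8
    repression_cap: float | None = 0.9
    time_grid_h: tuple[float, ...] = _DEFAULT_GRID


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level design parameters shared by the data generators."""

    seed: int = 0
    n_repeats: int = 3
    time_grid_h: tuple[float, ...] = _DEFAULT_GRID
    nb_dispersion: float = 0.05
    count_gain: float = 400.0
    size_factor_log2_sd: float = 0.2
    batch_log2_sd: float = 0.15
    housekeeping_ids: tuple[str, ...] = DEFAULT_HOUSEKEEPING
    housekeeping_means: tuple[float, ...] = (800.0, 1200.0, 600.0, 1500.0, 1000.0)
    stress_area_multiplier: float = 0.70
    n_plants: int = 10
    n_plants_cross: int = 8
    area_log2_sd: float = 0.30
    repeat_log2_sd: float = 0.10
    base_rosette_mm2: float = 90.0
    n_leaves: int = 10
    mean_cell_area_um2: float = 1600.0
    cells_per_leaf: int = 100
    tea_cv: float = 0.25
    tea_base_luminescence: float = 1000.0
    interaction_coefficients: Mapping[tuple[str, str], float] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.time_grid_h, float)
        if not np.all(np.diff(grid) > 0):
            raise ConfigurationError("time grid must be strictly increasing")
        if self.n_repeats < 2:
            raise ConfigurationError("n_repeats must be >= 2")
        if not 0 < self.stress_area_multiplier <= 2:
            raise ConfigurationError(
                "stress_area_multiplier must lie in (0, 2]")


@dataclass
class GroundTruthNetwork:
    """Signed weighted adjacency with kinetic node parameters.

    ``adjacency.loc[i, j]`` is the weight of regulator *i* acting on
    target *j* (positive = activation, negative = repression).
    """

    nodes: list[str]
    adjacency: pd.DataFrame
    onset_delay: pd.Series
    hub_flag: pd.Series
    basal: pd.Series
    decay: pd.Series
    onset_group: pd.Series
    max_lfc: pd.Series

    def __post_init__(self) -> None:
        if np.any(np.diag(self.adjacency.values) != 0):
            raise ConfigurationError("self-edges are not allowed")

    @property
    def steady_state(self) -> pd.Series:
        return self.basal / self.decay

    def edges(self) -> pd.DataFrame:
        """Long-form signed edge list (source, target, weight, sign)."""
        a = self.adjacency
        src, tgt = np.nonzero(a.values)
        w = a.values[src, tgt]
        return pd.DataFrame({
            "source": a.index[src],
            "target": a.columns[tgt],
            "weight": w,
            "sign": np.sign(w).astype(int),
        })

    def incoherent_ffls(self) -> list[tuple[str, str, str]]:
        """Ordered triples (X, Y, Z) with sign(X→Z) != sign(X→Y)·sign(Y→Z)."""
        a = self.adjacency.values
        n = len(self.nodes)
        out = []
        for x in range(n):
            for y in range(n):
                if x == y or a[x, y] == 0:
                    continue
                for z in range(n):
                    if z in (x, y) or a[y, z] == 0 or a[x, z] == 0:
                        continue
                    if np.sign(a[x, z]) != np.sign(a[x, y]) * np.sign(a[y, z]):
                        out.append((self.nodes[x], self.nodes[y],
                                    self.nodes[z]))
        return out

    def to_json(self, path) -> None:
        payload = {
            "nodes": self.nodes,
            "edges": self.edges().to_dict(orient="records"),
            "onset_delay_h": self.onset_delay.to_dict(),
            "hub": self.hub_flag.astype(bool).to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _group_delay(group: int, grid: Sequence[float]) -> float:
    """Input lag placing the log2FC = 1 crossing just before the
    group's onset time: the midpoint of the preceding grid interval."""
    onset = ONSET_TIMES_H[group - 1]
    grid = sorted(grid)
    i = grid.index(onset)
    prev = grid[i - 1] if i > 0 else 0.0
    # rounded onto the integrator's step grid so the input step falls
    # exactly on an integration step boundary
    return round((prev + onset) / 2.0, 2)


def arabidopsis_config(**overrides) -> NetworkConfig:
    """The study's default 20-TF network: five hubs, two delayed
    repressors (group 3), incoherent feed-forward loops over the input."""
    names = tuple(DEFAULT_TF_GROUPS)
    cfg = NetworkConfig(
        n_nodes=20, n_hubs=5, node_names=names, hubs=DEFAULT_HUBS,
        repressors=DEFAULT_REPRESSORS, onset_groups=DEFAULT_TF_GROUPS,
    )
    return replace(cfg, **overrides)


def make_ground_truth(config: NetworkConfig, seed: int) -> GroundTruthNetwork:
    """Draw a signed hub-dominated network with delayed repressors.

    Out-degree is concentrated on the hub nodes; repressor out-edges
    carry strictly negative weights; repressors sit in a later onset
    group than the activator hubs (the delay on the inhibitory arm of
    the feed-forward loop).  Requested incoherent FFLs are planted and
    verified before returning.
    """
    if config.n_nodes < 3:
        raise ConfigurationError("need at least 3 nodes")
    if config.n_hubs > config.n_nodes:
        raise ConfigurationError("more hubs than nodes")
    if config.require_incoherent_ffl and not config.repressors:
        raise ConfigurationError(
            "an incoherent feed-forward loop needs at least one repressor")

    rng = _substream(seed, "ground_truth")
    names = list(config.node_names
                 or (f"TF{i:02d}" for i in range(1, config.n_nodes + 1)))
    if len(names) != config.n_nodes:
        raise ConfigurationError("node_names length != n_nodes")
    if config.hubs is not None:
        hubs = list(config.hubs)
    else:
        hubs = sorted(rng.choice(names, size=config.n_hubs, replace=False))
    unknown = set(hubs) | set(config.repressors) - set(names)
    if not set(hubs) <= set(names) or not set(config.repressors) <= set(names):
        raise ConfigurationError(f"unknown node ids: {sorted(unknown)}")
    repressors = set(config.repressors)

    if config.onset_groups is not None:
        groups = dict(config.onset_groups)
    else:
        # random assignment; repressors forced into group 3 so that the
        # inhibitory arm lags the activator hubs
        groups = {n: int(rng.integers(1, 5)) for n in names}
        for r in repressors:
            groups[r] = 3
        for h in hubs:
            if h not in repressors:
                groups[h] = min(groups[h], 2)

    idx = {n: i for i, n in enumerate(names)}
    n = config.n_nodes
    adj = np.zeros((n, n))

    def draw_weight(source: str) -> float:
        mag = config.weight_scale * rng.uniform(0.5, 1.0)
        return -mag if source in repressors else mag

    for h in hubs:
        for t in names:
            if t != h and rng.random() < config.hub_out_prob:
                adj[idx[h], idx[t]] = draw_weight(h)
    for s in names:
        if s in hubs:
            continue
        for t in names:
            if t != s and rng.random() < config.background_edge_prob:
                adj[idx[s], idx[t]] = draw_weight(s)

    # plant the requested incoherent FFL: activator hub X → repressor Y,
    # Y ⊣ Z, X → Z
    if config.require_incoherent_ffl:
        act_hubs = [h for h in hubs if h not in repressors] or \
            [x for x in names if x not in repressors]
        x = act_hubs[0]
        y = sorted(repressors)[0]
        z = next(t for t in names if t not in (x, y))
        adj[idx[x], idx[y]] = abs(adj[idx[x], idx[y]]) or \
            config.weight_scale * 0.8
        adj[idx[y], idx[z]] = -(abs(adj[idx[y], idx[z]]) or
                                config.weight_scale * 0.8)
        adj[idx[x], idx[z]] = abs(adj[idx[x], idx[z]]) or \
            config.weight_scale * 0.8

    # cap summed incoming activation/repression per target so that
    # network input alone can never carry a node over the onset
    # threshold (first crossings stay stimulus-driven) and production
    # rates stay positive
    for j in range(n):
        col = adj[:, j]
        for mask, cap in ((col > 0, config.activation_cap),
                          (col < 0, config.repression_cap)):
            if cap is None:
                continue
            tot = np.abs(col[mask]).sum()
            limit = cap * config.basal
            if tot > limit:
                col[mask] *= limit / tot
        adj[:, j] = col

    adjacency = pd.DataFrame(adj, index=names, columns=names)
    grp = pd.Series({m: groups[m] for m in names})
    net = GroundTruthNetwork(
        nodes=names,
        adjacency=adjacency,
        onset_delay=pd.Series({m: _group_delay(groups[m], config.time_grid_h)
                               for m in names}),
        hub_flag=pd.Series({m: m in hubs for m in names}),
        basal=pd.Series(config.basal, index=names),
        decay=pd.Series(config.decay, index=names),
        onset_group=grp,
        max_lfc=pd.Series({m: _GROUP_MAX_LFC[groups[m]] for m in names}),
    )
    if config.require_incoherent_ffl and not net.incoherent_ffls():
        raise ConfigurationError("failed to plant an incoherent FFL")
    return net


# ---------------------------------------------------------------------------
# deterministic transcription kinetics


@dataclass(frozen=True)
class Stimulus:
    """Step stress input at t0; optionally decaying with a half-life."""

    t0: float = 0.0
    decay_halflife_h: float | None = None

    def level(self, t: np.ndarray, delay: float) -> np.ndarray:
        on = (t >= self.t0 + delay).astype(float)
        if self.decay_halflife_h is not None:
            dt = np.maximum(t - self.t0 - delay, 0.0)
            on = on * 0.5 ** (dt / self.decay_halflife_h)
        return on


@dataclass(frozen=True)
class Perturbation:
    """Clamp one node at a fixed level from t0 on (inducible
    overexpression: the transgene product is held high regardless of
    the endogenous dynamics)."""

    node: str
    level: float
    t0: float = 0.0


@dataclass
class Trajectories:
    """Dense per-node concentration trajectories x_i(t)."""

    times: np.ndarray
    values: pd.DataFrame          # n_times × n_nodes
    stimulus: Stimulus | None
    perturbation: Perturbation | None

    def at(self, t: float) -> pd.Series:
        """Concentrations at time t (linear interpolation)."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"time {t} outside simulated span "
                             f"[{self.times[0]}, {self.times[-1]}]")
        out = {c: np.interp(t, self.times, self.values[c].values)
               for c in self.values.columns}
        return pd.Series(out)


_HILL_N = 3.0
_HILL_K = 8.0   # fold-change units relative to the unstressed steady state


def simulate_dynamics(network: GroundTruthNetwork,
                      stimulus: Stimulus | None = None,
                      perturbation: Perturbation | None = None,
                      grid: Sequence[float] | None = None,
                      dt: float = 0.01) -> Trajectories:
    """Integrate dx_i/dt = basal_i + stim_i(t) + Σ act − Σ rep − δ_i x_i.

    Regulation is saturating: a regulator at fold-level u contributes
    w·u²/(K²+u²), so it is silent near baseline and contributes ≈ w
    once strongly induced.  The stress input reaches node i only after
    its onset delay, and its amplitude is basal·(2^max_lfc − 1) so the
    stimulated steady state sits max_lfc log2 units above baseline.
    Fixed-step RK4; clamped nodes are pinned after each step.
    """
    grid = np.asarray(grid if grid is not None else [0.0, 48.0], float)
    t_end = float(grid.max())
    names = network.nodes
    n = len(names)
    basal = network.basal.values.astype(float)
    decay = network.decay.values.astype(float)
    xss = basal / decay
    adj = network.adjacency.values  # adj[i, j]: regulator i → target j
    delays = network.onset_delay.values
    amp = basal * (2.0 ** network.max_lfc.values - 1.0)

    clamp_idx = None
    if perturbation is not None:
        if perturbation.node not in names:
            raise ConfigurationError(f"unknown node {perturbation.node!r}")
        clamp_idx = names.index(perturbation.node)

    n_steps = int(np.ceil(t_end / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)

    def f(x: np.ndarray, stim: np.ndarray) -> np.ndarray:
        u = x / xss
        hill = u**_HILL_N / (_HILL_K**_HILL_N + u**_HILL_N)
        reg = adj.T @ hill          # signed regulation onto each target
        return basal + reg + stim - decay * x

    x = xss.copy()
    if clamp_idx is not None and perturbation.t0 <= 0:
        x[clamp_idx] = perturbation.level
    out = np.empty((n_steps + 1, n))
    out[0] = x
    for k in range(n_steps):
        t = times[k]
        # the step input is gated at the step midpoint and held constant
        # within the step, so delay discontinuities aligned with step
        # boundaries are integrated exactly
        if stimulus is not None:
            t_mid = t + dt / 2
            stim = amp * np.array(
                [stimulus.level(np.array([t_mid]), d)[0] for d in delays])
        else:
            stim = np.zeros(n)
        k1 = f(x, stim)
        k2 = f(x + dt / 2 * k1, stim)
        k3 = f(x + dt / 2 * k2, stim)
        k4 = f(x + dt * k3, stim)
        x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if clamp_idx is not None and times[k + 1] >= perturbation.t0:
            x[clamp_idx] = perturbation.level
        if not np.all(np.isfinite(x)):
            bad = names[int(np.argmax(~np.isfinite(x)))]
            raise IntegrationError(
                f"non-finite state for node {bad!r} at t={times[k+1]:.3f} h")
        if np.any(x < -1e-9):
            bad = names[int(np.argmin(x))]
            raise IntegrationError(
                f"negative concentration for node {bad!r} "
                f"at t={times[k+1]:.3f} h")
        out[k + 1] = x

    # stimulus delays are step discontinuities; resample exactly on a
    # grid that includes the requested sampling times
    values = pd.DataFrame(out, index=times, columns=names)
    return Trajectories(times=times, values=values,
                        stimulus=stimulus, perturbation=perturbation)


def noiseless_log2fc(network: GroundTruthNetwork,
                     grid: Sequence[float],
                     stimulus: Stimulus | None = None) -> pd.DataFrame:
    """Gene × time log2(stress/control) from the deterministic kinetics."""
    stimulus = stimulus or Stimulus()
    g = sorted(grid)
    stress = simulate_dynamics(network, stimulus=stimulus, grid=g)
    control = simulate_dynamics(network, stimulus=None, grid=g)
    rows = {}
    for t in g:
        rows[t] = np.log2(stress.at(t) / control.at(t))
    return pd.DataFrame(rows).T  # time × gene -> index time


# ---------------------------------------------------------------------------
# probe-count readout


def simulate_nanostring(trajectories: Mapping[tuple[str, str], Trajectories],
                        design: pd.DataFrame,
                        config: SimulationConfig,
                        seed: int) -> CountTable:
    """Negative-binomial probe counts for a sampling design.

    ``design`` needs columns sample_id, line, treatment, time_h, repeat;
    each (line, treatment) pair must have an entry in ``trajectories``.
    Count mean = gain · x_i(t) · size_factor(sample) · batch(repeat);
    the five housekeeping genes have condition-independent means and see
    the same sample and batch factors, which is what makes them usable
    as normalizers downstream.
    """
    rng = _substream(seed, "nanostring")
    required = {"sample_id", "line", "treatment", "time_h", "repeat"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design missing columns: {sorted(missing)}")

    some_traj = next(iter(trajectories.values()))
    genes = list(some_traj.values.columns)
    hk = list(config.housekeeping_ids)
    hk_means = dict(zip(hk, config.housekeeping_means))

    repeats = sorted(design["repeat"].unique())
    batch = {r: 2.0 ** rng.normal(0.0, config.batch_log2_sd) for r in repeats}

    counts = {}
    meta_rows = {}
    disp = config.nb_dispersion
    for _, row in design.iterrows():
        key = (row["line"], row["treatment"])
        if key not in trajectories:
            raise ValueError(f"no trajectory for condition {key}")
        x = trajectories[key].at(float(row["time_h"]))
        sf = 2.0 ** rng.normal(0.0, config.size_factor_log2_sd)
        mu_net = config.count_gain * x.values * sf * batch[row["repeat"]]
        mu_hk = np.array([hk_means[g] for g in hk]) * sf * batch[row["repeat"]]
        mu = np.concatenate([mu_net, mu_hk])
        if disp > 1e-9:
            lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
        else:
            lam = mu
        counts[row["sample_id"]] = rng.poisson(lam)
        meta_rows[row["sample_id"]] = {
            "line": row["line"], "treatment": row["treatment"],
            "time_h": float(row["time_h"]), "repeat": row["repeat"],
        }

    counts_df = pd.DataFrame(counts, index=genes + hk)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample_id"
    return CountTable(counts=counts_df, meta=meta)


def stress_design(config: SimulationConfig, line: str = "wt") -> pd.DataFrame:
    """Paired stress/control design over the full time grid."""
    rows = []
    for rep in range(1, config.n_repeats + 1):
        for t in config.time_grid_h:
            for trt in ("control", "mannitol"):
                rows.append({
                    "sample_id": f"{line}_{trt}_{t}h_r{rep}",
                    "line": line, "treatment": trt, "time_h": t,
                    "repeat": rep,
                })
    return pd.DataFrame(rows)


def gof_design(config: SimulationConfig, lines: Sequence[str],
               control_line: str = "GFP-GR",
               times: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 24.0),
               ) -> pd.DataFrame:
    """Dexamethasone-induction design: each overexpression line plus the
    control line, sampled at the induction time points."""
    rows = []
    for rep in range(1, config.n_repeats + 1):
        for ln in list(lines) + [control_line]:
            for t in times:
                rows.append({
                    "sample_id": f"{ln}_dex_{t}h_r{rep}",
                    "line": ln, "treatment": "dex", "time_h": t,
                    "repeat": rep,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transient expression assays


@dataclass
class TEAMeasurement:
    """Raw luminescence replicates for one construct in one experiment."""

    effectors: tuple[str, ...]    # () = neutral control construct
    promoter: str
    experiment: int
    activities: np.ndarray


def tea_single_weight(network: GroundTruthNetwork, effector: str,
                      promoter: str) -> float:
    """Effective TEA weight of one effector on a promoter.

    Adjacency weights are mapped onto the relative-luminescence scale:
    a full-strength activator multiplies the reporter ~3x (weight +2),
    a full-strength repressor ~0.3x (weight −0.7).
    """
    w = network.adjacency.loc[effector, promoter]
    ref = np.abs(network.adjacency.values)
    ref = ref[ref > 0].mean() if (ref > 0).any() else 1.0
    scale = min(abs(w) / ref, 1.5)
    return float(2.0 * scale if w > 0 else -0.7 * scale if w < 0 else 0.0)


def simulate_tea(network: GroundTruthNetwork,
                 effectors: Sequence[str],
                 promoter: str,
                 n_reps: int,
                 config: SimulationConfig,
                 seed: int,
                 n_experiments: int = 3,
                 pair_weights: Mapping[tuple[frozenset, str], float] | None = None,
                 ) -> list[TEAMeasurement]:
    """Simulate one TEA construct set (plus its neutral controls).

    Replicate relative activity = max(1 + Σ effective weights, 0.05)
    × lognormal noise; the raw luminescence is that ratio times an
    experiment-level base level, and a neutral-control replicate set is
    emitted per experiment so the batch normalization is exercised.
    """
    effectors = tuple(effectors)
    if not 1 <= len(effectors) <= 2:
        raise ConfigurationError("1 or 2 effectors required")
    for node in effectors + (promoter,):
        if node not in network.nodes:
            raise ConfigurationError(f"unknown node {node!r}")
    rng = _substream(seed, f"tea:{'+'.join(effectors)}->{promoter}")

    key = (frozenset(effectors), promoter)
    if pair_weights and key in pair_weights:
        total = pair_weights[key]
    else:
        total = sum(tea_single_weight(network, e, promoter)
                    for e in effectors)
    ratio = max(1.0 + total, 0.05)

    sigma = np.sqrt(np.log1p(config.tea_cv ** 2))
    out = []
    for exp in range(1, n_experiments + 1):
        base = config.tea_base_luminescence * 2.0 ** rng.normal(0, 0.5)
        noise = rng.lognormal(-sigma**2 / 2, sigma, size=n_reps)
        ctrl_noise = rng.lognormal(-sigma**2 / 2, sigma, size=n_reps)
        out.append(TEAMeasurement(effectors, promoter, exp,
                                  base * ratio * noise))
        out.append(TEAMeasurement((), promoter, exp, base * ctrl_noise))
    return out


def simulate_tea_campaign(network: GroundTruthNetwork,
                          edges: pd.DataFrame,
                          config: SimulationConfig,
                          seed: int,
                          n_reps: int = 4,
                          pair_weights: Mapping[tuple[frozenset, str], float]
                          | None = None) -> pd.DataFrame:
    """TEA table covering every edge (regulator → target promoter) of an
    edge list, one construct set per edge, as a long-form table."""
    rows = []
    for k, (_, e) in enumerate(edges.iterrows()):
        ms = simulate_tea(network, (e["source"],), e["target"], n_reps,
                          config, seed + 1000 + k, pair_weights=pair_weights)
        for m in ms:
            for i, a in enumerate(m.activities):
                rows.append({
                    "effector1": m.effectors[0] if m.effectors else "GUS",
                    "effector2": (m.effectors[1]
                                  if len(m.effectors) > 1 else ""),
                    "promoter": m.promoter, "experiment": m.experiment,
                    "replicate": i + 1, "activity": a,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plant phenotypes


def _leaf_profile(n_leaves: int) -> np.ndarray:
    """Fixed fraction of rosette area per leaf position (old → young):
    middle positions largest, youngest leaves still expanding."""
    pos = np.arange(1, n_leaves + 1)
    prof = np.exp(-0.5 * ((pos - 0.35 * n_leaves) / (0.35 * n_leaves)) ** 2)
    return prof / prof.sum()


def simulate_phenotypes(config: SimulationConfig,
                        genotype_effects: Mapping[str, tuple[float, float]],
                        seed: int,
                        leaf_effects: Mapping[str, Mapping[int, float]]
                        | None = None,
                        cross_effects: Mapping[str, float] | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plant rosette/leaf/cell phenotypes plus genetic-cross areas.

    ``genotype_effects[line] = (control_mult, stress_mult)`` multiply the
    wild-type mean area; the global stress effect is
    ``stress_area_multiplier`` (0.70 ⇒ the 30 % wild-type reduction).
    Rosette areas are log-normal around the genotype × treatment ×
    repeat mean; leaf areas decompose the rosette over a fixed
    leaf-position profile (optionally distorted per genotype by
    ``leaf_effects``); a pavement-cell sample is drawn for leaf 3.

    Crosses: ``cross_effects[line]`` is the log2 area effect of one
    single cross versus the reference; the double-cross mean is the sum
    of the single-cross effects plus the configured interaction
    coefficient.  Returns (plants, crosses).
    """
    if "wt" not in genotype_effects:
        raise ConfigurationError("genotype_effects must include 'wt'")
    rng = _substream(seed, "phenotypes")
    profile = _leaf_profile(config.n_leaves)
    base_log2 = np.log2(config.base_rosette_mm2)
    stress_log2 = np.log2(config.stress_area_multiplier)
    cell_sigma = 0.35

    plant_rows = []
    for rep in range(1, config.n_repeats + 1):
        rep_eff = rng.normal(0.0, config.repeat_log2_sd)
        for line, (mc, ms) in genotype_effects.items():
            if not (0 < mc <= 2 and 0 < ms <= 2):
                raise ConfigurationError(
                    f"multipliers for {line!r} must lie in (0, 2]")
            for trt, mult in (("control", mc),
                              ("mannitol", ms)):
                mu = base_log2 + np.log2(mult) + rep_eff
                if trt == "mannitol":
                    mu += stress_log2
                for p in range(1, config.n_plants + 1):
                    area = 2.0 ** rng.normal(mu, config.area_log2_sd)
                    frac = profile.copy()
                    if leaf_effects and line in leaf_effects:
                        for leaf_pos, f in leaf_effects[line].items():
                            frac[leaf_pos - 1] *= f
                    frac = frac * rng.lognormal(0, 0.05, size=frac.size)
                    frac /= frac.sum()
                    leaves = area * frac
                    cells = rng.lognormal(
                        np.log(config.mean_cell_area_um2) - cell_sigma**2 / 2,
                        cell_sigma, size=config.cells_per_leaf)
                    row = {"genotype": line, "treatment": trt, "repeat": rep,
                           "plant_id": f"{line}_{trt}_r{rep}_p{p}",
                           "rosette_mm2": area}
                    row.update({f"leaf_{i+1}_mm2": leaves[i]
                                for i in range(config.n_leaves)})
                    row["cell_areas_um2"] = cells
                    plant_rows.append(row)
    plants = pd.DataFrame(plant_rows)

    cross_rows = []
    if config.interaction_coefficients:
        if cross_effects is None:
            raise ConfigurationError(
                "interaction_coefficients given without cross_effects")
        for (l1, l2), gamma in config.interaction_coefficients.items():
            a1, a2 = cross_effects[l1], cross_effects[l2]
            for rep in range(1, config.n_repeats + 1):
                rep_eff = rng.normal(0.0, config.repeat_log2_sd)
                cells = [
                    (f"{l1}x{l2}", 1, 1, a1 + a2 + gamma),
                    (f"{l1}xcontrol", 1, 0, a1),
                    (f"{l2}xcontrol", 0, 1, a2),
                    ("control", 0, 0, 0.0),
                ]
                for geno, p1, p2, eff in cells:
                    mu = base_log2 + eff + rep_eff
                    for p in range(1, config.n_plants_cross + 1):
                        cross_rows.append({
                            "cross": f"{l1}x{l2}", "genotype": geno,
                            "p1": p1, "p2": p2, "repeat": rep,
                            "rosette_mm2":
                                2.0 ** rng.normal(mu, config.area_log2_sd),
                        })
    crosses = pd.DataFrame(cross_rows)
    return plants, crosses
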