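# Methods

## The generative model

The ground truth is a directed, signed, weighted network over 20
transcription factors (TFs). Five designated hubs (ERF6, ERF8, ERF9,
ERF59, ERF98) carry most of the out-degree; ERF8 and ERF9 act purely as
repressors (all their out-weights negative). Each node carries a basal
transcription rate `basal` (concentration·h⁻¹, default 1), a first-order
decay `decay` (h⁻¹, default 2, i.e. a ~21 min half-life), an onset delay
(h) and a peak induction amplitude.

Concentrations evolve by

    dx_i/dt = basal_i + stim_i(t) + Σ_j w_ji · H(u_j) − decay_i · x_i

where `u_j = x_j / x_j(0)` is the regulator's fold level,
`H(u) = u³/(K³ + u³)` a saturating Hill term with `K = 8` fold and Hill
coefficient 3, and `w_ji` the signed edge weight (repression enters with
negative `w`). The switch-like exponent keeps regulation silent near
baseline (`H(1) ≈ 0.002`) and near-saturated for a strongly induced or
clamped regulator (`H(32) ≈ 0.98`), so a perturbed regulator produces an
approximately additive production change ≈ `w` in its direct targets
while second-order (two-step) effects stay small — the property that
makes direct edges recoverable from a perturbation screen.

**Stress input.** Stress is a step at t = 0 whose effect reaches node i
only after its onset delay; the input amplitude is
`basal·(2^maxlfc − 1)`, so the stimulated steady state sits `maxlfc`
log2 units above baseline (group amplitudes 6, 4, 3, 5, strongest for
the earliest wave). Delays are the midpoints of the sampling intervals
preceding the four onset times (0.67, 1, 2, 4 h), rounded onto the
integrator grid. Per-target caps on summed incoming weight (activation
≤ 0.8·basal, repression ≤ 0.9·basal) guarantee that network input alone
can never push a node across the log2FC = 1 threshold and that
production rates stay positive; the first threshold crossing is
therefore always driven by the node's own delayed input, which is what
makes the four onset groups exactly recoverable from noiseless
dynamics. The repressors' delay (group 3) behind the activator hubs
(group 1) is the delay on the inhibitory arm of the planted incoherent
feed-forward loops.

**Integration.** Fixed-step RK4, dt = 0.01 h. The step input is gated at
each step's midpoint and held constant within the step, so a delay
discontinuity aligned with a step boundary is integrated exactly (an
unregulated node under a delayed step matches the closed form
`basal/δ + (A/δ)(1 − e^{−δ(t−lag)})` to better than 0.1 % relative).
Non-finite or negative states raise an error naming node and time.
Inducible overexpression is modelled as clamping: the perturbed node is
pinned at a fixed level (default 32× its resting level) from induction
onward.

**Counts.** Probe counts are negative-binomial via a gamma–Poisson
mixture: mean = `gain · x_i(t) · size_factor(sample) · batch(repeat)`
with gain 400 counts per concentration unit, log-normal size factors
(log2 SD 0.2), a repeat-level batch factor (log2 SD 0.15) shared by all
of a repeat's samples, and per-gene dispersion 0.05 (variance
`m + 0.05 m²`). Five housekeeping genes have condition-independent
means (600–1500 counts) and see the same sample and batch factors —
exactly the assumption the geometric-mean normalization needs.
Dispersion → 0 degenerates to Poisson.

**TEA.** A construct's expected relative activity is
`max(1 + Σ effective weights, 0.05)`; adjacency weights map to the
luminescence scale as ≈ +2 for a full-strength activator (3× reporter)
and ≈ −0.7 for a repressor (0.3×). Raw replicate luminescence is that
ratio times an experiment-level base level (log-normal around 1000) and
multiplicative replicate noise (CV 0.25); every experiment includes a
neutral-control replicate set, so batch normalization is part of the
analysis path, not assumed away. Pair constructs default to the sum of
the single weights; per-(pair, promoter) overrides create the emergent
and enhancement scenarios.

**Phenotypes.** Rosette areas are log-normal (log2 SD 0.30) around a
genotype × treatment × repeat mean: wild-type base 90 mm² at 22 days
after stratification, a global stress multiplier 0.70 (the 30 %
wild-type reduction), per-line multiplicative effects under control and
stress, and a repeat effect (log2 SD 0.10). Leaf series decompose each
rosette over a fixed 10-position profile (mid positions largest);
pavement-cell samples draw 100 log-normal cell areas (mean 1600 μm²)
per third leaf. Crosses: the double-cross log2 mean is the sum of the
single-cross effects plus a configurable interaction coefficient γ;
n = 10 plants per genotype × condition (8 for crosses), 3 repeats
throughout.

One root seed; every dataset draws from an independent sub-stream keyed
by a dataset label, so adding a dataset never shifts another's draws.

## Analysis choices

* **Normalization** — per-sample size factor = geometric mean of the
  sample's housekeeping counts over the grand geometric mean (factors
  multiply to 1); values = log2((count + 0.5)/size factor). Pseudocount
  0.5 guards zero counts; the scale-invariance of the procedure is
  exact on the pure size-factor path. qPCR fold changes assume 100 %
  efficiency (fold = 2^ΔΔCt).
* **Time-course tests** — paired (by repeat) two-sided t-tests per gene
  and time on log2 values; BH adjustment across genes within each time
  point by default (configurable to a global family). Zero variance
  with zero difference yields p = 1. Onset threshold is strict
  (log2FC > 1); values after the first crossing are ignored. A late
  "rebound" requires a strict interior local minimum over 12–48 h
  (ties count as sustained) — on noisy series small dips satisfy this,
  so the scenario split is the most noise-sensitive readout.
* **Edge calling** — per target gene, a fixed-effect linear model
  (line, time, line×time, repeat block) fitted jointly for all genes
  via the shared design matrix; Wald contrasts line − control per time;
  BH over the whole per-line family (targets × times). The repeat
  enters as a fixed block rather than a random effect: with three
  repeats the variance component is barely estimable, and in balanced
  designs the contrast estimates coincide. The regulator's own probe
  (which mostly reads the transgene) is excluded from its target
  family. Only FDR < 0.1 defines an edge; no fold-change filter.
* **TEA calls** — one-sample two-sided t-test of experiment-mean log2
  ratios against 0 at α = 0.05 (the assay's significance rule is a
  package choice, configurable). The pairwise scenario tree uses a
  log2 margin of 0.5 (≈1.4×) and is symmetric in the two effectors
  (tie on |mean| broken toward the larger signed mean). A TEA verdict
  overrides the in-planta provisional sign, because the assay isolates
  the TF from indirect in-planta routes.
* **Core selection** — greedy by descending out-degree (ties
  lexicographic) until 85 % of edges are covered. The coverage default
  is a formalization of a descriptive choice and is flagged as such in
  reports.
* **Motifs** — FFLs by direct enumeration over edge pairs; cycles via
  bounded simple-cycle search; both verified against brute force in the
  test suite. Parallel time-stamped edges are collapsed (earliest sign)
  before topology analysis; self-loops cannot occur by construction.
* **Phenotype models** — all area models on log2 scale with a fixed
  repeat block. Pairwise cell-mean comparisons use the studentized-range
  (Tukey) distribution on the residual mean square. Leaf-series
  contrasts use a seeded Monte-Carlo max-|t| (Dunnett-type) family-wise
  adjustment across genotypes within each leaf (a deliberate
  replacement for mixed models with structured covariance and
  Kenward–Roger degrees of freedom; the qualitative question — which
  leaves differ — is the test surface). Adjusted p-values are floored
  at the raw p. Cell number = leaf area / mean sampled cell area with
  explicit mm²→μm² conversion. `expected_double_reduction` is the
  additivity hypothesis on the reduction scale, exactly
  1 − (1−r1)(1−r2).

## What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on:
overdispersed counts with shared normalization factors, repeat-level
batch effects, sequential threshold crossings, saturating and signed
regulation, batch-structured luminescence ratios, multiplicative growth
effects and log-scale epistasis. It does not emulate probe-level
chemistry, promoter sequence, protein or post-translational layers,
development-dependent expression (leaf stages), or image-derived
measurement error; passing tests therefore demonstrate the correctness
and calibration of the inference machinery under the stated model, not
robustness to those unmodelled features of real data.

## Problem sizes used in the checks

Chosen as the package's reporting scale: onset recovery on the 20-TF
default network (noiseless, exact); edge-caller null calibration on 500
jointly-fitted null genes; edge precision/recall pooled over three
seeded full GOF screens (20 lines × 5 times × 3 repeats each) on a
sparser, strong-weight network (weight scale 3, activation cap lifted,
hub out-probability 0.4) — strong direct effects are the regime where
direct-edge recovery is a meaningful claim, and the evaluation counts
only 1–4 h calls; TEA sign agreement over 100 seeded campaigns of 20
constructs; interaction-coefficient recovery and null false-positive
rate over 200 runs each (γ = +0.5 and 0).

## Known limitations

* Precision of edge calling is bounded by genuine indirect (two-step)
  regulation, which the perturbation design cannot distinguish from
  direct action; the Hill nonlinearity suppresses but does not remove
  it, and denser or stronger cross-regulation lowers precision.
* The late-behaviour classifier takes any strict interior dip as a
  rebound; with three repeats of count noise this over-calls rebounds
  relative to the underlying kinetics.
* The fixed-effect repeat block slightly understates uncertainty
  relative to a random-effects treatment when repeat variance is large
  and designs are unbalanced.
* TEA pair scenarios are a formalized decision tree over verbal
  categories; boundary cases near the 0.5 log2 margin are assigned
  deterministically, not probabilistically.
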