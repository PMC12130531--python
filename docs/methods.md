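# Methods

## Model

`netdasc` represents a signaling network as a signed directed graph
(activation / inhibition links) and endows it with normalized logic-based
ODE dynamics on the unit hypercube. For node *i* with activity
*x<sub>i</sub>* ∈ [0,1]:

    dx_i/dt = (e_i · F_i(x) − x_i) / τ_i

    F_i(x) = A_i(x) · Π_{k ∈ inhibitors(i)} (1 − H(x_k))
    A_i(x) = Σ_{j ∈ activators(i)} w_ij H(x_j) / Σ_j w_ij   (1 if no activators)
    H(x)   = x^n (1 + K^n) / (x^n + K^n)

The Hill response is normalized so that H(0) = 0 and H(1) = 1, which keeps
the drive — and therefore every fixed point — inside [0,1]: 0 is minimal
and 1 maximal activity, for every node on a common scale. Activation is a
weighted mean of activator responses (saturating, not additive beyond 1);
inhibition is a product of complementary responses, so a single saturated
inhibitor silences its target. Link weights enter only the activation
mean; inhibitors act unweighted, each contributing its full complementary
factor.

**Expression enters as capacity.** The patient-specific quantity is the
per-node capacity *e<sub>i</sub>*: the sample's normalized expression of
the corresponding gene (0.5 for nodes without a measured transcript —
complexes, families, chemicals, phenotype nodes). The capacity multiplies
the drive, bounding the node's attainable steady-state activity. The
alternative — seeding expression into the initial state — would be erased
by design, because initial states are randomized; shaping the vector
field is the only way a per-patient profile can influence where
trajectories end up. Input-free nodes have F ≡ 1 and relax exactly to
their capacity, which is how upstream expression is injected into the
network.

**Assumptions.** Deterministic continuous dynamics; a single global Hill
shape (n, K) and time constant for all links/nodes unless overridden;
regulation is monotone in each regulator; no delays, no stochastic terms,
no synthesis/degradation asymmetry beyond the single relaxation rate.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| τ (`tau`) | relaxation time constant | 1.0 (dimensionless time) | sets the time scale only; fixed points are τ-free |
| n (`hill_n`) | Hill steepness | 3 | sigmoidal but not switch-like |
| K (`hill_k`) | Hill half-response threshold | 0.5 | centered on the activity scale |
| w (`weight`) | link weight (activators) | 1.0 | relative influence within the activation mean |
| `default_capacity` | e for unmeasured nodes | 0.5 | neutral: neither silences nor saturates hubs |
| `lower_q`, `upper_q` | winsorizing quantiles for normalization | 0.01, 0.99 | guards single-sample outliers; (0,1) = plain min–max |
| `n_init` | random initial states per sample | 1000 | desk scale; production scale is a config value, not a code change |
| `dt` | RK4 step | 0.1 | comfortably inside the stability region for τ = 1 |
| `t_max` | integration horizon | 100 | ≈ 100 relaxation times |
| `tol` | convergence threshold on max\|dx/dt\| | 1e-6 | endpoint-only criterion |
| `alpha` | BH FDR level | 0.05 | |
| `min_effect` | median-difference gate | 0.1 | one tenth of the activity scale |
| `max_per_group` | pooled-draw cap per group/node | 10 000 | deterministic stride thinning |

## Numerical choices

- **Fixed-step RK4** rather than an adaptive stepper: identical arithmetic
  on every platform and for every batch partitioning, which makes runs
  bit-reproducible. Step-size error affects only the transient; fixed
  points are exact zeros of the vector field, and integration stops on
  max|dx/dt| < tol evaluated on the true derivative.
- States are clamped to [0,1] after each step as a guard against
  overshoot at aggressive step sizes; at the default dt the clamp never
  fires (asserted in tests, counted in `clamp_events`).
- The inhibition product is computed as exp(Σ log(1−H)); log(0) → −inf →
  exp → 0 handles fully saturated inhibitors exactly.
- Convergence is endpoint-only. Networks with strong negative feedback
  can oscillate and never meet the tolerance; the run then stops at
  `t_max`, the endpoint is still recorded, and a warning fires when the
  convergence rate drops below 99%. The empirical distribution then
  includes points on limit cycles — a faithful summary of sustained
  dynamics, not an error state.
- **Seeding**: each Monte-Carlo run draws its initial state from a
  substream keyed by (seed, run index), so results are independent of
  batch size and of how runs are distributed over workers; per-sample
  seeds derive from (random_state, sample position).
- Normalization degenerate case: a gene with zero cross-sample range maps
  to 0.5 everywhere. Min–max output always attains 0 and 1 per gene, so
  re-normalizing with quantiles (0,1) is the identity.

## DASC statistic

Within a cohort, all Monte-Carlo draws of all samples in a group are
pooled per node (samples concatenated in sorted-id order; deterministic
stride thinning bounds memory). Nodes are scored with the two-sample KS
statistic D on the pooled ECDFs, a median-difference effect size
(group B − group A), BH adjustment across nodes, and the call rule
q < α AND |Δmedian| ≥ min_effect.

Pooled draws are **not** independent across the runs of one sample, so a
p-value computed at the pooled draw count would be wildly anti-
conservative (any between-sample noise becomes "significant" at n of
thousands). The asymptotic KS p is therefore evaluated at an effective
sample size equal to the number of patient samples per group — the number
of independent units in the pool. This restores type-I calibration of the
BH layer (verified under the null in the test suite) while D itself still
compares the full pooled distributions. `effective_n='draws'` gives the
literal pooled-count p for comparison. Either way, p-values on pooled
dependent draws are heuristic ranks; the effect gate and the cross-cohort
intersection (same node called, same direction, in every cohort) carry
the inferential weight, and the output metadata says so.

## Synthetic data: what it emulates, what it does not

The generator emulates the *structure* of a multi-cohort differential
study: an Erdős–Rényi-style signed digraph (optionally with spliced
chain/toggle motifs), a baseline capacity per node (uniform 0.2–0.8), a
+shift capacity offset at planted nodes in group B, per-sample Gaussian
observation noise on the [0,1] scale, and a per-gene affine back-transform
to a raw expression scale so the normalization stage has real work to do.

Two deliberate design choices:

- **Planted nodes are made sources** (their in-links are stripped after
  motif insertion). A capacity shift at an internal node is attenuated by
  its own drive (Δx* = shift · F), so the detectable effect would depend
  on arbitrary topology; at a source the shift enters at full strength as
  group-shifted upstream expression and then propagates downstream
  through the dynamics.
- **Multi-cohort studies re-draw the topology per cohort** while sharing
  the planted node ids. Downstream secondary shifts are then
  cohort-specific and are removed by the intersection, while planted
  sources survive in all cohorts — this is exactly the role the
  cross-cohort step plays on real data, where cohorts differ in
  composition and noise rather than topology.

Not emulated: RNA-seq count statistics (library sizes, negative-binomial
dispersion), batch effects, correlated noise between genes, missing
measurements, scale-free topology, and any relation between network
position and expression level. Passing the recovery benchmarks therefore
shows that the *pipeline machinery* (normalization → parameter binding →
integration → pooling → KS/BH/gate → intersection) is correct and
calibrated under its own model; it does not certify performance on real
cohorts, whose headline results additionally depend on database snapshots
and preprocessing outside this package's scope.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use desk-scale study
conditions chosen once: recovery benchmark 50 nodes / density 0.04 /
5 planted / shift 0.3 / 20 samples per group / n_init 200 / 3 cohorts /
10 master seeds; null calibration 30 nodes / 8 samples per group /
n_init 50 / 50 replicates (the calibration of the BH layer does not
depend on cohort scale); oracle suites 500 random pool pairs and the
exhaustive set of 2×2 tables with total ≤ 40.

## Clinical module conventions

- H-score inputs are percentages summing to 100 (tolerance 1e-9); the
  score is linear, range 0–300.
- `TwoByTwo` counts follow the printed-table reading order (group-1 high,
  group-1 low, group-2 high, group-2 low); column percentages are
  reported at full precision with a 1-decimal display accessor.
- Method `auto` picks Fisher's exact test when any expected count < 5,
  else the uncorrected Pearson chi-square; Yates correction is available
  explicitly.
- Extreme-decile split size is round-half-up(fraction · n) (so n = 415 at
  10% gives 42 per tail); ties at the boundary resolve by stable sample
  order and the two groups are guaranteed disjoint.
- Survival modelling is intentionally excluded; `survival_export` emits a
  tidy table for external survival tools. The high/low H-score cut-off is
  user input, not inferred.

## Known limitations

- The regulatory functional form is one standard realization of
  normalized logic-based dynamics; other monotone forms (e.g. weighted
  inhibitor exponents, additive-saturating activation) would satisfy the
  same boundary constraints and can disagree quantitatively.
- Gene-to-node matching is exact case-insensitive symbol equality; no
  alias resolution, so identifier drift between network and expression
  sources silently falls back to the default capacity (the matched
  fraction is reported).
- KS p-values on pooled draws remain heuristic even at the sample-level
  effective n; treat the ranked D values and the cross-cohort
  intersection as the primary evidence.
- The endpoint-only convergence criterion cannot distinguish slow
  transients from genuine multistability at a given `t_max`.
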