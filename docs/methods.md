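# Methods

`gatekin` analyzes equilibrium single-channel gating records of the kind
produced by NMDA-receptor on-cell patches, plus two auxiliary measurements
that probe the channel's two gates: ion-permeation event counting from MD
z-traces and MTS modification-rate fitting from macroscopic currents. Every
stage can be exercised on synthetic data with known ground truth; this note
records the models, the defaults, and the design choices that were genuinely
open.

## Aggregated Markov gating model

A channel is a continuous-time Markov chain on states partitioned into a
`closed` and an `open` class; only the class is observable through the
current level. `KineticScheme` stores the generator matrix Q (s⁻¹, rows sum
to zero, off-diagonals ≥ 0) and requires strong connectivity of the
transition graph, checked on the support graph of Q.

- **Stationary distribution.** π solves πᵀQ = 0, Σπ = 1, by least squares on
  the augmented system; solves with condition number above 1e12 raise rather
  than return garbage. The equilibrium open probability is
  P_open = Σ_{open} π_i.
- **Class sojourn mixtures.** Restricting Q to the states of one class gives
  the sub-generator Q_AA; eigendecomposition yields sojourn components
  τ_i = −1/λ_i with weights from the entrance distribution. The entrance
  distribution is the *stationary flux* into the class (rate-weighted
  stationary occupancy of the source states) — the distribution an observer
  marking class entries sees at equilibrium. This choice is a convention;
  recording software resolves it internally and never exposes it.
  Sub-generators with complex eigenvalues (strongly cyclic intra-class
  wiring) are rejected rather than approximated, keeping the exponential
  mixture interpretation exact.
- Linear-algebra and probability-sum tolerances are 1e-9 relative.

## Synthetic data

**Dwell sequences** come from an exact Gillespie path started from the
stationary distribution, with state dwells aggregated by class; the final
event is truncated at the requested duration. All generators are
bit-reproducible for a fixed integer seed.

**Current traces** sample the dwell sequence at interval `dt`
(event boundaries land on the nearest sample edge; the boundary sample
belongs to the incoming class), optionally apply a Gaussian low-pass filter,
then add white Gaussian noise. The filter is Gaussian rather than a 4-pole
Bessel because it admits an analytic check: a Gaussian filter with −3 dB
cutoff f_c has impulse-response SD 0.1325/f_c and 10–90% step rise time
≈ 0.34/f_c. Noise is added after filtering, so `noise_sd` is the SD seen in
the rendered samples. Real recordings differ: hardware Bessel filtering
colors the noise and the open-channel level carries excess noise; tests
passing on these traces therefore validate detector logic, not robustness
to every instrumental artifact.

**Two-gate presets** (`make_two_gate_scheme`) wire four closed states in a
star around one open state: an `intercluster` state (slow gate; seconds),
`flicker_closed` and `m2_closed` (fast intra-cluster gates; 0.2 and 2 ms),
and `long_closed` (~0.1 s). Star wiring makes every closed component a
single-state sojourn, so the closed dwell mixture is known exactly and
T_crit between the 3rd and 4th components is analytic. Rates are synthetic
defaults chosen once so the wild-type-like preset sits at a realistic scale
for this receptor family — cluster duration ≈ 12.3 s, intercluster ≈ 2.3 s,
mean open time ≈ 6.4 ms, cluster P_open ≈ 0.58 — and so the two perturbed
presets change one gate each:

- `n1_ga_like` multiplies the open→`m2_closed` rate by 30 (mean open time
  collapses to ~0.6 ms, cluster P_open to ~0.22) and raises the cluster-exit
  rate so the cluster duration, and hence P_cluster, is unchanged.
- `n2_ga_like` speeds cluster exit and slows cluster entry and the
  `long_closed` return (clusters ~5.8 s, interclusters ~6.7 s, P_cluster
  ~0.46), leaving the fast gates untouched.

Both presets reduce equilibrium P_open to ≈ 0.18. These presets target the
*orderings* of the statistics, not any experimental rate constants, which
are not published for this system.

**Ion traces** are reflected 1-D Gaussian random walks (default step SD
1.5 Å/frame) between hard walls at ±30 Å. Each barrier (M3, M2) is a plane
at its window midpoint; a proposed step crossing the plane is accepted with
the per-barrier passage probability and otherwise reflected about the
plane — a controllable stand-in for a free-energy barrier rather than an
energy-landscape sampler. The generator emits a ground-truth crossing log
computed by a naive per-frame compartment walk, deliberately independent of
the vectorized detector it is used to check.

## Idealization

Half-amplitude threshold detection classifies each sample by the nearest of
two known levels. SKM alternates (i) Viterbi segmentation under Gaussian
emissions with a shared noise SD and transition probabilities re-estimated
from the current segmentation (+1 smoothing), and (ii) re-estimation of
class means and SD from the assigned samples, stopping when the
segmentation is unchanged (typically ≤ 5 iterations) or at `max_iterations`
(flagged, not an error). A degenerate class is re-seeded once from
quantiles, then raises. Classes are ordered by increasing |amplitude|, so a
~0 pA baseline is always the closed class regardless of initialization
order. The shared-SD emission model reflects that patch noise is
class-independent to first order.

**Dead time.** Events shorter than t_d are unresolvable: each is deleted
and its duration added to the preceding surviving event (a leading short
event merges forward), then adjacent same-class events merge. The
merge-into-preceding convention matches standard idealization software; the
operation conserves total duration and is idempotent. A record in which no
event reaches t_d collapses to a single event with a warning.

## Dwell-time inference

Durations below the dead time are censored, so a class's durations are
modelled by the left-truncated mixture f(t)/S(t_d),
f(t) = Σ (a_i/τ_i)e^(−t/τ_i). Because a left-truncated exponential is again
exponential in t − t_d, the MLE reduces to a plain exponential-mixture EM on
the shifted durations; fitted weights map back to untruncated areas via
a_i ∝ w_i e^(t_d/τ_i). This per-class mixture MLE is the package's fitting
model; it reports exactly the quantities of interest (component counts,
time constants, areas, their ratios) without modelling missed-event
corrections inside an aggregated scheme, which is out of scope.

Numerical choices: 20 EM starts from log-spaced τ grids spanning
[t_d, max t] (first start exact grid, the rest seeded jitters), coarse runs
to ΔLL < 1e-6 and the best start polished to ΔLL < 1e-8 (max 2000
iterations); τ floored at 1e-9 s; k refused when k > n/10. For speed the
durations are first compressed to ≤ 2000 weighted log-spaced support points
represented by their conditional means — this preserves the M-step
sufficient statistics exactly (the k = 1 MLE mean(t − t_d) is still exact)
and perturbs τ estimates only at the ~1e-4 relative level.

**Model selection** walks k upward (defaults: closed 3–6, open 2–4) and
accepts k+1 only if the log-likelihood gains at least 10 units (ties
accepted) *and* the smallest fitted area stays at or above the occupancy
floor, 1e-4 — the operational meaning of an added component with "zero
occupancy", which has no published epsilon.

## Cluster analysis

T_crit separates intra-cluster closures from interclusters between two
adjacent closed components, by default the 3rd and 4th. The default
criterion minimizes the total misclassified events,
a_i e^(−t/τ_i) + a_j(1 − e^(−t/τ_j)), with closed form
t* = ln(a_iτ_j/(a_jτ_i)) / (1/τ_i − 1/τ_j); the alternative equates the two
misclassified fractions (bisection). The criterion phrase "minimizing the
false event ratio" is ambiguous between the two conventions, so both are
implemented; they differ by ~20–30% for well-separated components, which is
why the convention tag travels with the segmentation. t* must land strictly
inside (τ_i, τ_j), else the components are declared non-separable.

Closed events longer than T_crit are separators; runs between separators
with ≥ 1 open event (configurable) are clusters. Record edges censor the
first and last runs and edge separators: censored runs are kept in the
cluster list (and in cluster P_open, whose ratio is unbiased by truncation)
but excluded from the mean cluster duration, as are edge separators from
the mean intercluster duration. P_cluster = mean cluster / (mean cluster +
mean intercluster); fields that cannot be computed are reported absent, not
zero.

## Permeation analysis

The pore axis is split into extracellular (above the M3 +10 plane,
z = 14.1 Å), vestibule (8.8 to −3.9 Å), and intracellular (below −7.0 Å),
with the M3 (8.8–14.1 Å) and M2 (−3.9 to −7.0 Å) windows as barrier
regions that confer no residence. A crossing is committed only when the ion
penetrates `commit_margin` (default 5 Å) beyond the far plane — the
operational meaning of "diffused into" the next compartment — which
suppresses boundary re-crossing chatter; margin 0 reproduces naive plane
counting. Coarse frames that jump intracellular↔extracellular directly are
logged as both barrier passages in traversal order. %M2 statistics are kept
as raw counts plus percentages; the vestibule-start restriction selects
ions whose first committed compartment was the vestibule, the population
for which an unbiased ion has even odds of leaving through either barrier.
For that null, each ion's *first* crossing is the exchangeable unit —
counting all crossings per ion gives correlated counts whose variance
exceeds binomial.

Pore-radius profiles (computed upstream, e.g. by pore-profiling software)
are averaged over a z window per frame and reduced across frames and
replicates to mean ± SD (ddof = 1) with min/max of the per-frame means.
Pore occupancy counts particles in the slab from the M2 top plane to the
M3 commit plane.

## MTS kinetics

The current during continuous reagent application is fit by
I(t) = baseline + amplitude·e^(−t/τ) (analytically seeded nonlinear least
squares; baseline free by default, zero behind a flag since the constraint
convention is not standardized), and k = 1/(τ[MTS]) in M⁻¹s⁻¹. Constant or
non-decaying records raise instead of returning a pinned τ (bound at 50×
the record span).

## Problem sizes and what the tests show

The test suite and `scripts/acceptance.py` use problem sizes chosen as
realistic study conditions that keep full runs fast: parameter recovery at
1e5 events with a 20 μs dead time (component counts exact, τ within 10%,
areas within 0.05), the two-gate dissociation over 20 records × 120 s per
preset with 3-SE directional checks, 1000–3000 ion walks for the detector
oracle and the 50% null, and 100-seed Monte Carlo for the MTS fit (k within
3% at 2% noise). Passing these demonstrates internal consistency and
correct implementation of the estimators on data matching the generative
assumptions (white noise, exponential mixtures, memoryless gating); it does
not certify performance on recordings with drift, sublevels, multiple
channels per patch, or correlated noise, all of which are out of scope.

## Known limitations

- No baseline-drift correction, conductance sublevels, or multi-channel
  superposition handling in idealization.
- Dwell fitting ignores correlations between adjacent open/closed
  durations; no rate-matrix estimation from dwells.
- The ion-walk generator is 1-D; committed-crossing bookkeeping assumes
  frame intervals short enough that multi-compartment jumps are rare.
- Fit uncertainties (CIs on τ, a) are not computed; ratio comparisons
  across fits rely on external replication.
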