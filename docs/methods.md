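# Methods

## Model

A clock circuit is a directed graph of genes plus external light
inputs. Gene states are binary, X_i(t) ∈ {0, 1}, defined on the
sampling grid t = k·t_S (default t_S = 0.5 h). Each gene edge j carries
a signalling delay τ_j ≥ 0 (a multiple of t_S) and a one-input gate
bit: 0 passes the lagged regulator state through (activation), 1
inverts it (repression). A gene with two gene inputs combines them with
a two-input gate: 0 = inclusive OR, 1 = AND. The ordered vector of free
gate bits is the logic configuration G, encoded MSB-first as
D(G) = Σ_l g_l 2^(d−l).

Light handling is fixed, not fitted: each light input k is the 24 h
periodic pulse signal L_k(t) = 1 iff (t − t_dawn) mod 24 < p_k, with
dawn at ZT0 and the lit interval half-open so that p_k = 0 and
p_k = 24 are exactly constant darkness and constant light. Multiple
light inputs to one gene are ORed; the combined light bit enters the
gene's update through a fixed outer gate chosen by the circuit's
free-running regime — OR for dark-free-running circuits (x OR 0 = x)
and AND for light-free-running ones (x AND 1 = x) — so clamping the
lights at the free-run level recovers the light-free rules identically.
This consistency condition is checked exhaustively in the test suite
for every built-in circuit and every configuration.

### Built-in circuits

| circuit | genes | gene edges | lights | d | τ slots | free run | τ_FR |
|---|---|---|---|---|---|---|---|
| neurospora_1loop | frq, FRQ | 2 | 1 | 2 | 3 | DD | 22 h |
| neurospora_2loop | frq, FRQ1, FRQ2 | 4 | 1 | 5 | 5 | DD | 22 h |
| arabidopsis_2loop | LHY, TOC1, X, Y | 6 | 3 | 8 | 9 | LL | 25 h |
| arabidopsis_3loop | + PRR | 8 | 4 | 11 | 12 | LL | 24 h |

Gate ordering is pinned so the published bitstrings decode correctly:
the six 2-loop *Arabidopsis* edges (LHY→TOC1, TOC1→X, X→LHY, LHY→Y,
TOC1→Y, Y→TOC1) take g1–g6, the Y and TOC1 combiners g7–g8, and the
3-loop circuit appends LHY→PRR (g9), PRR→LHY (g10) and the LHY combiner
(g11). Delay slots follow gene edges in the same order, then light
edges (so τ9–τ12 are the 3-loop light delays). Light pulse parameters
are fixed: the continuous LD input has p = photoperiod; the impulse
inputs default to p1 = 2 h, p3 = 0.5 h, p4 = 3 h for the *Arabidopsis*
circuits. Each circuit also carries its published optimal
configuration, delays and thresholds as defaults, and the 3-loop
circuit additionally the two top parameter sets fitted to luciferase
data (`G_OPT`, `G_DE`).

### Dynamics and attractors

Updates are synchronous and deterministic. Zero delays (present in the
published 3-loop parameter sets) create within-step dependencies that
are resolved by evaluating genes in topological order of the zero-delay
subgraph; a feedback loop whose delays are all zero has no well-defined
update and is rejected by the simulator (and classified as non-viable
by the fitting pipeline, since an instantaneous loop cannot oscillate).

The dynamical state at step k is the window of the last W/t_S state
rows (W = largest gene-edge delay) plus, under a non-constant light
program, the time of day. This state space is finite, so every
trajectory revisits a state; limit-cycle detection hashes the window
and reports the first recurrence, giving the exact transient and
period. A recurrent window whose states are all identical is a fixed
point (period 0). Under a light–dark program the recurrence key
includes the 24 h phase, so detected periods are multiples of 24 h;
entrainment means period exactly 24 h with a non-constant cycle (1:1
locking — subharmonics count as failure). The default search horizon
is 100 days; the state-space bound guarantees recurrence long before
this for the circuits shipped.

Viability of a parametrized configuration: (i) from an initial history
(the discretized data when fitting, otherwise a seed bank of constant
histories — all-OFF, all-ON, each single gene ON — accepted if any seed
qualifies), the free-running circuit must reach a limit cycle whose
period is within 20% of the target τ_FR; (ii) feeding that cycle into
LD 12:12 must produce an entrained 24 h cycle. Free-run-only fitting
protocols (constant-light data) skip (ii).

## Discretization

Continuous series are min–max normalized to [0, 1] per species and per
light regime (regimes are separate datasets during fitting; a global
option is not needed by any shipped protocol). A sample is ON iff its
normalized value is strictly above the species' threshold — ties
discretize to OFF. Candidate thresholds live on the lattice
[T_MIN, T_MAX] step T_R (defaults 0.2, 0.8); because a finite series
yields finitely many distinct bitstrings, the lattice is collapsed to
one representative (the smallest) per distinct bitstring before any
sweep, keying distinctness on the concatenation of all regimes.

## Fitting

The cost of (G, τ, T) is a one-step prediction score. For gene i the
observed upstream bitstrings are lagged by the candidate delays and
pushed through gene i's gates (lights come from the regime's light
program; light signals are closed-form in t, so light lags never
restrict the window); the prediction is compared with gene i's own
observed bits over the samples where all lagged gene inputs exist. The
default comparison is the normalized Hamming distance (fraction of
mismatching samples); scores are averaged over all scored genes and
regimes, keeping the total in [0, 1] with 0 a perfect fit. A
correlation mode, (1 − φ)/2 with φ the binary Pearson (Matthews)
correlation, is available for sensitivity analysis; it falls back to
the Hamming score when either bitstring is constant (φ undefined).
The Hamming default was chosen because it is defined for every input,
range-correct, and ranks identically to correlation in the regimes the
tests probe.

Delays are searched on the lattice {0, τ_R, …, t_MAX} with
τ_R = k_τ·t_S and t_MAX defaulting to τ_FR, subject to one constraint
per elementary cycle of the gene-edge digraph: the delays around each
feedback loop may sum to at most τ_FR (cycle enumeration is
cross-checked against a brute-force search in the tests; the counts are
1, 2, 3, 4 for the built-ins). Because each gene's cost depends only on
its own incoming delays, the sweep computes per-vertex cost tables
(vectorized over delay axes) and recombines them under the loop
constraints with an exact branch-and-bound over cost-sorted per-vertex
options. A brute-force product-lattice evaluation through the scalar
cost function serves as the independent oracle for this machinery in
the tests, and every reported optimum re-scores identically through
that scalar path.

Default grid: k_τ = 2 and T_R = 0.1 for the coarse pass, then an
optional refinement pass at full resolution (k_τ = 1, T_R = 0.025)
inside windows of ±3 coarse delay steps and ±5 coarse threshold steps
around each configuration's coarse optimum (±2/±2 and T_R = 0.05 are
the corresponding luciferase-protocol radii; both are `SearchGrid`
fields). Refinement can only improve a score since the refined lattice
contains the coarse optimum. Ranking is deterministic: ascending score,
ties broken by ascending D(G), then lexicographic delays (threshold
combinations are scanned in ascending product order, and flattened
delay tables are sorted stably, so ties resolve to the smallest
parameters).

Simulated annealing optimizes a single configuration on the same
lattice: a move changes one delay by ±τ_R or one threshold by ±T_R,
loop-infeasible proposals are rejected, acceptance follows a geometric
Metropolis schedule (temperature 0 = greedy descent), and the best
visited point is returned, so the result never degrades the start.

### Free-running luciferase protocol (3-loop circuit)

Reporter genes map onto model species (CCA1→LHY, TOC1→TOC1, GI→Y,
PRR9→PRR). The hypothetical gene X has no biological correlate: it is
excluded from costing, its input gate and delay are fixed (g2 = 0,
τ2 = 0, leaving 1024 candidate configurations), and the observed TOC1
bits proxy for X when scoring LHY. All light pulses are 24 h (the data
are constant-light) and the light delays, dynamically irrelevant in LL,
are fixed at 0. Viability requires only a free-running limit cycle with
period within 20% of 24 h.

## Synthetic data

The generator emulates noisy continuous observations of a known
Boolean clock. The ground truth must be viable; its attractor is
simulated in each regime (the LD cycle aligned to dawn), tiled to five
24 h cycles at 0.5 h sampling, mapped to plateau levels (OFF 0.1, ON
0.9 — asymmetric plateaus avoid degenerate normalization), optionally
smoothed by first-order exponential rise/decay, and perturbed by
i.i.d. Gaussian amplitude noise clipped at zero. The noise scale
follows the system-size scaling of stochastic kinetic simulations,
σ = 1/√Ω, with Ω = 25, 50, 1000, 1000 for the four circuits — the
proportionality constant 1 puts the Ω = 25 flip rate just under the 5%
mis-binarization bound the tests enforce at Ω = 50. Default shaping
time constants are 0 (instantaneous switching): this makes noise-free
generation exactly invertible by discretization, the property the
recovery benchmarks rely on; shaped waveforms are available via the
`rise`/`decay` fields. Every dataset ships with a truth record
(configuration, delays, threshold band, waveform and noise settings)
for recovery scoring.

What the generator does *not* emulate: stochastic kinetic trajectories
have cycle-to-cycle period and amplitude jitter and asymmetric
waveforms, whereas these series are exactly periodic up to amplitude
noise. Consequently some structurally distinct configurations
reproduce the generated bitstrings *exactly* (delay-shift aliases of
the generating rules) — the topological degeneracies that richer
stochastic data lift. Passing recovery tests therefore demonstrate
that the search machinery finds every optimal configuration and ranks
the generating one among them; on data with such exact aliases no
method could single it out, and the free-running-protocol test asserts
membership in the tied optimal set rather than unique top rank. The
two-regime (LD + free-run) protocol used everywhere else breaks most
aliases, and the generating configuration does rank uniquely first in
those tests.

## Problem sizes used by the tests and acceptance script

Recovery fits run the 1- and 2-loop *Neurospora* circuits at the coarse
grid (k_τ = 2, T_R = 0.1, refinement on for noise-free runs), ten noisy
replicates for the 1-loop circuit and three (at T_R = 0.2) for the
2-loop; the luciferase-protocol test uses the constrained 256-
configuration variant at k_τ = 3. These sizes were chosen to keep the
whole suite under a minute of fitting time while still exercising every
code path; the fitting engine itself handles the full 1024/2048-
configuration sweeps (a full free-running-protocol sweep takes on the
order of a minute).

## Known limitations

- Gates are restricted to compositions of the 1-input identity/NOT and
  2-input OR/AND operators; genes with more than two gene inputs are
  not supported.
- Updates are synchronous and deterministic; stochastic or asynchronous
  Boolean schemes are out of scope.
- The per-gene figure numbering of gate slots in the source circuit
  diagrams is not recoverable from text; the ordering above is the
  unique one consistent with all published bitstrings, but individual
  slot numbers could in principle differ from the original diagrams.
- The loop-constraint index sets are derived from elementary cycles of
  the gene-edge digraph rather than transcribed from the published
  bounds (which are only shown graphically); the counts and the
  feasibility of all published parameter sets agree.
- Temperature compensation and kinetic (differential-equation) models
  are not implemented; the free-running period sum rule of the 2-loop
  circuit (τ_FR = τ1+τ2+τ3+τ4) is verified numerically, not derived.
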