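# boolclock

Delayed Boolean-logic models of circadian gene networks: simulation,
exhaustive structure/parameter fitting, and photoperiod analysis.

## The problem

Circadian clocks are gene regulatory circuits that generate ~24 h
rhythms and entrain them to the day–night cycle. Differential-equation
clock models capture this biochemistry well but carry dozens of kinetic
constants that must be fitted to data — a major computational
bottleneck. `boolclock` implements the alternative: each gene is a
binary variable X_i(t) ∈ {0, 1} on a sampling grid t = k·t_S, each
regulatory interaction is a logic gate with a single *signalling delay*
τ_j (the net time for a regulator's state change to propagate), and
fitting continuous data introduces one *discretization threshold* T_i
per species. The update rule is

    X_i(t) = s_i( X_j(t − τ_j…),  L_k(t − τ_k…) )

where each s_i composes one-input gates (identity = activation, NOT =
repression), an optional two-input combiner (OR/AND), and a fixed outer
gate H_i that couples the OR of the gene's light inputs L_k so that
constant free-running light conditions (DD or LL) recover the
light-free rule exactly. The vector of free gate bits G = (g_1, …, g_d)
is the circuit's **logic configuration (LC)**, indexed compactly by its
MSB-first decimal expansion D(G). Delays are multiples of t_S bounded
by the free-running period, and only finitely many thresholds produce
distinct bitstrings — so the entire structure + parameter space is
finite and can be searched exhaustively.

The package ships four built-in circuits with their published optimal
parameter sets: the 1- and 2-loop *Neurospora* circuits (frq/FRQ
negative feedback, dark free-run, 22 h), and the 2- and 3-loop
*Arabidopsis* circuits (LHY, TOC1, X, Y, ± PRR; light free-run, 25 h
and 24 h). These admit 4, 32, 256 and 2048 logic configurations
respectively.

Who it is for: systems biologists who want to rank candidate regulatory
structures against expression time courses, or to explore entrainment
and phase–photoperiod behaviour of discrete clock models, without
committing to a kinetic parametrization.

## What it does

- **Simulation** — deterministic delayed synchronous updates under
  arbitrary 24 h light programs; exact limit-cycle detection by
  recurrence of the full delayed state; viability classification
  (free-running period within 20% of target + 1:1 entrainment in LD).
- **Fitting** — a one-step-prediction cost per gene (observed upstream
  bits, lagged and gated, versus the gene's own observed bits; the
  normalized Hamming distance by default, 0 = perfect). Exhaustive
  search over all configurations, loop-feasible delay lattices and
  informative thresholds, with per-vertex decomposition, an exact
  branch-and-bound for the loop constraints, and coarse-to-fine
  refinement; simulated annealing on the same lattice; the free-running
  luciferase-data protocol for the 3-loop circuit (species mapping,
  exclusion of the hypothetical gene X, proxy data, fixed light
  parameters).
- **Phase analysis** — ON→OFF transition times as Boolean phase
  markers, threshold down-crossings for continuous series,
  phase–photoperiod curves and dawn/dusk-locking classification,
  maximum symmetric entrainment interval.
- **Synthetic data** — noisy continuous time courses with known Boolean
  ground truth (plateau mapping + exponential rise/decay + Gaussian
  amplitude noise with σ = 1/√Ω), for benchmarking recovery.

## Worked example

Generate a noisy synthetic dataset from the 2-loop *Neurospora* circuit
(5 cycles LD 12:12 plus 5 cycles DD, 0.5 h sampling, σ = 1/√50), then
rank all 32 logic configurations against it:

```python
from boolclock import BooleanClockModel, builtin_model
from boolclock.synth import SyntheticSpec, generate

spec = builtin_model("neurospora_2loop")
series, truth = generate(SyntheticSpec(model=spec, seed=1))
fit = BooleanClockModel(series, "neurospora_2loop").fit()
print(fit.summary(top=5))
```

```
                       Boolean clock fit
================================================================
Circuit:            neurospora_2loop
Genes / edges:      3 / 4 (+1 light)
Gate slots (d):     5
Target period:      22.0 h (DD free run)
Regimes fitted:     LD, DD
Samples:            482
Method:             exhaustive
Configurations:     32
----------------------------------------------------------------
rank   D(G)  G               score  viable  period
   1      7  00111          0.0197     yes    22.0
   2      3  00011          0.0238     yes    22.0
   3      5  00101          0.0246     yes    22.0
   4     15  01111          0.0266     yes    22.0
   5      6  00110          0.0271     yes    23.0
================================================================
```

The generating configuration 00111 — both FRQ isoforms can
independently shut off *frq* transcription (edge gates NOT/NOT, AND
combiner) — ranks first among viable clocks with the lowest prediction
cost (1.97% of samples mispredicted), recovers the generating delays up
to the lattice resolution, and free-runs at 22 h in darkness. On
noise-free data its score is exactly 0.

The same pipeline is scriptable from the shell:

```sh
boolclock synth --model neurospora_2loop --replicates 1 --seed 1 --outdir bench
boolclock rank --model neurospora_2loop \
    --data LD=bench/neurospora_2loop_n0_r0_LD.csv \
    --data DD=bench/neurospora_2loop_n0_r0_DD.csv --out-csv ranking.csv
boolclock viability --model neurospora_1loop
boolclock phase --model arabidopsis_3loop --out phases.csv
```

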