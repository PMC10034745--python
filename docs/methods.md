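# Methods

## Scope and model

`mshdx` analyzes peptide-level deuterium-uptake kinetics from bottom-up
HDX-MS and embodies the design arithmetic of a millisecond quench-flow
labeling instrument. The analysis chain assumes EX2-like exchange at the
peptide level: each backbone amide exchanges with an effective first-order
rate `k_int,i / Pf_i`, where `k_int,i` is the residue's intrinsic
(random-coil) rate and `Pf_i ≥ 1` its protection factor. Side-chain and
His-labile hydrogens, EX1 bimodality and isotope-envelope structure are
out of scope.

## Intrinsic exchange rates

Per-residue rates use the standard three-term catalysis model

    k_int = k_A·[D⁺]·10^(λA+ρA) + k_B·[OD⁻]·10^(λB+ρB) + k_W·10^(λB+ρB)

with the poly-DL-alanine reference rates, nearest-neighbour side-chain
factors (λ acting on a residue's own amide, ρ on the following residue's)
and activation energies of Bai, Milne, Mayne & Englander, *Proteins* 17
(1993) 75–86, including the Connelly et al. (1993) treatment of ionizable
side chains. The tables ship as package data
(`mshdx/data/*.csv`, version `bai1993-d2o-v1`) and can be replaced by the
user via `RateTable.from_csv`; transcription provenance is recorded in the
CSV headers. Specific choices:

- **pD convention.** `pD = pD_read + 0.4` (glass-electrode correction of
  an uncorrected meter reading of a D₂O buffer). Validity is enforced for
  corrected pD 1–13 and temperature 258–323 K.
- **Solvent ionization.** `[OD⁻] = 10^(pD − pKD(T))` with `pKD = 15.05` at
  293 K and a van't Hoff temperature correction (ΔH = 14.17 kcal/mol,
  equivalent to d(pK)/dT ≈ −0.036 K⁻¹ near room temperature).
- **Temperature.** Arrhenius factors on the acid/base/water terms with
  Ea = 14/17/19 kcal/mol referenced to 293 K.
- **Ionizable groups.** Asp, Glu, His and the C-terminal carboxyl blend
  their protonated/deprotonated factors by Henderson–Hasselbalch at the
  working pD (pK in D₂O: 4.48, 4.93, 7.42, 4.0). The published table
  gives no base-catalysis factor for the deprotonated C-terminal
  carboxylate; it is taken as 0 (no effect).
- **Exclusions.** The first residue loses its amide to proteolysis, the
  second residue's label is lost during separation, and proline has no
  amide hydrogen; all three carry a rate of exactly 0 so they drop out of
  uptake sums. Free synthetic peptides are treated identically to
  proteolytic fragments. Exchangeable count: `Q = len − 2 − #Pro(≥3)`.

The theoretical maximum-exchange curve is
`D_int(t) = f_D₂O · Σ (1 − exp(−k_int,i t))`; it is non-decreasing and
bounded by `f_D₂O·Q`, and equals the sum of its single-residue terms
(both properties are tested).

## Back-exchange correction

A maximally deuterated (maxD) reference of each peptide calibrates
deuterium loss during quench/digestion/LC as a single scalar:
`retention = mean(maxD uptake) / (f_D₂O·Q)`. Observed uptake is divided
by the retention; values exceeding the theoretical maximum by > 5% are
warned about but never clipped, preserving noise structure for fitting.
Retention is modelled as time-invariant — on a turbulent quench-flow
instrument back-exchange shows no measurable dependence on mixing time —
and a linear regression of per-measurement retention against time
(slope in fraction/s, R², p-value) is reported so users can verify
time-invariance on their own data. On time-invariant synthetic data the
slope test rejects at its nominal α = 0.05 (calibrated type-I error,
tested over 500 seeds).

## Kinetic fitting and protection factors

Corrected curves are fitted to
`D(t) = Σⱼ Qⱼ(1 − exp(−(kⱼ t)^βⱼ))`, 1–3 phases, β ∈ (0.05, 1]
(β absorbs rate heterogeneity within a segment; β = 1 is a simple
exponential). Numerical choices:

- **Optimizer.** Trust-region-reflective least squares from 16 log-spaced
  rate multi-starts spanning `0.1/t_max` to `10/t_min` (phases staggered
  30-fold); deterministic with no random state; ties broken by lowest
  residual sum of squares. Amplitudes are bounded per phase and their sum
  soft-constrained to 1.05× the exchangeable maximum.
- **Weighting.** When every exposure has ≥ 3 replicates, points are
  weighted by inverse replicate variance, with each per-exposure variance
  shrunk 50% toward the pooled variance: raw 3-replicate variances are so
  noisy that they miscalibrate the downstream F-test (in two-phase
  simulations the raw-variance weights produced a spurious third phase in
  20% of runs; with shrinkage the true count is selected in 40/40 runs).
- **Model selection.** Smallest n not rejected against n+1 by the
  extra-sum-of-squares F-test at α = 0.05 (AIC available via
  `criterion="aic"`). Series that never rise above 0.02 Da are returned
  as `uninformative` with Q ≈ 0; fits needing more parameters than half
  the available data points are not attempted. A fit with essentially
  zero residual stops the search (the F statistic is undefined there).
- **Protection factors.** The theoretical intrinsic curve is fitted in
  the same manner and `ln Pf_j = ln(k_int,j) − ln(k_exp,j)` per phase,
  phases paired fastest-to-fastest at equal counts or by amplitude rank
  (with a warning) otherwise. Because independently fitted multi-phase
  models can split amplitude differently — a noise-absorbing slow phase
  makes per-phase pairing unstable — the pipeline additionally reports a
  peptide-averaged `ln Pf` from matched single-phase ensemble fits of
  both curves on the same schedule. On synthetic bundles with uniform
  ln Pf = 2 this summary is recovered within ±0.15 (the acceptance
  tolerance is ±0.3); per-phase values remain available as detail.
- **Decay fit.** The chemical-clock validation uses
  `A(t) = A₀·exp(−kt) + C` by nonlinear least squares with a second,
  relative-weighted pass (σ ∝ fitted signal), since clock-trace noise is
  predominantly multiplicative; the 95% CI is a Wald t-interval. With
  unweighted fitting the CI covered the truth in 89% of multiplicative-
  noise simulations; with relative weighting, 93%.

## Fluidics

Labeling time is the delay-loop transit time `V_loop / F_total` (mixer
dead volumes default to 0 and are configurable). Turbulence requires
`Re = LV·d/kv ≥ 2000` with `LV = F/(π(d/2)²)`; Re is exactly linear in
flow at fixed geometry. Default instrument: 0.733 mm tubing, kv =
1 mm²/s (water, 20 °C), total labeling-mixer flow 1154–2700 μL/s (floor
set by Re = 2000, ceiling by syringe-stall margin), 1:20 label and 1:1
quench mixing, stop-flow presets 2400/4800 μL/s, six loops at 1.75×
volume steps from 135 μL. Loop steps outside 1.25–2.5× are rejected and
outside the 1.5–2× design band warned about (coverage gaps). The loop
volumes themselves are constructed defaults, not measurements of any
physical instrument; loop calibration by tracer dilution
(`V_L = DV·C_collected/C_stock`) is provided for real hardware.

The planner uses continuous mode whenever some loop's transit time can
match the request within the flow limits (smallest feasible loop wins),
guaranteeing Re ≥ 2000 in both mixers by construction. Longer times use
stop-flow: the labeled bolus (sample × 21 after 1:20 mixing) parks in the
smallest loop that holds it; labeling time is modelled as the bolus
midpoint's fill transit plus the stopped delay plus its push transit.
Achieved times are reported on a 0.1 ms grid, inside the 0.5 ms accuracy
target; a 1 ms-step sweep from 50 ms to 300 s is gap-free on the default
loop set (tested exhaustively). Requests below the floor (smallest loop
at maximum flow, 50 ms by default) are rejected with the floor reported.

## Synthetic data

The generator forward-simulates
`observed = retention · f_D₂O · Σ(1 − exp(−(k_int,i/Pf_i)·t)) + ε` and
maxD references `retention · f_D₂O · Q + ε`, with ε Gaussian, additive
and homoscedastic (per-replicate SD 0.084 Da by default — chosen so a
270-replicate mean has a 95% CI of ~±0.01 Da, i.e. ~3% relative
dispersion of a few-Da signal). Defaults reproduce the validation study
conditions: five standard peptides (bradykinin, leucine enkephalin, a
consensus antifreeze peptide, two designed TPR peptides), pD_read 7.06,
23 °C, 95% D₂O, 15 exposures from 50 ms to 300 s, 3 replicates. All
randomness flows from the single seed in `SimulationTruth`. A
protein-digest workload generator (~270 overlapping segments over a
900-residue dummy sequence) exercises large-protein bookkeeping.

What the generator does **not** emulate — and therefore what passing
recovery tests cannot certify on real data: day-to-day variance
components, signal-dependent (heteroscedastic) MS noise, isotope-envelope
centroiding error, chromatographic back-exchange that varies with
gradient or temperature, EX1 bimodality, and peptide-to-peptide
correlations from shared spectra.

## Problem sizes

Stochastic checks run at sizes chosen to make their Monte-Carlo error
small relative to the tested margins: 500 seeds for CI-coverage and
type-I-error calibrations (binomial SE ≈ 1%), 40 seeds for phase-count
selection (each run refits up to three models from 16 starts), two seeded
five-peptide bundles for end-to-end recovery, and the exhaustive
299,951-point planner sweep.

## Known limitations

- The intrinsic-rate tables are this package's own transcription of the
  1993 compilation; newer reference-rate revisions can be supplied as a
  replacement CSV but are not bundled.
- Protection factors are segment-averaged; no per-residue deconvolution
  from overlapping peptides is attempted.
- The stretched-exponential form is an approximation to a sum of `Q`
  exponentials; with few phases the fitted rates are schedule-dependent
  ensemble quantities, which is why the peptide-averaged `ln Pf` uses
  matched fits on a common schedule.
- The fluidics model ignores mixer dead volume by default, viscosity
  changes with temperature or solvent composition, and valve/syringe
  actuation latency.
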