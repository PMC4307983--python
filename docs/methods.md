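# Methods

## The model

`galswitch.model` implements a minimal deterministic ODE family for the GAL
circuit under joint glucose/galactose input. The dynamical state is the
total concentration of three regulators — Gal1p (G1_T, also the expression
readout), Gal80p (G80_T), Gal4p (G4_T) — plus the active form R\* of a
glucose-dependent repressor. Mechanistic ingredients:

* **Galactose sensing.** A Hill fraction of total Gal1p is in the activated
  form G1\* = G1_T·gal^m/(K_gal^m+gal^m). Signalling (binding) is assumed
  fast relative to synthesis/decay.
* **Sequestration.** G1\* and Gal4p compete for Gal80p with dissociation
  constants K_seq80 and K_seq4. Free Gal80p solves
  `x + A·x/(K_seq80+x) + C·x/(K_seq4+x) = B` (A = G1\*, B = G80_T,
  C = G4_T); the left side is strictly increasing so the root in [0, B] is
  unique, found by vectorized bisection (70 iterations, ~2^-70 relative).
* **Transcription.** Free Gal4p activates *GAL1* and *GAL80* through a Hill
  term h+(G4_free; K_A, n_A); R\* represses *GAL1* and *GAL4* through
  h-(R\*; K_R1/K_R4, n_R), acting multiplicatively on the activated term.
  All species decay linearly at rate d.
* **Catabolite repression.** dR\*/dt = k_R·glu·(R_tot − R\*) − k_Rd·R\*, so
  the repressor equilibrates to R_tot·k_R·glu/(k_R·glu + k_Rd).

Two variants alter single arms: the *GAL80 open loop* replaces Gal4p-driven
*GAL80* expression with a constitutive rate `g80_const` (calibrated to 40%
of the fully induced wild-type level, i.e. 0.4·(alpha80+b80)); the
*dilution* variant removes R\* and instead scales each species' decay by
d·(1 + s_i·h+(glu; K_g, n_g)), modelling glucose acting through growth
rate.

### Default parameters and why

No published numeric set was available for this formulation, so the
defaults shipped in `ModelParams` were designed once, from the circuit's
structure, to realise the qualitative phenotype the model must explain, and
then frozen:

* K_R1 = 64.64 nM and K_R4 = 32.48 nM anchor the repressor-affinity scale:
  the 20%-reduced-affinity perturbation studied with the model corresponds
  to multiplying both by 1.25 (80.8 and 40.6 nM).
* The OFF state exists where repressed GAL4 output (b4 + alpha4·h-) stays
  below the basal Gal80p pool's buffering capacity; the ON state exists
  while G1\* can out-titrate total Gal80p. Choosing a basal *GAL4* floor
  (b4 = 3.2 nM/h) and a moderate basal *GAL80* supply (b80 = 8 nM/h)
  separates the two saddle-node folds; alpha1 = 500, alpha80 = 12,
  alpha4 = 16 nM/h, K_A = 4 nM, tight sequestration (K_seq = 0.15 nM) and a
  saturating repressor pool (R_tot = 350 nM, k_R = 0.02 /nM/h, k_Rd = 1 /h)
  place the bistable band at gal = 150 nM between roughly 18 and 40 nM
  glucose, inside the 10–10³ nM window, with the band widening in
  galactose (75 → 300 nM) as required for the regime diagram.
* d = 0.4 /h corresponds to a ~1.7 h protein dilution time; Hill
  coefficients are all 2 (weak cooperativity — the switch comes from
  sequestration, not from steep promoters).

A documented consequence of this topology: *reducing* repressor-promoter
affinity (K_R × 1.25) moves **both** saddle-node thresholds to higher
glucose — the bistable window shifts up. Decaying glucose then reaches the
bifurcation point sooner, so δ_b and δ_g shrink, which is the
reduced-repression phenotype. The variant comparisons in the tests assert
exactly this upward shift plus the open-loop area expansion.

### Numerics

* Integration: LSODA, rtol 1e-8 / atol 1e-10 nM (single trajectories).
  Nonlinear terms evaluate a nonnegative-clipped copy of the state so the
  flow pushes transiently negative components (within solver tolerance)
  back toward zero.
* Equilibria: at constant inputs R\* decouples, so the multistart Powell
  root search runs over (G1_T, G80_T, G4_T) from 32 Latin-Hypercube starts
  in the reachable box [0, 2·(alpha_i+b_i)/d] plus extremal corners; the
  saddle between the outer branches is recovered by re-solving from points
  interpolated (arithmetically and geometrically) between already-found
  roots. Roots are deduplicated at 1e-4 relative distance and accepted at
  residual < 1e-8 nM/h. Stability comes from central finite-difference
  Jacobians (relative step 1e-6).
* Regime labels: ≥2 stable equilibria ⇒ bistable; a lone stable
  equilibrium is called ON/OFF by comparing G1_T to the geometric mean of
  the ON/OFF branch levels over the scan's bistable points (fallback: the
  configurable `g1_on_threshold`, 40 nM). Saddle-node thresholds are
  bisected to 1e-3 relative precision.
* Basins: Latin-Hypercube initial conditions (same box; R\* in [0, R_tot])
  integrated in batch (RK45, rtol 1e-6) with early exit once ‖rhs‖ <
  1e-4 nM/h — a threshold deliberately above the solver's error floor
  (≈ rtol·|y|·d), at which point the state is within ~‖rhs‖/d ≈ 2.5e-4 nM
  of the equilibrium. Samples are assigned to the nearest stable
  equilibrium in log10(x+1) space; samples farther than 0.2 log units from
  every attractor at the 200 h horizon count as unconverged and must stay
  below 0.1%. Fractions are bit-reproducible for a fixed seed.

## The quantification pipeline

Per event, expression is log10(fluorescence/side-scatter); events with
nonpositive side scatter are rejected (counted), nonpositive fluorescence
is clipped to a floor (counted). Each time point is classified by fitting
1- and 2-component Gaussian mixtures (EM, 5 seeded restarts) and calling
bimodal only if the 2-component fit wins by BIC *and* both weights ≥ 0.05
*and* |μ2−μ1| ≥ 2·rms(σ). All three constants are exposed. The mixture is
fitted on a deterministic subsample of ≤ 2000 events (means converge much
faster than threshold fractions, which always use every event).

Subpopulation tracks: when bimodal, the component means; when unimodal
above the F_ON threshold (default 10^-0.2 a.u.), the single mean feeds
*both* tracks — after coherent activation the erstwhile repressed cohort
shares the induced level, and this keeps the repressed track's half-max
well defined. When unimodal below threshold only the OFF track is updated.
Counts are scaled to culture density when the table carries events/µl,
otherwise flagged unscaled.

Timing metrics use the window-min/max half-max convention with first
upward crossing and linear interpolation; undefined metrics are reported
as missing with reason codes, never zeros. Subpopulation growth rates are
OLS slopes of log2 counts (zero counts excluded, counted); OD growth rates
are finite differences of ln OD600 with an optional centered 5-point
moving average (edge-renormalized, so constants are preserved exactly).

Hill sugar fits use the decreasing form floor + (s0−floor)·k^n/(k^n+t^n)
with the floor pinned to 0 by default (freeable), initialisation at the
half-level sample and n = 4, and two fallback starts on non-convergence.
A ≥ 20% decline is required; flatter series raise `NonDecayingError`.

## The synthetic generator

`generate_experiment` builds a two-cohort analytical experiment rather
than integrating per-cell dynamics: cohort mean log-expression follows
logistic rises (ON half-rise at `rise_half_on` after induction; OFF at
`t_dep + rise_half_off`), cohort sizes grow exponentially with the
repressed cohort 15% faster on glucose and a diauxic pause of length
`lag` at depletion, glucose falls as c_glu·∫N dt, and galactose is
consumed pre-depletion only through a leak factor (0.10, set so the
default condition consumes ≈2.7% of its galactose by the time 78% of the
glucose is gone), then by the ON cohort during the lag and the whole
population afterwards. Events are drawn as Normal(log10 mean, sd) ×
lognormal side scatter, so the pipeline's normalization inverts the
construction exactly.

`p_on` is *defined* at the F_ON-mid read-out: because the cohorts grow at
different rates, the initial split p0 is back-computed (fixed-point over
the weakly p0-dependent depletion time) so that the ON share equals `p_on`
exactly at the midpoint between the two half-rise times. This keeps the
truth identity F_ON-mid = p_on exact under differential growth.

Default acquisition mirrors a plate-robot experiment: 1/3 h sampling over
14 h, 5000 events per sample (within the 1,000–20,000 cells collected per
time point in such setups), event noise sd 0.12 log10 units, cohort levels
−0.8 → 0.6 log10 units around the 10^-0.2 threshold, logistic rise rate
3.0 /h, 0.1% w/v of each sugar, 200 cells/µl starting density, growth
0.45 /h (glucose) and 0.35 /h (galactose).

What the generator does **not** emulate: instrument drift and spectral
spillover, cell-size/fluorescence correlation beyond the side-scatter
ratio, cell-to-cell switching during the bimodal epoch (cohorts are fixed
at t = 0), non-Gaussian expression tails, and density-dependent growth
saturation. Tests passing on this generator therefore validate the
estimators' statistical behaviour under the assumed structure, not
instrument-specific artefacts of real cytometry data.

### Estimator biases the tests account for

The ON cohort's mean is observable only once the mixture call separates
it (at ≈ 2·sd mean separation), so the estimated δ_a runs ~0.1–0.2 h late
and δ_g correspondingly short; with the default rise rate and noise this
bias sits well inside the max(0.35 h, sampling interval) recovery
tolerance. At the brief merge crossover after coherent activation, a
unimodal call's single mean blends the two cohorts; the mean-recovery
test compares only resolvable time points.

## Problem sizes

Analyses are run at desk scale: 30-point bifurcation grids with bisection
refinement, 2000-sample basin estimates (3 seeds where trends are
asserted), a 5×4 condition grid × 3 seeds for metric recovery, and
100+100 five-thousand-event samples for modality-call accuracy. These
sizes keep the full test suite and the acceptance script within a few
minutes on one CPU while leaving the asserted margins comfortably
resolved.
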