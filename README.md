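# galswitch

Modelling and quantification of the yeast galactose (GAL) switch under
mixed glucose/galactose inputs.

When *S. cerevisiae* meets both sugars at once, the population splits: a
fraction of cells induces the GAL genes early while the rest stay
repressed until glucose runs out, at which point the repressed cohort
activates coherently — a *transiently bimodal* response. `galswitch`
implements both halves of the analysis needed to study this behaviour:

* **A deterministic ODE model of the GAL circuit** with glucose acting
  through an activatable repressor R\*. The state is the total
  concentrations (G1_T, G80_T, G4_T) plus R\*; galactose converts Gal1p to
  an active form G1\* that sequesters the repressor Gal80p, freeing the
  activator Gal4p (positive feedback), while Gal4p also drives *GAL80*
  (negative feedback) and R\* represses the *GAL1*/*GAL4* promoters.
  Protein sequestration is treated as a fast binding equilibrium.
  For the repressor variant:

  ```
  dG1_T/dt = b1 + alpha1 · h+(G4_free; K_A, n_A) · h-(R*; K_R1, n_R) − d·G1_T
  dG80_T/dt = b80 + alpha80 · h+(G4_free; K_A, n_A) − d·G80_T
  dG4_T/dt = b4 + alpha4 · h-(R*; K_R4, n_R) − d·G4_T
  dR*/dt   = k_R·glu·(R_tot − R*) − k_Rd·R*
  ```

  with `h+`/`h-` activating/repressing Hill functions, G1\* =
  G1_T·gal^m/(K_gal^m+gal^m), and (G80_free, G4_free) solving the two
  competing binding equilibria. Analyses on top: multistart equilibrium
  finding, saddle-node bifurcation scans over glucose(×galactose) grids,
  Latin-Hypercube basin-of-attraction fractions, dominant-eigenvalue
  profiles, quasi-steady-state regime labelling of decaying-sugar
  trajectories, and the delayed-galactose statistic δ_b (time for glucose
  to decay to the bifurcation threshold). Variants: a GAL80 open loop
  (constitutive Gal80p) and a dilution-rate model (glucose scales decay).

* **A single-cell quantification pipeline** for time-resolved
  flow-cytometry event tables: per-event log10(YFP/side-scatter)
  normalization, 1-vs-2-component Gaussian-mixture modality calls
  (BIC + weight + separation rule), ON/OFF subpopulation tracking, and the
  timing metrics δ_a (activated-cohort half-max time), δ_g (duration of
  bimodality), F_ON / F_ON-mid (threshold fraction at the inter-cohort
  midpoint), response time (F_ON = 0.5), plus log2 subpopulation growth
  rates, Hill fits to sugar-depletion curves, metabolic delay and
  OD600-based growth rates.

* **A seeded synthetic-experiment generator** that emulates the robot-style
  acquisition (a sample every 20 min for 14 h): two cohorts with logistic
  log-fluorescence rises, glucose consumed before galactose, a diauxic
  growth pause, and analytic ground truth for every estimated metric.

## Worked example

```bash
python examples/03_single_cell_metrics.py
```

prints, for a synthetic 0.1% glucose + 0.1% galactose culture:

```
glucose depletion (truth):   6.32 h
delta_a  estimate / truth:   1.63 / 1.50 h
delta_g  estimate / truth:   5.89 / 6.02 h
F_ON-mid estimate / truth:   0.506 / 0.500
response time (F_ON = 0.5):  1.63 h
```

The early cohort reaches half-max expression at ~1.5 h; the repressed
cohort only follows ~6 h later, when glucose hits the bifurcation
threshold — δ_g is the length of that bimodal window, and F_ON-mid the
fraction of early activators. `examples/01_bifurcation_scan.py` and
`examples/02_basins_and_eigenvalues.py` show the model-side story: a
bistable glucose band at 150 nM galactose whose ON state loses both basin
volume and relaxation speed as glucose rises.

Other capabilities: `examples/04_sugar_kinetics.py` (Hill fits, metabolic
delay, diauxic dip), `examples/05_quasi_static_prediction.py` (coherent-
activation prediction and δ_b). A thin CLI mirrors the library:
`galswitch simulate|bifurcate|basins|synth|analyze|sugars|run`.

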