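# Methods

## Model

The model is a deterministic mass-action network over 16 species

```
DA, DA_rad (DA•⁻), DAQ, DAL, DAC, DecayProducts,
O2, O2_rad (O₂•⁻), H2O2, OH_rad (•OH),
FeII, FeIII, AFO, FeIIDA, FeIIIDA, FeIIIDA2
```

and 29 reactions (9 autoxidation, 11 Fe(III), 9 Fe(II); four of them
reversible: 2, 13, 14, 24). Concentrations are molar, time is seconds, rate
constants are per M·s (bimolecular) or per s (unimolecular). The coupled
ODEs are d**c**/dt = S·**v**(**c**) with **v** the vector of directed
process fluxes k·Π[reactants] and S the stoichiometry matrix.

Assumptions and conventions:

* **Conditional constants; implicit protons.** pH enters only through the
  per-pH rate-constant columns (6.5, 7.0, 7.4). There is no H⁺ species, no
  charge balance, no activity correction, and no temperature dependence
  (the constants are conditional values for 22 °C, 0.1 M NaCl). Intermediate
  pH values are not interpolated by default; `build_network(ph,
  interpolate=True)` applies log-linear interpolation between the tabulated
  columns and is flagged experimental.
* **AFO in Fe-monomer equivalents.** Ferric oxyhydroxide is not modelled as
  a discrete polymer: the dimerization step 2 Fe(III) → 2 AFO conserves iron
  exactly, and each surface reaction (dopamine-induced dissolution,
  reductive dissolution, superoxide reduction) consumes one monomer
  equivalent and releases one iron. Second-order "surface" constants are
  therefore per monomer-equivalent molarity.
* **Reaction 29.** The one-electron reduction of the semiquinone by free
  Fe(II) is encoded as FeII + DA•⁻ → FeIII + DA, the free-iron analogue of
  reaction 28 (and with the same constant, 1.92×10⁵ M⁻¹s⁻¹); any other
  product assignment would violate the iron or catechol-skeleton budget.
* **Conservation invariants.** Every reaction conserves iron (FeII, FeIII,
  AFO, FeIIDA, FeIIIDA, FeIIIDA2 carry 1 Fe) and catechol skeletons (DA,
  DA•⁻, DAQ, DAL, DAC, DecayProducts, FeIIDA, FeIIIDA carry 1; FeIIIDA2
  carries 2). `validate_network` checks both budgets plus rate-constant
  positivity; the test suite asserts the budgets over all 29 × 3 entries
  and asserts drift below 10× the solver rtol along trajectories.

## Scenarios, oxygen, and integration

A `Scenario` fixes pH, the initial state (all unlisted species start at 0;
added iron enters as free inorganic FeII/FeIII at t = 0 with no
pre-equilibration), the oxygen mode, clamps, duration and solver settings.

* **Oxygen.** `closed` sets [O₂] from the percent of air saturation and
  lets it evolve; `clamped` holds it constant (continuous sparging);
  `anoxic` clamps it at zero. Air saturation (21%) corresponds to
  2.5×10⁻⁴ M dissolved O₂ — a standard solubility figure for ~22 °C and
  0.1 M ionic strength — and x% saturation scales linearly as (x/21) of
  that value. The reference molarity is a scenario field, not a constant.
* **Clamping** zeroes the clamped species' net derivative; its reactions
  still drive every other species, matching fixed-concentration semantics.
  Clamped output series are forced exactly to the initial value.
* **Integration** uses LSODA (scipy `solve_ivp`) with rtol 1e-8 and atol
  1e-14 M by default (tests that trade precision for speed use 1e-6/1e-12).
  The output grid is 200 log-spaced points plus any user-requested sample
  times; requested times are part of the solver grid, so observable
  predictions at data times involve no interpolation error. Concentrations
  more negative than ~10³·atol abort with an integration error carrying the
  last good time; shallower negatives are clipped to zero on output.
  Per-reaction net fluxes (forward − reverse) are recorded on the same
  grid.
* An independent brute-force flux oracle (`reaction_flux_oracle`,
  `oracle_rhs`) recomputes every directed process straight from the
  reaction list; the vectorized right-hand side must agree with its
  stoichiometry-weighted sum to 1e-12 relative to the total flux magnitude.

## Observables

* **Ferrozine Fe(II)**: [Fe(II)] = (A₅₆₂ − ε_Fe(III)·Fe_T·l) /
  ((ε_Fe(II) − ε_Fe(III))·l), clipped to [0, Fe_T] with a flag. The assay
  responds to inorganic plus complexed Fe(II), so the model-side observable
  is [FeII] + [FeIIDA].
* **475/580 nm deconvolution** of DAC vs Fe^III^DA₂ uses the measured
  absorptivities ε_DAC,475 = 3245, ε_DAC,580 = 439 and ε_Fe(III)DA₂,580 =
  3121 M⁻¹cm⁻¹ with a 10 cm path. ε_Fe(III)DA₂,475 has no published value
  and is a **required** configuration field; the synthetic-data module
  ships a clearly-labelled fixture (1500 M⁻¹cm⁻¹), as do the ferrozine
  coefficients (27 900 / 1860 M⁻¹cm⁻¹). The default "sequential" solver
  pivots the bis complex out of the 580 nm equation first — the
  measurement's ordering — implemented as exact Gaussian elimination, so it
  agrees with the joint 2×2 solve to rounding error and the
  forward/deconvolve round trip is the identity to 1e-10. The
  mono-complex's absorbance is neglected (weak absorber at low
  concentration).
* **H₂O₂** inverts a linear 551 nm calibration, flagging extrapolation and
  clipping negative blanks to zero.

## Metrics

* **Iron turnover rate (TOR)**: the summed instantaneous oxidation flux of
  Fe(II) species — reactions 21, 22, 23 (free Fe(II)) and 25, 26, 27
  (Fe(II)DA) — divided by total iron; units s⁻¹. The semiquinone routes
  (28, 29) are excluded from the sum by convention. Fold-change comparisons
  cancel the normalization; the absolute scale is a documented convention,
  not a measured quantity.
* **•OH production rate**: flux₂₃ + flux₂₆ (Fenton chemistry of free and
  complexed Fe(II)).
* **DAC production rate**: formation (flux₅ + flux₆) net of first-order
  decay (− flux₉); a gross variant omits the decay term.
* **Initial rates** are least-squares slopes of concentration vs time over
  a window (default: the full 120 min, matching how near-linear traces are
  summarized), reported in µM/h.
* **Steady-state grids** clamp chosen species (DA, H₂O₂, O₂) at grid
  values and simulate until pseudo-equilibrium: all unclamped species
  satisfy |dC/dt|/max(C, atol) < 1e-6 s⁻¹, or 24 simulated hours elapse,
  whichever is first (the latter flags the cell unconverged). Failing
  cells are flagged, not fatal.

## Sensitivity and fitting

The sensitivity statistic is the relative residual r (mean absolute
relative deviation); it is undefined when the reference contains zeros.
One-at-a-time sweeps default to 6 decades centred on the table value with
5 points per decade; multiple observables concatenate with equal weight;
ties at the minimum resolve to the smallest rate constant; failed
simulations score an infinite residual and the sweep continues. The "shift
point" is the argmin; the influence score is max(r) − min(r) over finite
cells (0 for a flat sweep, i.e. a reaction whose reactants never occur in
the scenario).

Fitting optimizes selected forward/reverse constants in log₁₀ space with
box bounds (default: table value × 10^±3) by least squares (lmfit), with
per-point standard deviations as weights when provided and the r-loss as an
alternative. The first start is the table value; additional starts are
drawn log-uniformly within bounds from a seeded generator, so results are
bit-reproducible for a fixed seed. A post-fit perturbation check flags
parameters whose half-decade displacement leaves the loss unchanged
(unidentifiable in the scenario). The commercial software originally used
to fit these constants is not replicated — only the outcome contract
(constants that describe the data).

## Synthetic data

`generate_dataset` simulates a scenario, reads the observable channels off
the trajectory, and adds independent Gaussian noise with
sd = max(relative_sd·value, floor), truncated at zero (assay readouts are
non-negative; the truncation bias is excluded from mean-convergence checks
at low signal). Defaults emulate the bench protocol: triplicates, samples
every 10 min over 0–120 min, 5% relative noise with floors of 0.02 µM
(H₂O₂, DAC) and 0.05 µM (iron species) — declared fixture values, since the
real assays' error structure is unpublished. Datasets carry full generating
metadata (scenario, noise, seed, network hash) and regenerate bit-exactly.
The generator does not model instrument drift, correlated pipetting error,
or quenching-step kinetics, so passing tests demonstrate correctness of the
pipeline's algebra and estimators under idealized i.i.d. noise, not
robustness to real instrument pathologies.

The scenario catalogue (`bench_scenario`) encodes the emulated bench
conditions by figure-style name: 20 µM DA autoxidation at each pH; 20 µM DA
± 5 µM Fe(II)/Fe(III) air-saturated; 5 µM Fe(II) + 10 µM DA at 2.5/5/21%
O₂; anoxic 5 µM Fe(III) + 50 µM DA; and 5 µM Fe(II) ± 30 µM DA for
turnover readouts.

## Numerical choices and problem sizes

All headline quantities are single ODE integrations of the 16-species
system over 2–24 simulated hours on a 201-point output grid; each runs in
well under a second. The fit-recovery contract (constants 1, 21, 24f, 25
planted at 0.3–3× and re-estimated from 2%-noise triplicates) uses 20
seeded repetitions per constant with 13 sample times over 0–120 min and a
single optimization start from the table value. Event times (half-lives,
depletion times) interpolate linearly between grid points.

## Known limitations

* **Fe(II) oxidation timescales in the presence of dopamine.** With the
  tabulated constants, the Fe(III)DA₂ pool formed during Fe(II) oxidation
  feeds Fe(II) back through ligand-to-metal charge transfer (k₁₇ =
  7.26×10⁻⁵ s⁻¹ directly, plus dissociation through k₋₁₄ and the
  mono-complex LMCT k₁₆), sustaining a ferrozine-visible Fe(II) plateau of
  roughly 1 µM (≈20% of 5 µM total) at pH 7.0 with 10 µM DA. Complete
  (≥95%) Fe(II) oxidation is therefore only reached after the bis-complex
  reservoir drains (~20 h), far later than the ~70 min reported for the
  corresponding experiment; the reported values themselves are mutually
  inconsistent for this condition (30 min in one statement, ~70 min in
  another). Relatedly, the simulated no-dopamine half-life of Fe(II) in an
  air-saturated closed system at pH 7.0 is 2.8 h; this matches the reported
  40% decrease over 2 h at 21% O₂ (and 10% at 5% O₂ — the model gives 39%
  and 11%) but not the separate claim that Fe(II) "halved over 2 h".
  No constant was adjusted to force agreement; the tables are encoded as
  printed.
* The network has no •OH sinks: hydroxyl radical is a terminal product and
  its concentration is only meaningful as a cumulative production measure.
* No spatial or compartmental structure, no stochastic simulation, no
  buffer chemistry, no thermodynamic speciation solver, and no neuromelanin
  polymerization; Fe(III)DA₂ is the terminal complex (no tris complex).
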