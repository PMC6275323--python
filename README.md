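# fedakin — pH-dependent kinetics of iron-mediated dopamine oxidation

`fedakin` is a kinetic-modelling toolkit for the coupled redox chemistry of
dopamine (DA) and labile iron in mildly acidic to neutral aqueous systems —
the chemistry implicated in oxidative stress and aminochrome toxicity in
dopaminergic neurons. It implements a 29-reaction mass-action network with
conditional rate constants at pH 6.5, 7.0 and 7.4, covering:

* **dopamine autoxidation** — DA + O₂ → DA•⁻ + O₂•⁻, disproportionation to
  the *o*-quinone (DAQ), cyclization to leukoaminochrome (DAL) and oxidation
  to aminochrome (DAC), with first-order DAC decay;
* **Fe(III) chemistry** — precipitation of amorphous ferric oxyhydroxide
  (AFO, tracked in Fe-monomer equivalents), dopamine-induced dissolution,
  mono-/bis-catecholate complexation (Fe^III^DA, Fe^III^DA₂) and
  ligand-to-metal charge transfer;
* **Fe(II) chemistry** — oxygenation (Fe(II) + O₂ → Fe(III) + O₂•⁻), Fenton
  chemistry (Fe(II) + H₂O₂ → Fe(III) + •OH), and the analogous oxidation of
  the Fe(II)–dopamine complex.

On top of the simulator it provides the models of the bench assays used to
observe this chemistry (ferrozine Fe(II), two-wavelength 475/580 nm
deconvolution of DAC vs Fe^III^DA₂, DPD/HRP H₂O₂ calibration), derived
metrics (iron turnover rate, •OH and DAC production, clamped-species
steady-state grids), one-at-a-time rate-constant sensitivity analysis via
the relative residual

    r = (1/n) Σᵢ |MPᵢ − EDᵢ| / EDᵢ ,

bounded least-squares rate-constant fitting in log space, and a synthetic
dataset generator emulating triplicate noisy assay time series.

Intended users: chemical kineticists and quantitative biologists studying
metal-catecholamine redox chemistry, and anyone needing a tested, scriptable
reimplementation of this reaction network.

## Worked example

Simulate autoxidation of 20 µM dopamine at pH 6.5 in an air-saturated,
continuously sparged solution and summarize H₂O₂ production:

```python
import fedakin as fk
from fedakin.simulate import Scenario
from fedakin.metrics import initial_rate

sc = Scenario(ph=6.5, init={"DA": 20e-6}, o2_mode="clamped", t_end=7200.0)
traj = fk.simulate(sc)
print("rate:", round(initial_rate(traj, "H2O2", 7200.0), 4), "uM/h")
print("H2O2 at 2h:", round(traj.at("H2O2", 7200.0) * 1e6, 4), "uM")
```

prints

```
rate: 0.0709 uM/h
H2O2 at 2h: 0.1418 uM
```

i.e. spontaneous dopamine oxidation at the acidic end of the range produces
hydrogen peroxide at ~0.07 µM h⁻¹ — slow compared to pH 7.4 (~0.26 µM h⁻¹
under the same conditions), because the oxidation is carried by the
deprotonated dopamine fractions that grow with pH.

The same computations are exposed on the command line; for example the
fold-amplification of the iron turnover rate by 30 µM dopamine at pH 6.5:

```bash
$ fedakin reproduce tor_fold_50min_pH6.5
[PASS] tor_fold_50min_pH6.5: 10.26 fold vs 10 (+2.6%)
```

Other subcommands: `simulate` (tidy concentration/flux CSVs), `generate`
(synthetic replicate datasets), `sweep` (sensitivity), `scan`
(steady-state metric grids), `fit`, `catalogue`.

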