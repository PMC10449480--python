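# meltcycle

Thermal-denaturation analysis for **combinatorial protein variant
ensembles**: melting-curve reduction and Tm estimation from
Thermofluor/DSF plates and far-UV CD thermal scans, three-state
(native → molten globule → unfolded) population modelling, full 2⁴
factorial regression of melting temperatures against a mutational
design matrix, and conversion of temperature perturbations into
coupling free energies.

The package is built around the stability screen of the
*G. stearothermophilus* tryptophanyl-tRNA synthetase (TrpRS) D1-switch:
all 16 combinations of four core-packing mutations (I4V, F26L, Y33F,
F37I), each melted in six replicates on a 384-well plate heated
25 → 95 °C in 0.4° steps. Two probes see two successive transitions —
Sypro-Orange fluorescence reports loss of native core packing (the φ
transition, to a molten globule) and ellipticity at 221 nm reports
helix melting (the θ transition).

## The model

Each melt is a van't Hoff two-state sigmoid between linear baselines,

```
y(T) = (1 − f)·B_N(T) + f·B_U(T),
f(T) = 1 / (1 + exp[(ΔH_vH/R)(1/T − 1/T_m)])        (T in kelvin)
```

fitted per well ("Model" method) and cross-checked by baseline
extrapolation ("Ratio" method: the f = 0.5 crossing). The two fitted
transitions combine as sequential equilibria S1 ⇌ S2 ⇌ S3 with
ΔG_i(T) = ΔH_i(1 − T/T_m,i), giving the three state populations
P₁, P₂, P₃.

Per-variant melting temperatures are regressed on the full factorial
design,

```
T_m,i = β₀ + Σ β_j F_j + Σ β_jk F_j F_k + Σ β_jkl F_j F_k F_l
          + β_1234 F₁F₂F₃F₄ + ε_i ,      F_j ∈ {0,1}
```

so every main effect, the six two-way, four three-way and the four-way
coupling are estimated with replicate-based standard errors and Student
P values. Coefficients (in °C) convert to incremental folding free
energies through the proportionality δT_m/T_m0 = δΔG/ΔH, using the
calorimetric enthalpy partition ΔH_tot = −46, ΔH_φ = −27,
ΔH_θ = −11 kcal/mole.

Because raw plate data for such screens are rarely redistributable, the
package includes a first-class synthetic generator
(`meltcycle.synthetic_data`) that emulates the full acquisition — true
Tm structure from the factorial model, two probes, replicates, batches,
amplitude-proportional noise, optional post-transition fluorescence
quench — so every analysis stage is testable by parameter recovery.

## Worked example

Simulate an ensemble with a single injected effect — a 2.5 °C
stabilization of the φ transition by wild-type F37 — plus 2% amplitude
noise, then run the whole pipeline:

```python
import numpy as np
import meltcycle as mc
from meltcycle.pipeline import RunConfig, run_pipeline

beta = np.zeros(16)
beta[mc.TERM_NAMES.index("F37")] = 2.5
cfg = RunConfig(
    outdir="demo", scale="CELSIUS",
    simulate=mc.GeneratorConfig(beta_phi=beta, noise_sd=0.02, seed=7),
)
report = run_pipeline(cfg)
print(report.coefficients_phi.table().head())
```

prints (abridged):

```
    term  beta_C   se_C         t      P
Constant 63.9341 0.0462 1383.6178 0.0000
      I4 -0.0591 0.0653   -0.9050 0.3682
     F26  0.0252 0.0653    0.3851 0.7012
     Y33 -0.0576 0.0653   -0.8822 0.3803
     F37  2.5832 0.0653   39.5293 0.0000
R2_phi = 0.9935
```

The injected F37 main effect is recovered (2.58 ± 0.07 °C vs 2.5 true);
the null terms are correctly non-significant; and the energy table
converts the coefficient to ΔΔG_φ ≈ −1.09 kcal/mole, i.e. the mutation
F37I destabilizes the native state relative to the molten globule.
Output CSVs (`fits.csv`, `summary.csv`, `coefficients_*.csv`,
`energy_table.csv`, `profiles.csv`, `state_metrics.csv`) and a
`manifest.json` land in `demo/`.

The same pipeline runs from the shell:

```
meltcycle simulate --out sim --seed 7
meltcycle run --config run.yaml --out demo --seed 7
```

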