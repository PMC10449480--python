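# Methods

## Two-state forward model and Tm estimation

Each transition is modelled as a van't Hoff two-state equilibrium with
linear pre- and post-transition baselines:

    y(T) = (1 − f(T))·(a_N + b_N T) + f(T)·(a_U + b_U T)
    f(T) = 1 / (1 + exp[(ΔH_vH/R)(1/T_K − 1/T_m,K)])

Temperatures are °C at every interface and converted to kelvin only
inside thermodynamic expressions (R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹).
ΔH_vH > 0 is the van't Hoff enthalpy of *unfolding* and controls
steepness; it is an effective two-state parameter, not the calorimetric
enthalpy. ΔS is implied by the two-state condition ΔS = ΔH/T_m rather
than fitted. ΔCp is taken as zero — adequate over the ±15 °C each
transition spans, and the minimal model consistent with two successive
quasi-two-state steps.

**Transition bounds.** The smoothed first derivative (Savitzky–Golay,
window 11 points ≈ 4.4 °C, order 2; configurable) is centred on its
median so a uniform baseline slope does not register as signal. Walking
outward from the derivative peak to the points where |dy/dT| falls
below 10% of the peak gives the sigmoid segment; everything outside is
baseline window. A peak that does not rise above 3× the derivative's
scaled median absolute deviation means no detectable transition, and
the well is flagged for manually supplied bounds (a per-well override
table; there is no interactive prompt).

**Model method.** Nonlinear least squares over all six parameters
(`scipy.optimize.curve_fit`), initialised from linear fits in the
baseline windows, the derivative-peak temperature and a generic
50 kcal/mole enthalpy; bounds keep T_m inside the scan and ΔH_vH in
[1, 500] kcal/mole. Non-convergence triggers two seeded restarts with
T_m perturbed ±2 °C; a still-failing or bound-pinned fit is returned
flagged and excluded from averaging, never silently dropped.

**Ratio method.** Baselines fitted in the windows and extrapolated;
T_m is the f = 0.5 crossing by linear interpolation, choosing among
multiple crossings the one nearest the derivative peak. The method
errors out if the baselines cross inside the transition or f never
reaches 0.5. Limitation: the 10%-derivative windows still contain a
few percent of sigmoid tail. For transitions whose plateaus are
sampled within the scan this biases T_m by well under half a grid step
(measured worst case 0.37 °C over T_m ∈ [50, 70], ΔH_vH ∈ [60, 150]);
a broad transition within ~15 °C of the scan edge has no observable
unfolded baseline and the extrapolation is biased low by up to ~0.6 °C.
The model method is unaffected and is the default.

**DSF truncation.** Sypro-Orange fluorescence decays above the
transition as unfolded protein aggregates. DSF traces are truncated at
the global fluorescence maximum before any fitting; the two-state model
cannot represent the decay, and fabricating a kinetic aggregation model
is out of scope. A few quenched points always survive before the
maximum, so truncation-rescued fits are good to a fraction of a degree
rather than exact.

## Three-state populations

With the φ fit (DSF) and θ fit (CD 221 nm) as sequential equilibria
S1 ⇌ S2 ⇌ S3:

    K_i(T) = exp[−ΔH_i(1 − T_K/T_m,i,K) / RT_K]
    P1, P2, P3 = 1, K₁, K₁K₂  (each / (1 + K₁ + K₁K₂))

The P₂ maximum (grid search plus local quadratic refinement), the P₁
and P₃ values there, and the P₁ = P₃ crossing are unconstrained by the
fits and serve as validity metrics of the three-state approximation:
sharp, well-separated transitions give P₂max → 1 with P₁, P₃ → 0
between the midpoints. Note the diagnostic power depends on steepness:
at the ensemble's 8.5 °C gap, ΔH_vH of 300/250 kcal/mole gives
P₂max ≈ 0.99 while the generator's default 80/60 gives ≈ 0.64. The
low-temperature transition visible in heat-capacity profiles is not
modelled.

## Factorial regression

The 16 variants are indexed by a 4-bit barcode (I4 least-significant;
wild type 0, I4V 1, quadruple mutant 15). The design matrix has the
fixed term order constant; 4 mains; 6 pairs (lexicographic); 4 triples;
quadruple. Default coding is ZERO_ONE (indicator of mutation
*presence*, so "F37" coefficients quantify the effect of *removing*
phenylalanine 37); CENTERED (−½, +½) coding is offered, under which
each main-effect contrast is the mutation's effect averaged over its 8
background contexts. The two are linearly related; on noise-free data
the ZERO_ONE coefficients equal the alternating-sum multi-mutant
thermodynamic-cycle differences (Möbius inversion over mutation
subsets), which the tests verify against a combinatorial oracle.

Observations enter as per-replicate rows (96 = 16 × 6 by default), so
residual degrees of freedom for Student tests come from replicate
scatter — the only way a saturated 16-term model can report standard
errors. OLS is delegated to statsmodels; SE/t/P are NaN when
df_resid = 0.

**Model reduction.** Backward elimination removes, one at a time, the
highest-P term with P > 0.5 (refitting after each removal), subject to
weak heredity: a term is never removed while a retained significant
(P < 0.05) higher-order term contains it; the constant is never
removed. Both thresholds are configurable. A consequence worth knowing:
a truly null term has a uniform P value, so the P > 0.5 rule eliminates
it only about half the time — its protection is the P value it reports,
not guaranteed removal. Reduction is therefore off by default in the
recovery pipeline and enabled explicitly (`reduce: true`).

**Batch alignment.** Two measurement batches are reconciled by a single
additive offset — the mean over shared variants of the per-variant Tm
difference — before pooling; the offset is additive (units are
degrees), with no multiplicative option. At least 4 shared variants are
required; partial overlap warns.

## Free-energy conversion

A melting-temperature perturbation maps to an incremental folding free
energy via δT_m/T_m0 = δΔG/ΔH, applied per retained regression term
with the transition-specific calorimetric enthalpy (ΔH_φ = −27,
ΔH_θ = −11 kcal/mole out of ΔH_tot = −46; the negative unfolding
convention of the source calorimetry is preserved, and the partition is
not forced to close — the ~−8 kcal/mole remainder belongs to the
unmodelled low-temperature transition). The denominator scale is
selectable: KELVIN is the physically motivated default; CELSIUS is a
compatibility mode, retained because published per-term energies
back-solve to a ~64 °C reference only on the Celsius scale. Round trips
(energies → δT_m → energies) are exact in either mode provided
generation and recovery use the same mode; the recovery tests use
CELSIUS with T_m0,φ = 64.0 °C and T_m0,θ = 72.5 °C.

## Synthetic generator

Defaults mirror the study conditions: 16 variants × 6 replicates,
25 → 95 °C in 0.4° steps (176 points, 8.7 s dwell), DSF and CD221
probes, single batch. True melting temperatures follow the factorial
model with wild-type T_m,φ = 64.0 °C — an implementation choice (no
absolute T_m is published) consistent with the Celsius back-solution
and placing both transitions comfortably inside the scan. The
per-variant θ−φ gap is a fixed 16-entry table with mean exactly
8.5 °C and population SD 0.8 °C, making the ensemble-mean gap
deterministic. Default van't Hoff enthalpies are 80 (φ) and 60 (θ)
kcal/mole; noise is Gaussian with SD = 2% of transition amplitude;
every stochastic path takes an explicit seed (default 20230823) and the
noise stream is keyed by (seed, probe) so datasets are bit-reproducible.

What the generator does *not* emulate: aggregation kinetics (only a
phenomenological linear post-peak quench envelope), dimer dissociation,
dye-binding equilibria, temperature-dependent baselines' curvature, or
the low-temperature transition. Passing recovery tests therefore show
the analysis is self-consistent and unbiased under the stated noise
model — not that real instrument artefacts are handled beyond the
flag-and-exclude policy.

## Numerical and testing choices

* Ingestion never interpolates: wells with missing/non-numeric cells
  are flagged and excluded (midpoint fitting is sensitive to fabricated
  points); duplicate (well, temperature) records are fatal.
* Text outputs use 12 significant digits, so write → parse round trips
  preserve values to within 1 part in 10¹⁰.
* The noise-coverage property (recovered β within 3 SE of truth with 2%
  noise and 6 replicates) is scored as the fraction of all
  (simulation, term) pairs over 200 seeded simulations and must be
  ≥ 95%; the "all 16 terms simultaneously per simulation" reading has a
  nominal coverage of only ~0.94 under the t-distribution and is not a
  property of a correct implementation.
* Problem sizes in the test suite: noise-free recovery uses one to six
  replicates per variant (one ensemble fit is ~100 curves and takes
  about a second); the coverage study is the largest computation at
  200 × 96 curve fits.
* The `pipeline_cli` surface is a thin click wrapper (`meltcycle
  simulate | fit | states | regress | energies | run | report`); all
  logic lives in the library and the run manifest records version,
  seed and a configuration hash so identical configs give byte-identical
  CSVs.
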