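# Methods

## The model

`adcpk` implements a semi-mechanistic, multiple-analyte population
pharmacokinetic model for a monomethyl-auristatin-E (MMAE)
antibody-drug conjugate (ADC) dosed intravenously in cynomolgus
monkeys.  The conjugate is a mixture of drug-to-antibody-ratio (DAR)
species n = 0..8.  Each species distributes between a central and a
peripheral compartment and is eliminated from the central compartment
by two routes:

* **Proteolytic degradation** — saturable (Michaelis–Menten) catabolism
  of the whole conjugate, rate `Emax·Xnc/(Km·Vc + Xnc)` per species,
  releasing all n drugs of a degraded antibody;
* **Deconjugation** — sequential loss of one drug, DAR n → DAR n−1, with
  per-site rate constant following a Weibull density in the transformed
  DAR `x = 8 − n`:

  `K_ADCn = K·(κ/λ)·(x/λ)^(κ−1)·exp(−(x/λ)^κ)`,   K fixed at 1 h⁻¹.

For amounts (nmol), with `n = 8..0`:

```
dXnc/dt = −(CLd/Vc)·Xnc + (CLd/Vp)·Xnp − Emax·Xnc/(Km·Vc+Xnc)
          − n·K_ADCn·Xnc + (n+1)·K_ADC(n+1)·X(n+1)c
dXnp/dt = (CLd/Vc)·Xnc − (CLd/Vp)·Xnp
```

Free MMAE follows linear two-compartment kinetics driven by the two
release fluxes `Amp = Σ n·Emax·Xnc/(Km·Vc+Xnc)` and
`Amd = Σ n·K_ADCn·Xnc`:

```
dXmc/dt = Fmp·Amp + Fmd·Amd − (CLm/Vm + CLmd/Vm)·Xmc + (CLmd/Vmp)·Xmp
dXmp/dt = (CLmd/Vm)·Xmc − (CLmd/Vmp)·Xmp
```

`Fmp` and `Fmd` are the fractions of pathway-released drug that appear
as measurable free MMAE in plasma (deconjugation largely produces
linker-bearing catabolites the MMAE assay does not see, hence the small
`Fmd`).  Two auxiliary states accumulate `Amp` and `Amd` so that
pathway attribution is integrator-consistent rather than post-hoc
quadrature.

Observed analytes: total antibody `Tab = Σ Xnc/Vc` (µg/mL via the
antibody MW 145 239 g/mol), conjugated drug `acMMAE = Σ n·Xnc/Vc` (nM)
and free MMAE `Xmc/Vm` (nM).

### Equation corrections

The source equations as printed contain transcription defects that
violate mass balance; the implementation uses the corrected forms: the
peripheral equation carries `−(CLd/Vp)·Xnp` for every species, and the
proteolytic release flux is `Σ n·Emax·Xnc/(Km·Vc+Xnc)` with the DAR 0
species degrading without releasing drug.  `Emax` is used with units
nmol/h (amount/time), which is the only dimensionally consistent
reading of the elimination term.

### The DAR 8 deconjugation rate

With `x = 8 − n` and shape κ = 1.10 > 1 the Weibull density is zero at
the origin, so the DAR 8 species has a *zero* deconjugation rate even
though the narrative around the model says the highest-DAR species
sheds fastest (a reported rate of 3.52 h⁻¹).  No mapping of x onto DAR
reproduces that value from the reported λ, κ and K; the package keeps
the literal `x = 8 − n` as the default and exposes
`dar_mapping ∈ {"8-n", "9-n", "n"}` for sensitivity analysis.  With
κ < 1 the density is unbounded at the origin; the origin rate is
clamped to zero there as well, since an infinite rate constant is
unphysical.

## Default parameters

Typical values (units as above): Emax 0.0407 nmol/h, Km 0.959 nmol/L,
Vc 0.0996 L, CLd 0.00197 L/h, Vp 0.183 L, λ 1.51, κ 1.10, Fmp 0.783,
Fmd 0.0242, CLm 2.27 L/h, Vm 1.00 L, CLmd 23.0 L/h, Vmp 88.4 L.
Derived checks: the free-MMAE distribution/elimination half-lives are
0.0272 h and 29.9 h; Vc corresponds to ≈40 mL/kg at the default 2.5 kg
body weight (plasma volume, as expected for an antibody).

Inter-individual variability (IIV) is log-normal and diagonal, carried
by exactly six parameters with variances ω²: Emax 0.0945, Vc 0.0118,
Vp 0.230, Fmd 1.78, CLm 0.333, Vmp 0.0670.  Residual error is
proportional on each analyte's reporting scale with SD σ: acMMAE 0.257,
Tab 0.194, MMAE 0.327.  The source table does not state whether its IIV
column is a variance or an SD; the package reads it as a **variance**
(the convention of the estimation software family it derives from) and
the σ column as an **SD** (giving assay-plausible 19–33% residual CVs).
A config switch (`iiv_scale: sd`) flips the IIV interpretation.

## Synthetic data

No individual-level data are public, so the package reconstructs the
study *design* and generates synthetic datasets with the stated
statistical structure:

* single IV conjugate doses 0.3/1/3 mg/kg, 4 subjects each, all three
  analytes at {0, 5 min, 4, 12, 24, 72, 168, 336, 504, 672, 840, 1008} h;
* 3/5 mg/kg conjugate q3w ×4 (504 h interval), 10 subjects each, Tab and
  MMAE only, rich sampling after doses 1 and 4 and pre-dose/0.25 h after
  doses 2–3;
* single IV MMAE 0.03/0.063 mg/kg, 10 subjects each, 12 samples to 504 h —
  52 subjects in total.

Body weight is fixed at 2.5 kg.  Censoring applies the assay limits
0.05 nM (MMAE), 0.195 nM (acMMAE) and 0.06 µg/mL (Tab); censored
records are flagged, never deleted.  Pre-dose samples are evaluated
immediately *before* the dose, so the t = 0 record of a drug-naive
subject is a true zero reported as censored.  Per-subject random
streams derive from `SeedSequence([master_seed, subject_index])`, so
datasets are reproducible and adding subjects never perturbs existing
draws.  The generator reproduces the *scheduled* design (1432 records);
the historical analysis datasets were smaller through attrition the
text does not describe, and no attrition is emulated.  Assay-shaped
noise near the limits, anti-drug antibodies and dropout are likewise
out of scope, so passing tests validate the statistical machinery, not
those real-data features.

## Estimation

The reference analysis used a proprietary hybrid ITS-MCPEM
implementation; `adcpk` substitutes a documented ITS/EM-type scheme
claiming equivalence only at the level of parameter-recovery behaviour:

1. **Inner step** — per-subject MAP (empirical-Bayes) random effects by
   bounded quasi-Newton on the penalised log-likelihood.  Subjects with
   MMAE-only dosing have closed-form (eigen-decomposed two-compartment)
   predictions and only their CLm/Vmp effects active.
2. **Outer step** — (a) recentring of IIV-carrying typical values by the
   mean MAP effect; (b) ω² update by the curvature-corrected moment
   `mean(η̂² + posterior variance)` (the diagonal Laplace variance; this
   avoids the shrinkage collapse of the plain mode-based update, and the
   prior variance is used for effects a subject's data cannot inform);
   (c) per-analyte 1-D bounded searches for σ; (d) a blockwise
   quasi-Newton search of the shared structural parameters — the MMAE
   disposition block against the IV-MMAE subjects (closed-form, cheap),
   then the conjugate/release block against the conjugate-dosed subjects,
   which is an exact coordinate step because the MMAE-only subjects'
   likelihood does not involve those parameters.  An optional pooled
   warm-up (random effects zero) exists but is off by default: the
   pooled objective is biased under inter-individual variability and
   can strand the conjugate-block parameters in a spurious basin.
3. Below-limit records enter the likelihood as censored normal
   probabilities, `log Φ((LLOQ − f)/(σ·f))` (the M3 method); a zero
   prediction under censoring contributes log 1 = 0.

Structural parameters are estimated as logs (positivity) and the
release fractions as logits (boundedness).  The OFV is −2× the joint
penalised log-likelihood at the random-effect modes, including the
log-normal prior normalising constant; only OFV differences between
fits are meaningful.  BIC = OFV + k·ln(N) with N all
likelihood-contributing records (censored records carry information and
are counted).  Convergence: |ΔOFV| < 0.01 and max relative parameter
change < 10⁻³, or the sweep cap.

Model variants (for likelihood-ratio / Schwarz comparisons) are
realised by one generalised ODE kernel: an additional linear
proteolytic clearance (`clp`), a power-of-DAR multiplier on the
proteolytic capacity (`emax·((n+1)/5)^γ`), a constant (DAR-independent)
deconjugation rate, and deconjugation also in the peripheral
compartment.  With the default flags the kernel is bit-identical to the
final model.

## Numerics

* Stiff integration by LSODA with an analytic Jacobian (rate constants
  span ~23 h⁻¹ down to ~0.001 h⁻¹); the right-hand side is numba-jitted
  with a pure-Python fallback.  Simulation tolerances rtol 10⁻⁸ /
  atol 10⁻¹⁰ nmol; O(atol) negative excursions are floored at zero.
* Doses are instantaneous state increments with an integrator restart;
  a sample scheduled exactly at a dose time reads the pre-dose state.
* Finite-difference step 10⁻⁴ on transformed parameters for all
  quasi-Newton searches; 1-D σ searches bounded on [10⁻³, 3].
* ω² floored at 10⁻⁶ with a warning if an update degenerates.
* The linear (emax = 0) limit is verified against a matrix-exponential
  oracle to < 10⁻⁶ relative error; conjugated-drug mass balance
  Σ n·(Xnc+Xnp) + Amp_cum + Amd_cum is conserved to integrator
  tolerance.

## Problem sizes

The simulate-and-refit experiment in `scripts/acceptance.py` uses the
complete 52-subject design (1432 scheduled records) with a reduced
iteration budget (eight ITS sweeps), which recovers
the well-informed typical values (CLm, Fmp, Vc, Vm, σ's) to within the
finite-sample spread of a 52-animal study.  Test-suite fits use smaller
cohorts and tighter caps; they exercise the same code paths.

## Pathway attribution

For a dosed individual the share of circulating-MMAE input due to
proteolysis is `100·Fmp·Amp_cum(T) / (Fmp·Amp_cum(T) + Fmd·Amd_cum(T))`
at horizon T (default 1008 h, the last single-dose sampling time).  At
the typical parameters this is ≈99% at 0.3 mg/kg and ≈97% at 3 mg/kg:
although deconjugation moves *more drug off the antibody* than
proteolysis early after dosing, almost none of it appears as plasma
MMAE (Fmd ≈ 0.024 versus Fmp ≈ 0.78).  Population summaries report the
mean and min–max over simulated subjects; the wide range is driven by
the large Fmd variability (ω² = 1.78).

## Known limitations

* The ITS/EM scheme uses MAP modes and diagonal Laplace curvature, not a
  Monte-Carlo E-step, so ω² estimates retain some small-sample bias;
  typical values and σ are the well-calibrated outputs.  An importance
  sampling E-step hook (`mc_samples`) exists but is off by default.
* Weakly identified parameters (Km, CLd, λ, κ under sparse designs)
  converge slowly and inherit the finite-sample correlations of the
  52-animal design.  Approximate %RSE is available on request
  (`fisher_standard_errors`, or `adcpk fit --rse`): numerical Fisher
  information on the transformed scale with random effects at their
  modes — indicative precision, not exact marginal curvature.
* The model is linear in free-MMAE kinetics by assumption; very low
  MMAE concentrations after conjugate dosing are extrapolated from the
  IV-MMAE dose range.
* No tissue/tumour compartments, FcRn or target-binding submodels, and
  no covariate model beyond fixed body weight.
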