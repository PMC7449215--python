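# caspopk — caspofungin population pharmacokinetics and dose-finding

Caspofungin, a first-line echinocandin for invasive candidiasis, shows
high pharmacokinetic variability in critically ill patients, and the label
(SmPC) fixed-dose regimen leaves many ICU patients — especially heavier
ones — below the exposure associated with efficacy.  This package
implements the full analysis chain used to study that problem and to
evaluate weight-based dosing:

1. **Structural model** (`caspopk.pk_core`) — a linear two-compartment
   IV-infusion model in rate-constant parameterisation (Ke, kcp, kpc) with
   central volume scaled by body weight, `V = V0 · WT/78` (78 kg = cohort
   median).  Concentrations and AUCs are closed-form (bi-exponential hybrid
   constants, superposition over dose events, exact exponential
   primitives), which makes 1000-patient × 14-day Monte Carlo simulation
   cheap and exact.
2. **Population estimation** (`caspopk.popfit`) — a nonparametric
   adaptive-grid (NPAG-style) maximum-likelihood estimator: the population
   distribution is a discrete set of support points with probability
   masses.  Weights are solved by EM on the (convex) mixture likelihood;
   support locations are refined by the mixture-EM location step plus
   shrinking grid perturbations.  Residual error follows the assay
   polynomial `SD = C0 + C1·C` (0.05, 0.08) with a profiled multiplicative
   (gamma) or additive (lambda) scale.  Bayesian posteriors per subject,
   weighted parameter summaries (mean/SD/median/CV%), AIC/BIC, and an OLS
   covariate screen are included.
3. **Diagnostics** (`caspopk.diagnostics`) — observed-vs-predicted r,
   weighted bias (mean weighted prediction error) and imprecision
   (bias-adjusted mean weighted squared prediction error),
   prediction-corrected visual predictive checks, and external validation
   of independent cohorts without refitting.
4. **PTA engine** (`caspopk.pta`) — Monte Carlo probability of target
   attainment for fixed (70/50, 100/70, 70, 100 mg) and weight-based
   (2/1, 1.5/1.25, 2/1.25, 1, 1.5 mg/kg) regimens against a 24-h AUC
   target of 98 mg·h/L (200 mg·h/L upper threshold) and species AUC/MIC
   targets (C. glabrata 450, C. albicans 865, C. parapsilosis 1185) over
   MICs 0.01–1 mg/L.
5. **Synthetic cohorts** (`caspopk.synthetic`) — study-like data (20 ICU
   patients, weights 48–139 kg with median 78, label dosing, nine samples
   per occasion on day 3, five repeat occasions, 219 concentrations) with
   known ground-truth parameters, so the whole chain is testable without
   patient data.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each is a thin driver over the library; outputs land in `results/`):

```bash
python analysis/01_generate_cohort.py   # cohort.csv + truth.csv + manifest
python analysis/02_fit_population.py    # NPAG fit, summaries, covariate screen
python analysis/03_model_diagnostics.py # GOF, pcVPC, external validation
python analysis/04_pta_tables.py        # PTA tables
```

`01` prints the design fidelity check:

```
cohort: 20 subjects, 25 occasions, 219 concentrations
weights: min 48, median 78, max 139 kg
```

`03` reports the goodness of fit of the population model on that cohort —
population r 0.82 and individual (posterior-mean) r 1.00 here, against a
residual gamma scale fitted at 0.65:

```
     level      r    bias  imprecision   n
population 0.8172 -0.8407       1.7577 219
individual 0.9956  0.0080       0.0328 219
```

and `04` the dose-finding result.  At the day-3 window (48–72 h), a fixed
70 mg maintenance dose reaches the AUC ≥ 98 target for only a minority of
simulated patients and attainment collapses with weight (83% at 50 kg,
52% at 78 kg, 20% at 120 kg in this run), while weight-based regimens are
weight-independent by construction; the 2 mg/kg load + 1.25 mg/kg daily
regimen attains the C. glabrata AUC/MIC target of 450 in 100% of patients
up to the 0.06 mg/L EUCAST breakpoint, but no regimen covers
C. parapsilosis at MIC 1 mg/L:

```
mic               0.01   0.03   0.06  0.10  0.25  0.50  1.00
C. albicans      100.0  100.0   97.0  85.0  23.0   1.0   0.0
C. glabrata      100.0  100.0  100.0  99.0  71.0  20.0   1.0
C. parapsilosis  100.0  100.0   92.0  67.0   8.0   0.0   0.0
```

The same pipeline is available as a CLI (`caspopk datagen|fit|diagnose|pta`),
each run stamped with its seed and config hash.

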