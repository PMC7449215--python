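# Methods

## Structural model

The drug is described by a linear two-compartment model with zero-order
infusion input into the central compartment:

    dA1/dt = R(t) − (Ke + kcp)·A1 + kpc·A2
    dA2/dt = kcp·A1 − kpc·A2
    C(t)   = A1 / V,   V = V0 · WT / 78

with Ke the elimination rate constant (h⁻¹), kcp/kpc the
central↔peripheral distribution rate constants (h⁻¹), V0 the central
volume (L) referenced to the 78-kg cohort median weight, and WT the
subject's total body weight (kg).  Units are fixed package-wide: hours,
mg, litres, mg/L, mg·h/L.  V0 is treated as litres at the 78-kg
reference; the scaling `V = V0·WT/78` makes exposure under mg/kg dosing
exactly weight-free (`dose/V = dose_per_kg·78/V0`), which the tests assert
bit-for-bit.

Concentrations are evaluated in closed form through the hybrid constants
α+β = Ke+kcp+kpc, α·β = Ke·kpc: the unit-bolus response
`(A·e^{−αt} + B·e^{−βt})/V` with A = (α−kpc)/(α−β), B = (kpc−β)/(α−β) is
convolved with each infusion's boxcar and superposed over dose events;
AUC on any window is the exact integral of the piecewise bi-exponential.
β is computed as `αβ/α` to avoid catastrophic cancellation; when the two
roots coincide to within 1e-9 relative (a measure-zero configuration), β
is nudged by 1e-9 rather than adding a second code path; when kpc = 0 the
β-term's coefficient is exactly zero and the term is dropped.  The closed
form is the only production path — numerical ODE integration
(`scipy.integrate.solve_ivp`, rtol 1e-10) exists solely as the
independent oracle in the test suite, where the two agree to ≤1e-6
relative over parameter sets spanning 0.01–2× the population means.

Time origin is the start of the first infusion; all reporting windows
(0–24, 48–72, …, 312–336 h) are half-open.  Steady state is always
realised by simulating the full regimen, never by analytic shortcuts, so
accumulation during days 1–3 is represented faithfully.

## Residual error model

Observation SD follows the assay polynomial `SD = C0 + C1·C_obs` with
C0 = 0.05 mg/L, C1 = 0.08, inflated multiplicatively (`gamma·SD`,
default) or additively (`SD + lambda`) to absorb process noise.  The
scale is profiled during estimation by bounded golden-section search on
[0.1, 10] once per outer cycle, accepted only if the mixture likelihood
does not decrease.

## Nonparametric population estimation

The population distribution is a discrete mixture: support points θ_j
(four-dimensional parameter vectors) with masses w_j.  The marginal data
likelihood `Σ_i log Σ_j w_j L(subject_i | θ_j)` is maximised by
alternating:

1. **Weights.**  For a fixed support the problem is convex in w on the
   simplex; EM multiplicative updates (`w_j ← w_j · mean_i L_ij/Σ_k w_k
   L_ik`) are provably ascending and run to an objective tolerance of
   1e-6.  A subject whose likelihood underflows at every support point is
   reported by id.
2. **Support.**  Survivors (mass > 1e-6) are refined two ways per cycle:
   the mixture-EM location step (each point is moved to the maximiser of
   its responsibility-weighted log-likelihood, a bounded Nelder–Mead in
   log-parameter space), and coordinate perturbations of ±f·range with f
   starting at 20% and halving on stalls down to 0.1%.  The enlarged
   candidate set is re-solved with a warm start; the new configuration is
   kept only if the objective did not fall, so the recorded objective
   trace is non-decreasing by construction (the acceptance tests check it
   to 1e-8).

The initial support is a scrambled Halton set (default 2,048 points;
cohort-scale analyses here use 512, which the recovery experiments below
were run at) over the box Ke ∈ [0.005, 0.5] h⁻¹, V0 ∈ [1, 30] L, kcp,
kpc ∈ [0.01, 5] h⁻¹ — roughly the published means ± many SDs; a warning
is attached if the solution piles onto a box edge.  Because sparse PK
likelihoods form narrow correlated ridges (e.g. Ke–V0 trading off at
nearly constant clearance) that coordinate-wise moves cannot follow, the
grid is additionally seeded with per-subject individual estimates: each
subject's best grid point polished against its own likelihood.  This
two-stage initialisation is what lets a 512-point grid in four dimensions
resolve sharply peaked mixtures.

AIC/BIC use the explicit counting rule `n_par = 4·J + (J−1) + 1{scale
fitted}` for J final support points; the nonparametric "parameter count"
is convention-dependent and the rule is configurable.  Observations
flagged below the quantification limit are excluded with a logged count
rather than modelled.

Per-subject Bayesian posteriors reweight the support by prior × subject
likelihood; individual predictions use the posterior-mean parameters,
population predictions the prior-weighted mean of per-point predictions.

## Covariate screen

For each (parameter, covariate) pair the screen fits `posterior-mean
parameter ~ covariate` by OLS (statsmodels) and reports the slope, its
p-value and the AIC change against the intercept-only model, ordered by
p-value with a 0.05 threshold (forward-addition order).  Source
procedures of this kind sometimes conflate the p-value and AIC criteria;
the screen deliberately reports both and leaves the composite decision to
the analyst.  Constant covariates or constant responses are flagged
untestable rather than raising.  The final model's weight effect on V is
a fixed structural relation (`V = V0·WT/78`), applied during estimation,
not an estimated coefficient.

## Diagnostics

Prediction error is `observed − predicted` (so over-prediction yields
negative bias, reported in mg/L); weights are 1/SD² from the error model.
Bias = Σw·e/Σw; imprecision = Σw·e²/Σw − bias², floored at zero.

The VPC is prediction-corrected only: each observed and simulated value
is rescaled by (bin-median population prediction)/(own population
prediction); the variability-correction refinement is omitted as it
requires distributional detail this pipeline does not track.  Bins
default to the nine nominal sampling offsets ±0.5 h on the
time-after-dose axis.  Percentiles are linear-interpolation quantiles;
simulated bands are the 2.5–97.5% envelope of per-replicate percentiles,
and the stored simulated curves the across-replicate medians.  Records
with non-positive population prediction are excluded with a count.

External validation predicts an independent cohort from the fitted
distribution without refitting.  Digitized external cohorts that report
only a weight range receive one uniform draw per subject from that range
under the global seed.

## Monte Carlo PTA

Simulated patients are parameter vectors drawn either from a fitted
support (resampled by mass) or — when reproducing published tables whose
joint distribution was never printed — from independent log-normals
moment-matched to the published mean/SD per parameter
(μ = ln(m²/√(m²+s²)), σ² = ln(1+s²/m²)).  The independence approximation
is documented and matters: real joint supports correlate Ke and V0,
narrowing the clearance distribution, so mid-range PTA cells are not
exactly reproducible from marginal summaries alone.  Only the extreme
cells (low-MIC 100%, high-MIC 0%) are distribution-robust, and those are
what the acceptance checks pin to the published values.

Regimens are a loading dose at t = 0 and daily maintenance every 24 h,
1-h infusions, simulated over the full 14-day horizon.  Fixed-dose
regimens are evaluated at point weights 50/78/120 kg (a configurable
spread around each band exists but is off by default; the MIC table uses
the 78-kg median).  Per-kg regimens are evaluated at the reference
weight, which is exact because weight cancels.  Residual assay error is
not added to simulated AUCs — targets are model exposures.  PTA is
reported as round-half-up integer percent with raw fractions retained.

## Synthetic cohorts

The generator reproduces the study design, not its biology: 20 subjects;
weights honouring min/median/max anchors of 48/78/139 kg exactly (the two
middle order statistics pinned to 78 for even n, the rest sampled
uniformly below/above and the extremes pinned); label dosing (70 mg load;
50 mg daily ≤80 kg, 70 mg >80 kg; hepatic-impairment reductions
implemented); sampling on day 3 at pre-dose and 1, 2, 3, 4, 6, 8, 12,
24 h after the infusion start; five subjects resampled on day 6 after a
maintenance escalation of 40% from day 4 (real adjustment magnitudes were
not published — this value is synthetic and configurable); six samples
dropped from six distinct occasions, never the pre-dose sample; total 219
concentrations.  Truth distributions: a single point at the population
medians, a 50/50 two-point mixture (Ke 0.04 vs 0.16 h⁻¹), or independent
log-normals at the published moments (default).  Non-weight covariates
are sampled within cohort-table ranges (log-uniform for skewed labs)
purely as screen fodder; no physiological coupling is claimed, so a
passing covariate screen on synthetic data demonstrates only statistical
behaviour (type-I error, planted-signal power), not clinical covariate
effects.  Everything derives from one seed and cohort CSVs are
byte-reproducible.

What the synthetic data do not emulate: assay BLQ censoring, CVVH or
hepatic pathophysiology, correlated parameter–covariate structure, and
interoccasion variability.  Recovery results on synthetic cohorts
therefore bound estimator behaviour under the study design, not
performance on real ICU data.

## Numerical and scale choices

* Recovery experiments: 512-point initial grids, ≤60 cycles; a 20-subject
  cohort fit takes ~10–20 s on one CPU.  The population-mean recovery
  criterion (median over 10 seeded cohorts within 20% for Ke and V0)
  reflects the information content of a day-3-only rich design;
  individual seeds can err by more, dominated by Ke for slow
  eliminators observed over a single 24-h span.
* Monte Carlo PTA: n = 1,000 per the study design; at this size the
  binomial SE of a mid-range cell is ~1.6 points, while the pinned
  extreme cells are insensitive to n.
* pcVPC: 500 replicates.
* EM tolerance 1e-6 (objective), prune threshold 1e-6 mass, outer
  convergence when the cycle gain is below 1e-6 with the perturbation
  fraction at its 0.1% floor.
* Seeds: every stochastic component takes a single integer seed; the
  package default is 20200820.

## Known limitations

Plasma protein binding is not modelled (total concentrations only), as in
the source analysis.  Parametric mixed-effects estimation and
interoccasion variability are out of scope.  The PTA engine reproduces
dosing scenarios; it does not issue clinical recommendations.
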