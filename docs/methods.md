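# Methods

## The modelling problem

Late genitourinary toxicity after prostate radiotherapy is graded on ordinal
scales (0 = none … 4 = severe, e.g. hemorrhagic cystitis). Given each
patient's cumulative bladder dose–volume histogram (DVH) and a late-toxicity
grade, the analysis asks: which single dose level d makes V_d — the fraction
of bladder volume receiving at least d Gy — the best univariate predictor of
grade ≥ 2 toxicity, how well does the resulting logistic model discriminate
and calibrate, and what uniform-dose (EUD/NTCP) summary describes the same
outcome?

## Models

**DVH conventions.** All volumes are fractions in [0, 1]; readers divide
percent by 100 and absolute cm³ by the organ total. Cumulative curves are
gridded from 0 Gy (curves starting above 0 Gy are left-extended with
volume 1, which is physically forced), strictly increasing in dose and
non-increasing in volume. V_dose queries interpolate linearly on the
cumulative curve — the conventional treatment, since exported DVH tables do
not define behaviour between grid points — and return 0 beyond the recorded
maximum dose. Differential bins take v_i = cum_i − cum_{i+1} with the last
bin absorbing any residual volume at the maximum dose, so Σv_i = 1 always.

**Generalized EUD.** EUD = (Σᵢ vᵢ Dᵢᵃ)^{1/a} over differential bins, a power
mean with the structure-specific volume exponent a (bladder: a = 1.4, a mixed
serial–parallel organ). It is evaluated in log space to stay stable for large
|a|, tends to the maximum bin dose as a → +∞ and to the minimum as a → −∞,
and is monotone in a (power-mean inequality). Both limits and monotonicity
are property-tested.

**Logistic NTCP.** NTCP(EUD) = 1 / (1 + (TD₅₀/EUD)^{4γ₅₀}). TD₅₀ is the
uniform dose giving 50% complication probability; γ₅₀ is the normalized slope
TD₅₀·|dNTCP/dD| at TD₅₀, which for this functional form equals the γ₅₀
parameter exactly (checked numerically to 1e−5 relative via central
differences with step 1e−4·TD₅₀). Fitting maximizes the Bernoulli likelihood
with pᵢ = NTCP(EUDᵢ) over (log TD₅₀, log γ₅₀) — the log transform makes the
positivity constraints unconstrained — using Nelder–Mead with a 1e−8
log-likelihood tolerance. Non-convergence is flagged rather than raised.

**Univariate logistic risk model.** P = σ(a + b·X) with X the bladder volume
*fraction* (not percent) inside the reference isodose. The fraction scale is
deliberate: with rounded published coefficients a = −2.5, b = 4.3 the
tabulated (volume, risk) constraint pairs are only reproducible when X ∈
[0, 1] (σ(−2.5 + 4.3·0.59) ≈ 0.51). Fitting uses Newton ML (statsmodels)
with Wald standard errors and two-sided slope p-values — the conventional
report for a single-covariate logistic model — and AIC = 2k − 2·loglik with
k = 2. Complete separation is flagged (converged = False, slope p = NaN, BFGS
fallback estimates) rather than raised.

**Threshold scan.** For each candidate dose d on a grid (default 1 Gy steps
from 5 Gy to the cohort's 99th-percentile maximum dose), fit toxicity ~ V_d
and record AIC and slope p. The selected threshold has minimal AIC among
converged fits with p < 0.05; AIC ties break to the lowest dose
(deterministic); grid doses where V_d is constant across patients (e.g. 0 Gy,
where everyone is at 1) are skipped with a log notice. A refinement pass at
0.1 Gy over ± one coarse step around the provisional optimum is merged in by
default — the selected thresholds reported for this kind of analysis carry
sub-Gy resolution, and refinement can only lower the minimal AIC. The scan
accepts an outcome rule (grade ≥ k) and an optional subset filter so that
both full-cohort analyses and analyses restricted to patients with any
toxicity (discriminating grade ≥ 2 from grade 1) are runnable.

**Group comparison.** Mann–Whitney rank-sum on any per-patient dosimetric
scalar (mean bladder dose, V_dose), two-sided normal approximation with tie
and continuity corrections; the U statistic is exact-checked against an
all-pairs count in tests.

**Internal validation.** B bootstrap resamples (default 1000) of the
original size, drawn with replacement; the logistic model is refit on each
resample and its AUC (rank/Mann–Whitney formulation, ties at ½) computed on
that same resample, matching a per-dataset apparent-performance scheme. The
headline value is the median of the B AUCs; the mean is reported alongside,
and a Harrell-style optimism-corrected variant (fit on resample, score on the
original) is available as an option. Resamples with a single outcome class
are redrawn, not skipped, so the distribution always has B entries; redraws
are counted and a >50% redraw rate aborts (a guard — it cannot trigger for
cohorts with at least one case of each class, since the miss probability
(1−k/n)ⁿ ≤ e⁻¹).

**Calibration.** Hosmer–Lemeshow: observations grouped into deciles of
predicted risk (quantile cut, ties grouped; degenerate groups trigger an
automatic reduction in bin count with a log notice), statistic
Σ_g (O_g−E_g)² / (E_g(1−E_g/n_g)), df = groups − 2, upper-tail χ² p. p < 0.05
indicates lack of fit. Calibration-curve data are per-group (mean predicted,
observed rate, count).

**Risk tables.** Inverting P = σ(a + b·X) at risk level r gives
X* = (logit r − a)/b. Thresholds outside [0, 1] are reported with an
"unreachable" flag rather than clamped silently. Percentages render rounded
half-up to one decimal with a decimal point regardless of locale.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
treatment planning. Each patient's cumulative DVH is
cum(d) = s(d)/s(0) with s(d) = 1/(1 + exp((d − d50)/w)) — monotone,
two-parameter, and shaped like the banded bladder-DVH families of prostate
plans. Defaults: d50 ~ Normal(55 Gy, 8 Gy), w ~ LogNormal(log 6, 0.3), dose
grid 0–85 Gy in 0.5 Gy steps. These values were chosen so the volume fraction
at the 51.43 Gy predictor spans roughly (0.1, 0.95) across patients, giving
the threshold scan contrast to detect; they are tunable and not claimed to
describe any particular clinic's plans. Toxicity is drawn from
y ~ Bernoulli(σ(−2.5 + 4.3·V)) at the predictor dose, then split into grades
with fixed conditional mixtures (negatives → grades 0:1 = 118:43, positives →
grades 2:3:4 = 9:4:1, the development cohort's proportions). Optional
covariates (age, PSA, Gleason group, prescribed dose) are generated
independently of outcome, so covariate screens have a true null.

Two consequences are worth stating plainly. First, with these DVH defaults
the event rate is ≈50%, far above the ≈8% grade ≥ 2 prevalence of a real
cohort: matching both the published coefficients and a realistic prevalence
is impossible, because prevalence is determined by the coefficients and the
V distribution jointly, and the V spread is what gives the scan its power.
The generator therefore prioritizes a recoverable signal; prevalence-matched
cohorts can be produced by passing a different truth model or DVH location.
Second, real DVHs carry plan-specific structure (shoulders, re-planning
composites, inter-structure correlation) the sigmoid family does not; passing
tests demonstrate the estimators recover known truths under the assumed
model, not that the model describes any clinic's data.

## Numerical and design choices

- Selection under the null: the scan performs ~80 correlated significance
  tests at p < 0.05, so with outcome labels permuted it still selects a dose
  in roughly a quarter of replicates. This is inherent to AIC-plus-p-cutoff
  scanning without multiplicity correction (which mirrors the analysis as
  specified); users should treat a selected threshold as descriptive, not
  confirmatory.
- Scan recovery scales as expected with cohort size: at n = 2000 the selected
  dose lands within ±2.5 Gy of the generating 51.43 Gy in 20/20 seeded
  replicates; at n = 400 single runs scatter by several Gy while the mean
  across seeds brackets the truth.
- Test and acceptance problem sizes (n = 2000–5000, 20–100 replicates,
  B ≤ 1000) were chosen to keep the full suite around a minute while leaving
  Monte-Carlo noise well inside the asserted tolerances.
- TD₅₀ anchor: the development analysis prints both 68.04 Gy and 68.08 Gy for
  the same quantity; this package uses 68.04 Gy wherever a fixed anchor is
  needed.
- Published risk-table thresholds (8 / 26.5 / 59%) are not exactly
  reproducible from the rounded coefficients (−2.5, 4.3): e.g.
  σ(−2.5 + 4.3·0.08) = 0.104, not < 0.10. Inversion of the rounded
  coefficients gives 7.0 / 25.9 / 58.1%, within 1.5 percentage points of the
  printed table; the package implements the algebraic inversion and documents
  the rounding gap rather than adjusting coefficients.
- Degenerate inputs: single-class outcomes, constant predictors, empty
  groups, non-monotone DVHs, and out-of-range grades raise typed errors
  naming the offending patient where applicable; separation and optimizer
  non-convergence are flagged on the result object instead.

## Known limitations

No fractionation correction (EQD2/BED) — physical dose only. One DVH per
patient (no plan summation). Univariate models only; no multivariable NTCP,
no LKB probit variant, no external validation, no confidence intervals for
TD₅₀. The synthetic generator does not correlate DVH shape with covariates.
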