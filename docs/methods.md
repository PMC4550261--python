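# Methods

This note documents the models, the synthetic-study generator, the
numerical choices, and the limitations of `pregsignal`.

## Reproductive timeline from fecal steroids

Fecal PdG (µg/g dry feces) lags circulating progesterone by 2–3 days.  The
luteal onset is the earliest sample with
`PdG_i >= mean_b + k * sd_b` **and** `PdG_i > mean_b`, where the baseline
statistics are taken over the 3–4 immediately preceding samples (sample
SD, n−1 denominator) and `k = 2` by default.  Two conventions are fixed
here and surfaced as parameters:

* **Baseline width** — 4 preceding samples when available, else 3,
  favoring the more stable baseline estimate.
* **Strict-mean condition** — the classical `mean + 2·SD` threshold
  degenerates on a constant baseline (SD = 0 qualifies every sample); the
  additional strict inequality against the mean makes a flat series yield
  no rise.

Windows are in calendar days, not sample indices: peri-ovulatory days are
{rise−3, rise−2} (the excretion lag is absorbed into these offsets) and the
fertile phase is the 5 days rise−6 … rise−2 (sperm survival plus the
peri-ovulatory days).  Conception is the **last** fertile day.  When a
delivery date exists, it is back-dated by the 176.3-day mean gestation
(rounded to 176 when a calendar date is required; the fractional constant
is kept for reporting), and among candidate fertile windows the one whose
last day is nearest the back-dated estimate is chosen, with the residual
discrepancy reported.  Which fertile day to pick under conflict is a
genuinely open convention; nearest-window is this package's choice and is
flagged in the output.

Candidate rises without sustained elevation (fewer than 2 of the next 3
samples above the candidate's threshold) are treated as non-conceptive
cycles; their days fall into the `other` label and out of the three-period
contrast.  Pregnancy months are fixed 30-day blocks anchored at conception
(month boundaries are not defined more precisely in field practice), and
PCP is the 30 days before conception.

**Detection-error bound.**  The 2-SD rule is scale-free in the baseline
noise: for an i.i.d. Gaussian baseline the per-sample false-fire
probability is the tail of a t₃-like statistic, ≈ 0.09.  A noise sample
immediately before the true rise therefore occasionally pulls detection
one sample early, and detection can be one sample late under a coarse
cadence.  On gap-free series the conception-dating error is bounded by the
sampling cadence, with ≥ 90% of females inside ±2 days at a 3-day cadence;
dropouts stretch the effective cadence and the bound with it.

## Facial colorimetry

A session's chart (≥ 4 patches of known reflectance, imaged under the same
exposure as the face) defines an affine map from camera RGB to modeled
(LW, MW) receptor captures, fitted by ordinary least squares against the
captures expected from reflectance × illuminant × sensitivity band
weights; the fit's residual RMS is returned for QC, and a grey-only
(rank-deficient) patch set is rejected.  The map is affine because the
exact functional form of the upstream camera characterization is not
standardized; an affine map is exactly recoverable when the true response
is linear, and scale-consistent (scaling all patch RGB by c rescales the
map by 1/c, leaving captures unchanged).

Outcomes per photo: R/G opponency `(LW−MW)/(LW+MW)` ∈ (−1, 1) and
luminance `(LW+MW)/2`.  Luminance is log-transformed for modeling (it is
well approximated as lognormal); the R/G ratio can be negative, so a
blanket log transform is ill-defined for it and it is modeled on its
natural scale.  The shorthand "MW+LW/2" sometimes seen for the achromatic
channel is implemented as the mean capture (MW+LW)/2.

The shipped receptor model (`SYNTHETIC_RECEPTOR_MODEL`) and chart
(`synthetic_colorchecker`) are synthetic test fixtures: they encode no
real macaque spectral sensitivities and no real chart's reflectances.
Real analyses must supply measured sensitivity/illuminant weights and
chart data.  Pixel linearization (RAW development) is assumed done
upstream; face-region masks are user input.

## Dominance

Chance-corrected dyadic indices (default) shrink sparse dyads toward 0.5;
unobserved dyads sit exactly at 0.5.  The raw-proportion variant is kept
behind `corrected=False` since the literature uses both.  NDS ties are
broken by total wins, then id, for deterministic ordinal ranks.  Because
small study groups often order rank by age almost perfectly, the pipeline
reports the rank–age Pearson correlation as a collinearity diagnostic and
keeps age (not rank) in the models when |r| is near 1.

## Mixed models and inference

All models share fixed effects (intercept, status with 3 levels, age) and
crossed Gaussian random intercepts for female identity and observation
date.  Fitting is maximum likelihood via the Laplace approximation: an
outer L-BFGS-B optimization over (β, family parameters, log σ_g) with an
inner Newton solve (step-halving, warm-started) for the random-effect
modes.  For the Gaussian family the marginal likelihood is Gaussian and
the Laplace approximation is exact, so LMEs are true ML; the statsmodels
`MixedLM` ML fit serves as an independent cross-check in the test suite,
as does `Logit` for the no-random-effect binomial limit and direct pmf
summation for the zero-truncated negative-binomial likelihood.

Numerical choices: random-effect SDs are optimized on the log scale with
a floor of 1e-4 — boundary fits (expected with only 5 females) are flagged,
never errored; fixed effects are bounded at ±15 so quasi-separated factor
levels (a period with no occurrences) end at the bound and are flagged;
inner Newton tolerance 1e-9, outer ftol 1e-11, maximum 500 iterations;
standard errors come from the numerical Hessian of the Laplace
log-likelihood.

Hurdle models decompose exactly: total log-likelihood = binomial
occurrence part + zero-truncated NB part on the positives.  A count part
with < 5 positive observations is refused with a message.  LRTs compare
full vs null (status removed, age retained); `delta_df` is the true
parameter-count difference — 2 for a 3-level factor in a single part — and
a combined-hurdle mode sums both parts' likelihoods (Δdf = 4) because
published hurdle LRTs are sometimes accounted that way.  The LRT statistic
is invariant to re-leveling the status factor; re-leveling with month1 as
baseline exposes the month2-vs-month1 contrast.  A zero-inflated binomial
variant of each occurrence model is compared by AIC; note that with
Bernoulli data a constant inflation probability is only identifiable when
covariates move the occurrence probability.  No multiple-testing
correction is applied (one status test per outcome), and this is noted in
the report output.

Collinearity screening computes phi on occurrence flags and Pearson r on
counts for every behavior pair; when a pair exceeds |0.7| the more
prevalent member is dropped — the broader category (body contact) is
treated as an aggregate of the more specific one (grooming), which stays.

## Synthetic-study generator

The generator emits the full study a field season would produce, with the
default design fixed at: 5 females aged (8, 9, 11, 13, 17) years — mean
11.6, range 8–17 as in the emulated study design; conceptions spread over
a two-week window so that PCP and both pregnancy months fit inside the
December–March season; 153 focals allocated 46/57/50 across periods; 88
photos allocated 28/35/25; hormone sampling every 3 days with 10%
weather dropouts; deliveries at conception + N(176.3, 3) days, rounded.

**Behavior calibration.**  For each behavior × period with target event
total T over n focals (rate r = T/n), occurrence probability is
`p = min(0.25, r/2)` and the zero-truncated positive-count mean is `r/p`
(≥ 2), so expected totals equal T while every behavior keeps ≥ 75% zero
focals in expectation — above the ≥ 70% floor that motivates the hurdle
structure.  Occurrence is Bernoulli on the logit scale and positive counts
are zero-truncated NB2 (dispersion k = 1.5) on the log-mean scale, each
with Gaussian female and date random intercepts (SDs 0.3 / 0.3 logit and
0.2 / 0.2 log) — Gaussian being the standard mixed-model convention.  The
planted logit/log-mean offsets are solved by Gauss–Hermite quadrature so
the *marginal* rates (after integrating the random effects) hit their
targets; without this the Jensen shift inflates expected totals by ~8%.
Calibration is in expectation — realized totals are stochastic, with a
per-replicate SD of roughly a third of the total for burst-prone
behaviors.

Grooming and body contact are social behaviors without published totals in
the emulated design; their occurrence rates (female-directed grooming
0.25/0.12/0.12 across periods, male-directed 0.15/0.10/0.12) mirror the
reported direction of a post-conception decline in female-directed
grooming.  Contact is generated as a superset of female grooming plus an
independent 0.10 extra-occurrence probability, which analytically yields a
pooled grooming–contact phi ≈ 0.77 — the strong collinearity the screening
stage must catch.  Grooming durations are sums of Gamma-distributed bout
lengths, generated for completeness but not modeled.

Hormones: baseline PdG ~ N(1.0, 0.1) µg/g; elevated PdG 5.0 (month 1) then
3.5 (month 2) µg/g with 10% lognormal noise, so PdG declines across
pregnancy; E1C flat at 10 ng/g (with a 1.3× follicular bump across the
fertile window), so the E1C/PdG ratio rises in month 2.  The planted rise
is at conception + 2 days, making the classifier's conception estimate
(rise − 2) recover the plant.  A configured rise below baseline-mean +
2·SD sets a `rise_below_detectability` flag.  Color: per-photo LW/MW are
lognormal (log-SD 0.08) around period means parameterized by luminance
(1.00/0.90/0.88) and R/G (0.10/0.11/0.07) — faces darken from PCP to
month 1, and redden less from month 1 to month 2.  Agonistic interactions
follow a linear age-ordered hierarchy with win probability
`expit(steepness × rank difference)`, steepness 5, 200 interactions.

**What the generator does not emulate**: assay error structure (CVs,
sensitivity ranges), autocorrelated hormone baselines, within-day behavior
clustering beyond the date random effect, acoustic call structure, pixel
images (receptor captures are generated directly; chart-level RGB
fixtures exercise the calibration code), parity/reproductive history, and
non-conceptive cycling females.  Passing recovery tests therefore show the
pipeline is correct under the assumed data-generating process, not that
the field assumptions themselves hold.

## Problem sizes used in validation

The simulation-based checks run at the scale of the emulated study design:
parameter recovery and LRT type-I error use 5 females × 150 focals on 30
shared dates (200 and 500 replicates respectively); generator calibration
checks average 100–200 replicate studies; oracle-equivalence checks use
1,000 random hormone series and random 6×6 win matrices.  These sizes are
the package's validation design and match the data volumes the pipeline is
intended for.

## Known limitations

* With 5 females, random-effect variances frequently hit the boundary;
  estimates are reported with flags rather than errors, and fixed-effect
  SEs can be optimistic in that regime.
* The Laplace approximation for Bernoulli data with few clusters carries a
  mild bias in the variance components (and, slightly, in extreme
  coefficients); the type-I error of the status LRT remains within
  [0.03, 0.08] at α = 0.05 in the validation design.
* The truncated-count model refuses very sparse behaviors rather than
  fitting them; period-specific zero cells (e.g. a behavior absent in one
  pregnancy month) produce bounded, flagged coefficients.
* Conception dating error is bounded by the hormone sampling cadence (see
  above), not by ±2 days unconditionally.
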