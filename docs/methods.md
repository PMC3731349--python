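# Methods

## The measurement problem

Contrast-enhanced ultrasound (CEUS) tracks an intravenous bolus of
gas-filled microbubbles through tissue. Averaging echo intensity over a
region of interest (ROI) frame by frame yields a time–intensity curve
(TIC): a pre-arrival baseline, a steep wash-in, a peak, and an
exponential-tailed wash-out. In renal imaging the ROI is a 5 mm × 5 mm
square on the peripheral cortex, and changes in the TIC's shape over
weeks track the progression of chronic ischemic renal disease well
before blood chemistry moves. This package implements that pipeline:
ROI extraction, kinetic fitting, index derivation, and the longitudinal
test for the earliest week at which each index changes.

## Kinetic model

The bolus passage is modelled by the lagged gamma-variate

    I(t) = A (t − t0) exp(−α (t − t0)) + C,   t ≥ t0;   I(t) = C otherwise,

with `A` the wash-in upslope scale (intensity/s), `α` the rate constant
(1/s, the reciprocal of curve width), `t0` the bolus arrival lag (s) and
`C` the baseline intensity asymptote. The five perfusion indices follow
in closed form, all baseline-subtracted:

| index | formula | meaning |
|---|---|---|
| A | — | wash-in slope scale |
| α | — | wash-out rate constant |
| AUC | A/α² | area under the curve; blood-volume proxy |
| DPI | A/(α·e) | derived peak intensity (curve amplitude) |
| TTP | 1/α | time from arrival to peak |

Two modelling notes. First, the lag `t0` is not part of the textbook
gamma-variate but is required for bolus data, where the contrast reaches
the kidney seconds after injection; it is estimated (bounded by the
observed peak time) unless fixed by the caller. Second, DPI is
implemented as A/(α·e) because that is the curve maximum above baseline
of the model; source material sometimes typesets the amplitude with an
ambiguous exponent sign ("A/α·exp¹"), which we read as the same
quantity.

## Fitting

`fit_gamma_variate` minimizes the sum of squared residuals with a
bounded trust-region-reflective least-squares solver (A ≥ 0, α > 0,
t0 ∈ [0, observed peak time], C free; ftol 1e-8, up to 500 iterations
per parameter). Initialization: baseline mean over the pre-peak prefix,
crude arrival from a 3σ threshold, then the standard log-linearization
ln((I−C)/(t−t0)) = ln A − α(t−t0), whose OLS slope and intercept give
(α₀, A₀); if the slope is non-negative (no decay) a peak heuristic
(α₀ = 1/TTP_obs, A₀ = peak·α₀·e) takes over. The observed peak is the
first argmax after 3-sample moving-average smoothing; a peak at either
end of the series raises a truncated-bolus error rather than returning a
meaningless fit. The log-linearization excludes samples whose
enhancement I−C is below 1e-7 of the peak enhancement: beyond that the
difference drowns in the floating-point granularity of C and corrupts
the regression.

Fitting operates on the TIC in its recorded units — dB video intensity
by default, since commercial TIC tools report DPI in dB — with an
optional pre-linearization to power (10^(I/10)) available but off by
default.

## Synthetic data

The generator exists so every stage is testable without any acquisition
hardware. It emulates:

- **TICs**: the model curve sampled on a 160 s / 10 Hz grid (the
  acquisition envelope of the emulated protocol), with speckle-like
  noise as i.i.d. mean-1 gamma factors (sd = cv) multiplying the linear
  power, re-compressed to dB when the acquisition is log-compressed.
  This preserves the linear-scale mean exactly and keeps power positive.
- **Cine loops**: disjoint pixel regions (cortex band, delayed medulla)
  each following their own kinetics plus per-pixel noise — enough to
  exercise ROI geometry, extraction linearity and arrival ordering, not
  a physical ultrasound simulation (no attenuation, no motion, no
  point-spread function).
- **Cohorts**: 5 subjects, weeks 0–16, staggered dropout after weeks
  (6, 6, 12, 13, 16). Kinetic truth per subject-week is
  baseline × subject effect × drift^week × replicate noise, log-normal
  effects throughout (positivity). Healthy baseline kinetics are
  inverted from pre-operative index means (TTP 9.03 s, DPI 13.04 dB →
  α ≈ 0.1107/s, A ≈ 3.93), and the default ischemia scenario drifts A by
  0.97/week and α by 0.93/week.

Parameter choices that were genuinely open, fixed once:

- Between-subject and replicate log-SDs (0.15 and 0.05): the emulated
  study reports only cross-sectional SDs of means, so these are
  order-of-magnitude choices for a homogeneous lab-animal cohort.
- Replicate noise on (A, α) is correlated, ρ = 0.9: all five indices of
  a subject-week derive from fitting the *same* noisy TIC, and
  Monte-Carlo fits of the generator's own TICs measure
  corr(log Â, log α̂) ≈ 0.87–0.89. Independent noise would overstate the
  variance of ratio indices such as DPI = A/(α·e).
- The drift directions reproduce the documented index trends (AUC, DPI,
  TTP rising; A falling) with α *falling*. A rising α would contradict a
  rising TTP through the identity TTP = 1/α; the generator accepts
  arbitrary drifts so the opposite reading can be simulated.

The weekly factors implied by drifts (d_A, d_α) are d_A/d_α² for AUC,
d_A/d_α for DPI and 1/d_α for TTP, so all four trend directions hold
exactly when d_α < d_A < 1. (Note d_A > d_α² alone is *not* sufficient:
it leaves DPI free to fall.)

## Longitudinal statistics

Each index is analysed on the irregular subject × week panel with a
random-intercept model, y_iw = μ + Σ β_w·[week = w] + b_i + ε_iw,
estimated by feasible GLS: (1) OLS for the fixed effects; (2)
method-of-moments variance components — total residual variance from
the OLS residual mean square, between-subject variance from the mean
cross-product of distinct within-subject residual pairs (clipped to
[0, total]); (3) GLS re-estimation under V_i = σ²I + σ_b²J (Woodbury
inverse per subject). Each β_w gets a Wald z test against the baseline
(smallest) week; the earliest week with p < 0.05 is the index's
detection week. Weeks observed in fewer than 2 subjects are dropped
with a warning; no multiplicity correction is applied across weeks
(raw per-week P values are the convention for this design), while
Bonferroni-adjusted pairwise t tests are provided separately for
stage-labelled scalar series such as blood chemistry.

Choices and caveats:

- Wald z inference is asymptotic. On 1,000 simulated null panels of 20
  subjects × 8 weeks the empirical size is ≈ 0.045–0.048 at nominal
  0.05; at 5 subjects the test is anti-conservative and detection weeks
  from such small cohorts should be read as orderings, not calibrated
  claims. This mirrors the scale of the study design the package
  emulates.
- MoM + GLS agrees with a REML linear mixed model (statsmodels MixedLM,
  used as an independent cross-check in the tests) to well under a
  tenth of a standard error on the fixed effects; SEs differ by ~15%
  because the variance-component estimators differ.
- Zero-variance panels are reported with exact-zero effects and p = 1
  (scale-aware tolerance 1e-12 of the data magnitude) instead of 0/0
  noise.
- Dropout is treated as non-informative; no survival modelling.

## Numerical and degenerate-input policy

- Fit never returns a worse sse than its initialization; non-convergence
  returns `converged=False` with best-so-far parameters rather than
  raising.
- Constant or boundary-peaked TICs → truncated-bolus error; flat TICs →
  no-bolus-detected; zero-variance TICs → r² undefined (rmse only).
- ROI pixel extents are round(size_mm/spacing) floored at 1, centred
  with even extents biased to the top-left; out-of-bounds ROIs are
  errors, never clipped silently.
- All stochastic paths take explicit integer seeds; identical seeds give
  bit-identical TICs, cines, cohorts, and pipeline reports (JSON is
  written with sorted keys and no timestamps).

## What the tests do and do not show

The synthetic generator matches the analysis assumptions by
construction, so passing tests demonstrate the *estimation machinery* —
recovery of known kinetics under speckle-like noise, calibration of the
panel test, reproduction of the expected index trend directions and
detection ordering (TTP/DPI at or before A). They do not validate the
gamma-variate as a physiological model, the noise model against real
speckle statistics, motion/attenuation robustness, or behaviour under
informative dropout. Problem sizes used by the test suite and the
acceptance script (200 fit replicates, 1,000 null panels, 200 simulated
cohorts, 50³ grid oracle) were chosen to make Monte-Carlo error small
relative to the asserted margins.
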