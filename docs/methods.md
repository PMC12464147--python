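# Methods

## The measurand and the model

A fingertip photoplethysmogram shows, for every heartbeat, a systolic
peak followed by a smaller reflected peak.  The peak-to-peak delay
(pulse propagation time, PPT) approximates the transit time of the
pressure wave to the peripheral reflection sites and back, a path whose
length scales with body height.  Averaging PPT beat by beat over the
valid part of a night gives the overnight PPT (OPPT); dividing height
(m) by OPPT (s) gives the overnight stiffness index OSI in m/s, which is
directly comparable to pulse-wave-velocity-style thresholds (the default
low/high split of 10.9 m/s sits near the conventional 10 m/s
hypertension-mediated-organ-damage boundary for carotid–femoral PWV).

The package treats OSI analysis as five cooperating parts: a synthetic
study generator, the waveform extractor, the ABPM index calculator, the
risk-score layer, and the statistical comparison machinery, orchestrated
by a pipeline that emits per-subject and study-level tables.

## Synthetic study generator

Because patient data of this kind are not publicly shareable, the
generator is first-class, tested code rather than a fixture.  One latent
vascular-stiffness factor `z` per subject (standard normal, correlated
0.5 with age) drives both measurement arms:

* **PPG arm.** Reflected-wave speed `v = 10.9 + 0.30 z` m/s; true mean
  PPT = height / v.  Each beat is synthesised as two Gaussian bumps
  (systolic σ = 30 ms; reflected σ = 40 ms, 35–65 % amplitude, delayed
  by the per-beat true PPT), with beat-interval variability, slow
  baseline wander, white noise, and contiguous high-amplitude noise
  bursts covering a configurable fraction of the night (motion-like
  artifacts; optionally masked, emulating a device that discards
  artifact periods).  Narrow bump widths were chosen so that a distinct
  second peak exists across the whole physiological 120–280 ms delay
  range; with broader bumps the two components genuinely merge and the
  composite peaks shift by several ms, which is a property of the
  waveform, not of the extractor.
* **ABPM arm.** Awake systolic pressure `141 + 10 z` mmHg; systolic
  dipping `14 − 4.4 z` %; 24-h pulse pressure `53 + 3 z` mmHg riding
  partly (0.4×) on systolic level; AASI `0.42 + 0.10 z`.  Each subject
  owns one diastolic-on-systolic line with slope `1 − AASI`; readings
  every 20 min are the true period mean plus within-period noise for
  SBP, and the line value plus residual noise for DBP.  Diastolic period
  means and diastolic dipping are therefore *implied* by the line — the
  generator does not configure them independently, which keeps the AASI
  estimator exactly unbiased and the noise-free recovery chain exact.

Marginals (age 58.1 ± 10.8 y, 71 % male, height by sex averaging
175 cm, BMI 28 ± 4, lipids, creatinine, AHI classes roughly
28/38/30/4 %) emulate a middle-aged, mostly male hypertensive clinic
population.  Effect sizes are deliberately at the generous end of what
such studies report, and the stature share of PPT variance is
exaggerated relative to real cohorts (the generator's PPT–height
correlation is ≈ 0.9): both choices were calibrated once so that the
qualitative "OSI beats OPPT uniformly" correlation pattern is
reproducible in ≥ 90 % of 79-subject replicates, which a real-data
effect profile cannot deliver at that sample size.  Passing tests on
these cohorts therefore demonstrate estimator correctness and the
direction of the structure, not real-world effect magnitudes.

What the generator does **not** emulate: PPG optics and perfusion
physiology, sleep architecture and staging, cardiorespiratory coupling,
reading-level ABPM artifacts beyond white noise, missingness patterns.

## Waveform extraction

Feet are found by zero-phase band-pass filtering (0.5–8 Hz), taking
systolic peaks at ≥ 0.4 s spacing (peak priority suppresses reflected
peaks), and anchoring each foot at the pre-peak upstroke minimum.  Beat
windows are half-open foot-to-foot ranges of 0.4–1.5 s that avoid masked
samples.  Within a beat (zero-phase low-passed at 12 Hz; 8 Hz visibly
biases a 120 ms delay by > 2 ms through bump broadening), p1 is the
global maximum and p2 is searched in (p1 + 80 ms, end − 80 ms]: the most
prominent local maximum above 1 % relative prominence, ties broken to
the earlier candidate (the reflected wave is the physiologically earlier
event); failing that, the largest interior local maximum of the first
derivative where the pulse still holds ≥ 25 % of its systolic rise (the
decay-limb shoulder), else the beat is rejected.  Both landmarks get
three-point parabolic sub-sample refinement — at 100 Hz the raw 10 ms
grid is coarse relative to the differences of interest; refined recovery
error on noise-free constant-delay nights is ≤ 0.3 ms.

Quality control is idempotent: static rules (PPT within 100–400 ms, beat
length 0.4–1.5 s, foot-to-systolic upstroke 80–350 ms) define a
reference population, against which rolling 5-minute *robust* statistics
(median and IQR with a 5 % relative scale floor) reject amplitude
outliers (> 3 robust z) and PPT excursions (> 80 ms from the rolling
median).  Robust statistics matter: a mean/SD rolling window lets an
artifact burst inflate its own yardstick and mask itself.  OPPT is the
plain mean over valid beats (a median option exists); a night reports
only if valid beats cover > 3 h, otherwise `InsufficientValidSignal`.

## ABPM indices

Readings are edited with a simple plausibility filter (SBP 60–260, DBP
40–150, PP 15–120 mmHg, DBP < SBP; ≥ 14 valid readings per 24 h), a
deliberate simplification of published ABPM editing procedures whose
full rules live outside this package's scope; thresholds are
configurable.  The asleep period is the half-open diary interval
[bedtime, waketime).  Pulse pressure is the difference of period means;
dipping is (awake − asleep)/awake × 100 on period means (not a mean of
hourly dips); AASI is 1 − OLS slope of DBP on SBP over all valid 24-h
readings, computed on at least 10 readings with non-zero SBP variance
and never clipped (negative values are legitimate).

## Risk scores

Friedewald LDL (TC − HDL − TG/2.2, invalid above 4.5 mmol/l TG), the
2021 race-free CKD-EPI eGFR, SCORE2 for ages 40–69 and SCORE2-OP for
70–89 with moderate-risk-region recalibration, and the Framingham
general-CVD Cox function (lipid-based; cholesterol converted at
38.67 mg/dl per mmol/l).  Coefficients, baseline survivals and
calibration scales are versioned JSON data files citing their source
publications, verified in tests against published chart cells and the
published Framingham worked example (10.48 %).  Eligibility mirrors
study practice: diabetes, age outside 40–89, missing lipids, or SBP
outside 100–179 mmHg yield a typed `NotApplicable` with a reason.  For
plots and tertile displays, Framingham values above 30 % are capped at
31 %.  Scores use *current* smoking; the cohort carries both a smoking
history flag and a current-smoking flag because the two are routinely
conflated in clinical tables.

## Statistics

Group tables auto-select tests: Welch's t for two groups unless a
Shapiro–Wilk check (α = 0.05) on pooled within-group residuals rejects
normality (then Wilcoxon rank-sum), Kruskal–Wallis beyond two groups,
chi-squared for categorical variables unless a 2×2 expected cell falls
below 5 (then Fisher's exact); Bonferroni Q is computed over one family
per emitted table.  Correlations are Pearson for BP-derived metrics and
Spearman for risk scores.  Dependent correlations sharing the OSI/OPPT
measurement are compared with Williams' statistic in its determinant
form,

t = (r12 − r13) √[ (n−1)(1+r23) / ( 2·((n−1)/(n−3))·|R| + r̄²(1−r23)³ ) ],

|R| the 3×3 correlation-matrix determinant, r̄ = (r12+r13)/2, referred
to t with n−3 df; OPPT is sign-flipped first so both predictors share
the "higher = stiffer" orientation.  Monte-Carlo calibration at n = 79
keeps the empirical type-I error within [4 %, 6 %] at α = 0.05.
Adjusted models are OLS of each outcome on OSI plus the fixed confounder
set {age, sex, BMI, diabetes, smoking history}, with per-term VIFs,
residual diagnostics, Hommel adjustment of the exposure p-values across
the model family (delegated to statsmodels and cross-checked against a
brute-force closed-testing oracle in the tests), and a sensitivity refit
after removing observations with Cook's distance > 4/n or |externally
studentized residual| > 3 — a conventional concretisation of "potential
outliers and influential observations"; a binary confounder whose
carriers are all trimmed is dropped from the refit rather than failing.

## Pipeline conventions

The OSI split uses the analysed cohort's median by default (a fixed
threshold is selectable for cross-cohort work and the rule used is
recorded in the manifest).  Subjects failing the 3-h validity floor or a
score eligibility rule stay in the derived table with explicit
not-applicable markers.  The replicated structure check evaluates the
OSI-versus-OPPT pattern only over outcomes where both correlations are
significant (p < 0.05), matching the convention of testing correlation
differences only for significant correlations; it runs at truth level
(simulator beat-level PPT rather than re-extracted waveforms), since
waveform-level fidelity is established separately and the pattern lives
in the cohort structure.  Full-waveform runs default to 7-h nights at
100 Hz (~2 M beats per 79-subject study, a few minutes of CPU); tests
use shorter nights and smaller cohorts.

## Numerical and degenerate-input choices

Zero-phase (forward–backward) filtering everywhere avoids phase bias in
PPT.  Parabolic refinement clamps its offset to ±0.5 sample.  Flat or
garbage signals yield empty beat lists with a warning, not exceptions;
empty periods, missing diaries, unusable records, degenerate regressions
and rank-deficient designs raise typed errors naming the problem.
Correlation comparisons require |r| < 1, n ≥ 4 and a positive
semi-definite correlation triple.  All randomness flows from explicit
integer seeds through per-subject, per-stream `SeedSequence` spawns, so
cohorts, waveforms and readings are bit-reproducible and independent of
evaluation order.

## Known limitations

Two-Gaussian beats are a caricature of real pulse morphology (no
dicrotic notch dynamics, no respiratory amplitude modulation); the
device-internal algorithms the extractor stands in for are proprietary
and unpublished, so agreement with any specific device cannot be
claimed.  The ABPM editing filter is intentionally simpler than
published editing procedures.  Risk-score outputs are calibrated for
their published populations, not validated against outcomes here.  The
generator's effect sizes and stature share are tuned for structural
reproducibility, not population realism (see above), and synthetic
diastolic dipping is a consequence of the AASI line rather than an
independent dial.
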