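# Methods

This package re-implements, as tested code, a study of orientation
adaptation under naturalistic film viewing: engineering film frames so that
low-spatial-frequency contrast energy carries exactly one orientation,
scheduling a counterbalanced tilt-judgement experiment around those
adaptors, and estimating adaptation-induced response biases with a
multilevel probit model plus a sequential permutation analysis.  Because no
behavioural data ship with the repository, a synthetic observer with known
ground truth generates the responses every downstream stage is validated
against.

## Stimulus engineering (`tiltfilm.frames`)

An adaptor frame is produced by the chain *whiten → 1/f → orientation ×
spatial-frequency band-pass → inverse transform → energy match → circular
crop*, all in the 2-D Fourier domain with the phase spectrum untouched
(preserving scene structure).

* **Whitening** sets every non-DC amplitude to one constant.  The constant
  is chosen to preserve total contrast energy; any constant would satisfy
  the definition, and the final energy-matching step makes the choice
  immaterial in the full pipeline.
* **1/f** scales each non-DC amplitude by the reciprocal of radial
  frequency in cycles per degree (cpd), computed from the pixels-per-degree
  (ppd) metadata.  The DC coefficient carries mean luminance and is
  excluded from whitening, 1/f, filtering and energy bookkeeping: "total
  energy" always means contrast energy (sum of squared deviations from the
  mean), the only reading under which energy matching is well defined at
  f = 0.
* **Spatial-frequency filter**: flat top over [1, 4] cpd with raised-cosine
  edges falling to zero over half an octave.  The ramp is a raised cosine
  in log2 frequency because an octave is a log unit; a linear-frequency
  ramp would make "half an octave" side-dependent.
* **Orientation filter**: raised cosine `0.5 (1 + cos(pi d / w))` in the
  angular distance `d` from the adaptor, zero beyond `w = 45°`.  Its full
  width at half height is therefore 45°, matching the test grating's stated
  45° orientation bandwidth, which is why the "periodicity of 45°" wording
  is read as FWHH = 45° rather than a full period of 45° (zero at ±22.5°);
  the alternative reading remains available by setting `ori_halfwidth`.
* **Angle convention**: orientation is measured from vertical, positive
  clockwise, 180°-periodic.  A frequency bin's orientation is the
  orientation of the grating it represents (`atan2(fy, fx)` with y down),
  fixed in one helper (`frequency_grid`) and pinned by a test using a
  synthetic vertical grating.  The test-grating definition is built on the
  conventional polar-Fourier mapping (radial = spatial frequency,
  angular = orientation).
* **Energy match**: after filtering, the contrast image is rescaled so its
  energy equals that of the *original unfiltered* frame, then mean
  luminance is restored.  A zero-variance frame, or a filter that removes
  all energy, raises an error.
* **Circular crop** fills everything outside a centred 14.30° disc with
  mean luminance (mid-grey), removing the cardinal cues of a rectangular
  frame edge.
* **ppd default 75.5**: viewing distance is not part of the published
  geometry; 75.5 px/deg makes the 14.30° stimulus fill a 1080-px display
  height, reproducing the stated display/stimulus relationship without
  assuming a distance.
* Whitening and 1/f are applied per frame; a shared normalising constant
  across a whole film is a trivial variant that only changes frame-to-frame
  luminance dynamics, which the energy match re-imposes anyway.

The test grating is defined directly in the frequency plane as a separable
raised-cosine bump (centre 2 cpd; FWHH 1.148 cpd and 45°), given a uniform
spatial phase at the image centre, and scaled to the requested RMS contrast
(std/mean, default 1.0).  At 100% RMS contrast the luminance excursion is
not clipped; the object is a linear luminance grid, and display-specific
clipping/gamma is out of scope.

## Experimental design (`tiltfilm.design`)

Each participant completes a baseline session and two adaptation sessions
(one cardinal adaptor 0°/90°, one oblique 45°/135°; pair and order
counterbalanced over the 8 cells).  The two standard orientations, shared
by all of a participant's sessions, are the unique pair from
{−67.5°, −22.5°, 22.5°, 67.5°} in which *each* standard is equidistant from
both adaptors — per adaptor one standard sits 22.5° away and the other
67.5°.  (The weaker condition "one at 22.5, one at 67.5 per adaptor" is
satisfied by two pairs; individual equidistance is what makes the published
worked example unique.)

Experimental sessions hold 600 trials: per standard, 20 trials at ±10°
offsets, 40 at ±5°, 60 at −2.5°/0°/+2.5° (300 per standard).  Adaptation
sessions split the 600 trials into 120 blocks of five, each preceded by a
22.40-s film clip (44.80 min viewing/session; 240 clips and 89.6 min across
both sessions).  The per-offset allocation within adaptation sessions is
not separately published; the baseline 20/40/60 scheme is reused because it
reproduces the published totals and the same emphasis on small offsets (a
`DesignSpec` field makes it configurable).  Practice: session 1 has 84
doubled-offset plus 504 standard-offset feedback trials; sessions 2–3 have
14 feedback plus 196 no-feedback trials (14 per standard × offset cell),
the latter folded into the baseline dataset.  Offsets/standards are
assigned by a seeded constrained shuffle of the exact cell counts, so
left/right offsets balance within every session × standard stratum and an
unbiased observer's expected ±1-coded mean response is 0.  The baseline
condition is coded `adaptor_deg = −999` in memory and on disk.

## Synthetic observer (`tiltfilm.observer`)

Responses are Bernoulli draws from

    P(right) = (1 − lapse) · Φ(slope · (T + b)) + lapse/2

with `T` the test offset (deg) and `b` the total bias in degrees:
baseline anisotropy per standard + tilt-aftereffect term (adaptation
sessions only) + optional injected per-cell bias + a participant-level
N(0, sd²) offset.  The probit core mirrors the analysis model, making
parameter recovery exact in expectation.

The aftereffect profile is the classic odd shape — repulsion within ~50° of
the adaptor, attraction beyond, zero at 0° and 90°.  It is implemented as
the two-harmonic odd series `a [sin 2d + c sin 4d]` with `c` chosen so the
zero crossing sits exactly at the configurable crossover (default 50°) and
`a` normalising the peak to `tae_amplitude`.  The published source for this
study gives no quantitative effect size for its own stimuli (the observed
effects were far below classical ones), so the default amplitude is a
conventional tilt-aftereffect magnitude, 2°, with slope 0.3 probit/deg —
these are modelling conventions, not measured values.  Build-up follows
`b(t) = b_inf (1 − e^{−t/τ})` in within-session trial index, a simple
saturating stand-in for the logarithmic build-up reported for classical
adaptation; the form is pluggable and `τ = ∞` gives an instantaneous
aftereffect.

What the generator does *not* emulate: sequential dependencies beyond the
build-up term (no response hysteresis), lapse asymmetries, drift in slope,
eye movements, or any image-computable pathway from the actual filtered
frames to bias.  Passing recovery tests therefore show the analysis code is
correct and calibrated under its own assumptions, not that real film
viewing produces these biases.

## Multilevel probit bias model (`tiltfilm.glmm`)

The analysis model is `P(right) = Φ(η)` with

    η = β₀ + β₁T + β₂F + β₃S + β₄(F×S) + u_participant

where T (7 offset levels), F (4 adaptors + baseline level), S (4
standards) and F×S are all categorical (dummy coding; reference levels
configurable and the reported cell quantities are coding-invariant), and
the participant intercept is Gaussian.  Only a random intercept is fitted:
the source describes "participant as a random effect" without further
structure, and that is the minimal faithful reading.

Estimation is marginal maximum likelihood: the participant intercept is
integrated out with 21-node Gauss–Hermite quadrature, the analytic gradient
is supplied, and L-BFGS-B optimises [β, σ_u] (σ_u ≥ 1e−6; convergence
ftol 1e−12).  No Python package in the supported stack fits a frequentist
probit GLMM, so the likelihood is implemented here; the test suite
cross-checks it against R `lme4::glmer` (probit, adaptive quadrature) on a
simulated cohort — log-likelihood, σ_u and all 20 cell intercepts agree —
and against `statsmodels` ordinary probit in the single-participant limit,
where σ_u is pinned at ~0.  Covariances come from the numerically
differentiated observed information.  Partially counterbalanced cohorts
leave some dummy columns empty or collinear; a pivoted-QR column basis is
fitted instead, which leaves predictions for observed cells unchanged.
Separation or divergence (|β| > 50) raises an explicit error.

A condition cell's **bias** is its conditional intercept: η at the 0°
offset reference with the random effect at zero.  Baseline subtraction
(adaptation cell minus the baseline cell at the same standard) isolates the
adaptation-attributable bias; its Wald p-value uses the contrast variance.
A degree-equivalent is reported as bias divided by the local probit slope
per degree, taken from the contrast of the ±2.5° offset levels since T is
categorical (flagged as derived).  Raw p-values are reported across the 16
cells, matching the source analysis; no multiplicity correction is applied.
A second, descriptive uncertainty (`prediction_se`) averages the model's
per-trial predicted responses within observer × cell and takes the SE of
those means across observers.

The **baseline quality check** compares, per participant, an intercept-only
and an intercept + slope binomial regression (logit link) of response on
offset: statistic 2Δloglik, referred to χ²(df = 1) — one added slope
parameter — and pass iff p < .05.  Its type-I rate is verified at ~5% on
simulated guessers.

## Sequential permutation analysis (`tiltfilm.sequential`)

Within each (session × adaptor-relative standard) stratum of 300 trials,
responses are coded +1 (right)/−1 (left) and accumulated as running means
forward from trial 1 and in reverse from trial 300; both traces share the
full-sample mean at their far end.  Traces are computed per participant and
averaged ("mean bias accumulation"); strata are keyed by the standard
re-coded relative to the adaptor so attraction/repulsion reads uniformly.

The null hypothesis — accumulation direction carries no information — is
simulated by randomising, independently per trial *and per participant*,
whether the forward or reverse trace value enters the across-participant
average; 1000 such permutations give per-trial 2.5%/97.5% quantiles, and
trials where a trace falls *strictly* outside (touching the band does not
flag, per the "falls outside" reading) are flagged.  Because forward and
reverse values at each index average to a common midpoint, this null is
exactly a sign-flip distribution on the per-participant half-differences,
and under a stationary observer its pointwise coverage is the nominal 95%
(verified by Monte-Carlo; the acceptance script reports it).  Randomising
the *aggregate* value pair instead yields a two-point null whose 95%
quantile band always spans both observed traces — nothing can ever be
flagged — so that variant, while available (`level="aggregate"`) for
comparison, cannot be what generated the published bands; the
per-participant construction is the default.

Folding to absolute standards negates the negative-standard traces and
pools them with the positive stratum before aggregation and band
construction; folding an already-folded result is rejected.  No correction
for the multiplicity of per-trial comparisons is applied (the source
analysis applies none); flags on adjacent trials are strongly dependent
because consecutive cumulative means share almost all their trials.

## Problem sizes and numerical choices

* Defaults reproduce the study scale: 24 participants, 600 experimental
  trials per session, 300 per stratum, 1000 permutations.
* The test suite exercises the statistical machinery on a 1/10-scale design
  (30 trials per standard per session, 8–24 participants) chosen so each
  multilevel fit completes in seconds; calibration checks use 60–120
  Monte-Carlo cohorts with binomial tolerance bounds.  The acceptance
  script's coverage study uses 500 cohorts of 8 participants × 100 trials
  with 1000 permutations.
* Recovery tests average estimates over three replicate cohorts and test
  against the standard error of that mean; a single-draw 2-SE check would
  fail ~5% of the time per cell by construction.
* Seeds: every stochastic component (schedule shuffling, observer draws,
  permutations) takes an explicit seed; cohort streams are spawned from a
  `SeedSequence` keyed by a CRC of the participant id, so schedules and
  responses are bit-reproducible and independent of participant-list order.
* Degenerate inputs raise errors rather than warn: constant frames
  (undefined phase), zero-energy frames, apertures larger than the frame,
  gratings beyond Nyquist, missing responses in accumulation, single-observer
  prediction SEs, baseline cells absent for subtraction.

## Known limitations

* The multilevel model supports only a random intercept; random slopes
  would need a different quadrature scheme.
* The degree-equivalent bias uses a local two-point slope; with strongly
  non-probit data the conversion is only indicative.
* `quality_check` follows the source in using a logit-link psychometric
  check even though the bias model is probit; the LRT calibration is
  unaffected.
* The permutation null is discrete with 2^P atoms for P contributing
  traces; below ~6 participants the 2.5% quantile cannot resolve the tail
  and strict-exteriority flags become anti-conservative.  The study-scale
  strata (24–48 traces) are far from this regime.
* The stimulus chain operates on single frames; temporal properties of the
  film (clip assembly, audio, motion energy) are modelled only as counts
  and durations in the design module.
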