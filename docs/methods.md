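# Methods

## The measurement model

Each cell contributes three time series sampled every 12 min (dt = 0.2 h):
the raw CDK4/6 KTR cytoplasmic:nuclear ratio, the CDK2 KTR ratio, and the
APC/C<sup>Cdh1</sup>-degron nuclear intensity. The raw CDK4/6 reporter is
not CDK4/6-specific: both kinases phosphorylate it, so the observed signal
is modelled as

    raw CDK4/6 = true CDK4/6 activity + f · CDK2 activity + noise,

with a single global contamination fraction *f*. The corrected activity
subtracts the CDK2 term with a fixed *f* = 0.35 (`Thresholds.f_correction`).
All classification thresholds operate on the corrected signal.

### Estimating f

`estimate_correction_factor` exploits acute CDK4/6 inhibition: with the
CDK4/6-specific component nulled, the post-inhibition raw signal is an
affine function of simultaneous CDK2 activity with slope *f*. The
estimator pools (cell, frame) points from S/G2 cells — selected as cells
whose degron was already rising before the inhibitor, because their high
and still-ramping CDK2 activity spreads the regressor — within
[t_add + 2 frames, t_add + 4 h], and fits ordinary least squares with a
free intercept. Design choices:

- *Free intercept*: inhibitors leave a small reporter floor; forcing the
  line through the origin would bias the slope.
- *First 2 frames excluded*: reporter dephosphorylation after inhibition
  takes up to one frame; the first frames may be transitional.
- *Pooled fit* rather than per-cell fits averaged: a single global f is
  the model, and pooling weights cells by their usable frames.
- Noise on the regressor (CDK2 is itself measured) attenuates the OLS
  slope by var(noise)/var(CDK2); at measurement noise sd 0.02 and the
  S/G2 CDK2 spread used here the bias is ≈ 0.003, an order of magnitude
  below the reported precision. Replicate-mean recovery is verified to
  ±0.005 in the test suite.
- `flatness` reports the absolute residual time-trend of the corrected
  signal over the fitting window; it is the diagnostic that the
  correction removed the CDK2 ramp.

Negative corrected values are kept (not clipped) in all statistics;
clipping is cosmetic only.

## Event detection

Onsets are **threshold crossings with persistence**, not derivative-based
change points: the fate definitions downstream are threshold-based, and a
persistence horizon is the natural guard against noise excursions.

- CDK4/6-on: corrected activity > 0.7 sustained 2 h (the same horizon as
  the post-mitotic high/low classification window).
- CDK2-on: activity > 0.76 sustained 1 h (the CDK2 ramp is slow, so a
  shorter horizon suffices and reduces right-censoring near trace ends).
- Onset time is the first above-threshold frame — grid-aligned and
  reproducible; no sub-frame interpolation.
- Traces are median-filtered (window 3, nearest-edge padding, masked
  samples excluded) before detection. The window is a free parameter; a
  3-frame median removes single-frame segmentation glitches without
  lagging monotone ramps.
- Masked (missing) frames are never interpolated; they are simply skipped
  at every decision point.

APC/C-off (`detect_apc_off`) estimates a baseline band from an expanding
prefix of the degron series (≥ 10 samples) and reports the first time the
signal exceeds baseline + 3 sd **and** keeps rising for 1 h
(nondecreasing within a 2-sd allowance, excursion at least doubling)
**and** never relapses into the baseline band afterwards. The relapse
condition encodes the biology — degron accumulation is monotone once
APC/C is inactivated — and is what makes the detector robust on
zero-clipped baselines, whose sd is otherwise underestimated. Onsets that
cannot be confirmed (less than 1 h of follow-up) are not called.

For cycling cohorts all detection runs on the post-anaphase segment; the
pre-anaphase mother-cell signal is not part of any figure-level analysis.

## Fate classification

- *Quiescence release*: `high` iff an onset was detected and the
  corrected signal stays above 0.7 through the G1/S transition (or trace
  end). "Persistently increased" needs a horizon; trace end is the
  conservative choice.
- *Mitotic exit*: `high` iff above 0.7 at **every** unmasked frame in
  (anaphase, anaphase + 2 h] (using the whole window rather than the
  single 2-h frame, for noise robustness); otherwise `delay` iff a later
  onset exists (t_delay = onset − anaphase; any post-2 h onset counts,
  with no upper cutoff); otherwise `low`. The three labels partition the
  cohort; labels scored on < 10 h of post-anaphase recording carry a
  truncation flag.
- *Stress outcome*: scored only for cells eligible at the moment of
  stress — corrected CDK4/6 > 0.7, CDK2 > 0.76 and degron flat at 11 h.
  Eligibility and the CDK2-at-stress value use a symmetric ±2-frame
  median at t = 11 h: unbiased on a linear ramp, and tolerant of the
  first post-stress frames. `low` iff CDK2 at 15 h is below 0.76 **or**
  has declined by > 20% from its value at 11 h; the relative clause
  catches cells that reverse clearly while plateauing above threshold.

## Bimodality

`is_bimodal` requires a 2-component Gaussian mixture to beat the single
Gaussian by BIC **and** Ashman's D ≥ 2 between the fitted components. BIC
alone prefers two components for almost any non-Gaussian unimodal sample
(including a gradually spreading ramp), so the separation requirement is
what makes the call mean "two distinct modes".

`bimodal_threshold` fits the mixture to log intensities and returns the
equal-posterior boundary (the root of the quadratic between the means),
falling back to the inter-mode KDE minimum, and to the median with a
degeneracy warning when the components overlap within one pooled sd.

## The synthetic generator

The generator reproduces the kinetic and statistical structure of the
live-cell experiments, not their mechanism; activation is a piecewise-
linear rise, not an ODE. Per cell it draws a small set of latent kinetic
parameters, builds noise-free series, composes the raw CDK4/6 signal with
the f·CDK2 term, and adds i.i.d. Gaussian noise (sd 0.03) clipped at 0.

Key defaults (hours, unitless activity):

| parameter | default | rationale |
|---|---|---|
| dt / duration | 0.2 / 24 | 12-min frames; release time courses run ~1 day |
| p_activate | 0.54 | fraction of released cells that activate under the emulated conditions |
| delay_range | 5–13 | variable delay before the rapid CDK4/6 rise |
| rise_time / plateau | 1.0 / 0.9 ± 0.05 | rapid, switch-like activation to a high plateau |
| CDK2 baseline / slope | 0.5 ± 0.08 / 0.1 h⁻¹ | gradual ramp: crosses 0.76 a few hours after CDK4/6-on and 1.0 (S phase) ~5 h after ramp start, keeping the 2-h post-mitotic CDK2 distribution graded rather than bimodal |
| cdk2_lag | 1.0 (±50% per cell) | CDK2 follows CDK4/6 activation after a short, variable lag |
| apc_trigger / degron_rate | 1.0 / 1.0 h⁻¹ | degron rises once CDK2 reaches the S-phase level |
| mitotic_fate_probs | 0.6 / 0.2 / 0.2 | high / low / delay mix at mitotic exit |
| delay_fate_range | 2–9 | transient-G0 durations after mitosis |
| f_true | 0.35 | CDK2 contamination of the raw reporter |
| rb mixture | lognormal, medians 1 and 10, σ_log 0.3 | well-separated bimodal Rb pS807/811 intensities with strictly positive values |

Ground truth stores the *continuous-time threshold crossings* of the
noise-free kinetics (corrected CDK4/6 at 0.7, CDK2 at 0.76, degron-rise
start), since those are the quantities the detectors estimate; recovery
tolerances are quoted in frames.

Perturbations modify the latent series and re-noise from a derived random
stream (so a perturbed cohort is exactly the counterfactual of its
parent):

- *CDK4/6 inhibitor*: true activity ramps to residual·plateau within 2
  frames; the raw signal keeps the f·CDK2 term. G1 cells reverse their
  CDK2 ramp after a 1 h lag (CDK4/6 activity still feeds CDK2 activation
  in G1); post-G1/S cells keep ramping.
- *CDK2 inhibitor*: CDK2 decays to baseline; the raw CDK4/6 reporter
  settles 15% (configurable, within the observed 10–20%) below its
  pre-treatment level.
- *Stress*: each cell with a flat degron at t_add exits with probability
  logistic in its CDK2 activity (midpoint 0.9, steepness 10 — a free
  parameterization of the observed monotone decrease; steepness ∞ gives
  the step-function limit). Exiting cells inactivate CDK4/6 within 2
  frames and CDK2 after `cdk46_to_cdk2_lag` (1 h default; 0 for
  osmotic-like stresses that suppress both at a similar rate). Cells past
  G1/S never respond.

### What the generator does *not* emulate

Autocorrelated measurement noise, photobleaching drifts, segmentation
artifacts beyond isolated missing frames, cell division during the
record (one anaphase at most), mother–daughter correlations, and any
mechanistic coupling (cyclin D/p21 competition, Rb site kinetics).
Passing tests therefore demonstrate that the *analysis* recovers the
*model's* structure at realistic noise; they do not certify performance
on drifting or heavily autocorrelated real recordings.

## Study sizes and numerics

The analyses use n = 1000 release cells (fate fractions), n = 2000
cycling cells (bimodality, live-fixed matching; the fixed-cell cohort
uses 3000 cells with fixation times spread 1–13 h after anaphase), and
n = 4000 released cells for the stress dose-response (~570 eligible G1
cells across three 0.1-wide CDK2 bins) — sizes typical of automated
live-cell imaging experiments (hundreds to thousands of tracked cells
per condition). Bootstrap bands use 1000
resamples over cells (frames within a cell are dependent). All grids,
seeds and thresholds are explicit function arguments; fixed seeds make
every reported number bit-reproducible. Time-grid uniformity is enforced
at 1e-6 relative tolerance; CSV round-trips preserve values to ≤ 1e-9.

## Known limitations

- The correction uses one global f; per-cell (random-effect) fractions
  are out of scope.
- Onset times are grid-aligned (no sub-frame interpolation), so all
  recovery statements are ±1–2 frames.
- `detect_apc_off` requires 1 h of post-onset follow-up; G1/S transitions
  in the last hour of a record are right-censored.
- The stress dose-response is parameterized logistic; only its
  monotonicity and S-phase resistance are treated as structural.
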