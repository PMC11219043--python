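# Methods

## Scope and model

The package quantifies learned changes in the amplitude of the
vestibulo-ocular reflex (VOR) and the optokinetic reflex (OKR) from raw
horizontal eye-position time series. The underlying response model is a
single sinusoid at the (known, fixed) stimulus frequency: for a vestibular
or optokinetic stimulus with velocity `A·sin(2πft)`, the smooth-pursuit /
reflexive eye-velocity response is `−g·A·sin(2πft + φ)` with gain `g` and
phase `φ`, superimposed with saccades, movement artifacts, sensor noise and
slow drift. The analysis estimates the response amplitude `g·A` robustly
against the non-sinusoidal components; learning is expressed as the percent
change of that amplitude relative to a pre-training baseline.

## Measurement procedure

1. Position is low-pass filtered (Butterworth, order 4, 15 Hz cutoff) and
   differentiated with a Savitzky–Golay filter (30 ms window, quadratic,
   first derivative) to obtain velocity.
2. A first ordinary-least-squares fit of
   `v(t) = a·sin(2πft) + b·cos(2πft) + c` uses every sample. The constant
   term absorbs drift-induced offsets; the frequency is never fitted.
3. Exclusion mask: samples with absolute residual strictly greater than
   31 °/s are marked, each marked sample is dilated by 50 ms on both sides
   (clipped at the trace ends), and any surviving retained run strictly
   shorter than 10 ms is removed as too short to constrain a fit. The
   excluded fraction is counted over *all* samples of the test, pads and
   short-segment removals included.
4. If the excluded fraction strictly exceeds 0.45 the test is invalid and
   reports no amplitude. Otherwise a second, final fit on the retained
   samples gives the amplitude `√(a²+b²)`, phase `atan2(b, a)` and gain
   (amplitude ÷ stimulus peak velocity). Exactly two passes are performed;
   empirically a third mask/refit iteration moves the amplitude by well
   under 0.5 % on standard synthetic traces, so iteration to convergence
   would buy nothing.

Tie handling is strict everywhere ("more than"): a residual of exactly
31 °/s, a segment of exactly 10 ms, and an excluded fraction of exactly
45 % are all kept.

Two readings of the 10 ms segment rule are implemented behind
`fit.min_segment_applies`: the default `"retained"` removes surviving
fragments between exclusions; the alternative `"excluded"` instead
restores sub-10 ms threshold crossings before padding (treating them as
spurious single-sample crossings rather than saccades). The default is the
reading under which the rule has a clear statistical purpose — fragments
shorter than the Savitzky–Golay window cannot constrain the fit.

Similarly, whether the 45 % rejection fraction counts the padded and
short-segment samples is an open reading; the default
(`fit.excluded_fraction_counts: all`) counts everything excluded for any
reason, since the rule speaks of data points excluded, and a
`threshold_only` alternative counts just the residual-threshold
crossings.

## Learning metrics

- VOR testing blocks contain three 45 s tests; their valid amplitudes are
  averaged (a block with 1–2 valid tests still contributes its mean; a
  block with none yields an absent point, never an imputed value).
- ΔVOR(t) = 100·(amp(t) − amp(0))/amp(0), with time 0 the testing block
  immediately before training. In pre-training sessions the points at
  negative times are referenced to the session's first (−30 min) block, so
  each phase reads as change since its own start; the training phase is
  still referenced to the time-0 block.
- OKR sessions are sixty 50 s training blocks, each itself measured.
  Baseline is the mean of blocks 1–3, the post-training value the mean of
  blocks 58–60; ΔOKR is their percent change, with intermediate points at
  blocks 10, 20, 30, 40 and 50.

## Statistics

Shapiro–Wilk screens normality (a failure is logged, not acted on — the
comparisons remain parametric, matching how such datasets are convention-
ally reported). The main comparison is a two-factor repeated-measures
ANOVA, group (between) × time (within) with animal as subject, computed as
a mixed ANOVA; with a single group it reduces to the one-factor
repeated-measures ANOVA, which satisfies F = t² against the paired t-test
for two time points. Significance flags use the uncorrected p at α = 0.05;
Greenhouse–Geisser corrected p-values are reported alongside whenever
there are enough subjects for the sphericity screen (more subjects than
within levels). Tukey HSD post hocs are computed over the family of all
group × time cell means — the common convention that covers both
"group difference at a time point" and "within-group change between time
points" contrasts. Animals missing a within level are dropped from that
comparison only, with a logged warning. In the pipeline's stats stage the
baseline learning point (identically zero for every animal by
construction) is excluded from the ANOVA; it carries no information and
its zero variance would only degrade the sphericity estimate.

## Synthetic data

The generator inverts the measurement model: velocity is built as
`−g·A·sin(2πft + φ)` plus half-sine saccade velocity pulses, white
velocity noise and a constant drift term, integrated (trapezoidal rule) to
position, plus independent white position noise. Saccade trains are
homogeneous Poisson in onset, thinned to enforce non-overlap (which trims
the realized rate a few percent below nominal). Cohorts draw one
multiplicative log-normal gain-jitter factor per animal, applied to the
whole trajectory — between-animal variability therefore scales amplitudes
without distorting any animal's programmed percent change.

Defaults, chosen once as realistic for head-fixed mice on a magnetic
eye-tracking rig and not asserted as facts about any particular dataset:

| parameter | default | note |
|---|---|---|
| sampling rate | 1000 samples/s | typical for such rigs; all ms-denominated thresholds convert to samples at run time |
| saccade rate | 1 /s | amplitudes uniform 100–300 °/s, durations 20–80 ms, random sign |
| velocity noise | 2 °/s SD | white |
| position sensor noise | 0.01 ° SD | white, added after integration |
| gain jitter | 5 % (log-normal SD) | per animal |
| drift | 0 °/s | configurable |

What the simulator does *not* emulate: real saccade main-sequence shape
(pulses are half-sines), blinks and signal dropouts, non-stationary noise,
slow gain fluctuation within a session, and any actual plasticity dynamics
(training blocks advance the protocol clock; their learning effect is
injected through the programmed gain trajectory). Parameter-recovery
results therefore validate the estimator chain, not the biology: passing
tests show the pipeline measures what was programmed under realistic
contamination, not that any particular animal data are this clean.

## Numerical choices

- Zero-phase (forward–backward) filtering is the default: the application
  direction is an open choice, and zero phase keeps the velocity record's
  phase meaningful; at 0.5–1 Hz the amplitude is unaffected either way.
  A causal single pass is available via `filter.zero_phase: false`.
- Savitzky–Golay polynomial order 2 with derivative order 1; the window is
  rounded to the nearest odd sample count (minimum polyorder + 2). The
  combined conditioning chain passes 0.5–1 Hz components at ≥ 99.5 % of
  the ideal differentiator response and removes > 99 % at 30 Hz.
- The sinusoid fit solves the 3×3 normal equations of the
  {sin, cos, 1} basis; the Gram matrix is well scaled, and a condition
  number above 1e12 (retained span under one cycle, or near-empty mask)
  raises a degenerate-fit signal instead of returning garbage.
- Percent-change metrics are exact at the baseline point (0 by identity,
  not by subtraction), and scale-invariant by construction.

## Problem sizes in the validation suite

The acceptance-style tests and `scripts/acceptance.py` run the pipeline at
the study's own conditions (45 s tests at 1 kHz, cohorts of 5 animals per
group, 60-block OKR sessions). Monte-Carlo replicate counts were chosen
as the smallest that make the checked proportions stable: 100–200 tests
for recovery sweeps, 100 replicates for interaction power and 200 for the
type-I calibration in the test suite; the standalone script uses 40/60
replicates for the same two rates, which is enough to reproduce the
qualitative result (≈100 % power, false-positive rate near 5 %).

## Known limitations

- The desaccading threshold (31 °/s) presumes stimulus peak velocities
  near 10 °/s; much larger stimuli would push smooth-pursuit residual
  excursions toward the threshold.
- Gain is reported as an amplitude ratio only; phase is carried through
  but no phase-based learning metric is computed.
- The mixed ANOVA assumes complete cases; animals missing a time point
  are dropped from that comparison rather than modelled (no mixed-effects
  machinery).
- File I/O targets plain-text traces with YAML sidecars; no acquisition-
  system binary formats are read.
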