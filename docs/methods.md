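# Methods

This note documents the models, conventions and numerical choices behind
`whisksel`, and what the synthetic generator does and does not emulate.

## Task model

The generator reproduces the selective-detection trial economy: a trial
mixture of 20% catch and an even target/distractor split (configurable
simplex, validated to sum to 1), two stimulus amplitudes ("large" and
"small", drawn 50/50 on stimulus trials), a 200 ms post-stimulus lockout
in which licking aborts the trial, a 1 s response window, and inter-trial
intervals drawn uniformly from 6–10.5 s.  Optogenetic light is applied on
one third of trials ("on") plus a small tagged fraction (8%, "tag"), as a
triangular waveform rising from a per-trial onset 200–500 ms before the
stimulus to a peak 100–200 ms after it and decaying over 400–600 ms.

Behavioral outcomes are drawn per trial as a Bernoulli response with
probabilities per (trial type × amplitude × light) from a response model.
Large-amplitude and catch defaults use the control/suppression session
averages of the experiment the package is modeled on (hit 0.94/0.96, FA
0.37/0.59, spontaneous 0.29/0.43); small-amplitude probabilities (hit
0.65/0.70, FA 0.25/0.40) and the 3% lockout-lick (abort) rate are free
parameters chosen to sit inside the psychometric dynamic range, since no
source values exist for them.  Response times are uniform in the response
window; hits append a short reward-lick bout, which is what makes the
engagement-epoch machinery exercisable.

## Spiking model

Units are inhomogeneous Poisson.  Each unit draws a baseline rate
(log-normal, median 8 Hz, log-sd 0.5 — a plausible layer-5 regular-firing
range) and an evoked kernel added at each stimulus onset:

    r(t) = max(0, baseline + A · (t/τ) · exp(1 − t/τ))

an alpha function peaking at `t = τ` with amplitude `A`.  Preferred
(contralateral) stimuli use τ drawn from 40–45 ms; unpreferred
(cross-hemispheric) stimuli use 60–80 ms, reproducing the latency gap
between direct and propagated responses.  Small-amplitude stimuli scale
`A` by 0.4 (free parameter).  Emission is Poisson per 5 ms bin — the
canonical analysis resolution — with spike times jittered uniformly
within the bin; exact thinning is deliberately not used because every
downstream statistic operates on 5 ms bins.

**Selectivity coupling.**  Preferred amplitudes are log-normal (median
25 Hz, log-sd 0.4).  Unpreferred amplitudes couple linearly:

    A_unpref = m + s·(A_pref − mean(A_pref)) + σ_resid·ε

with the residual scale `σ_resid = sd(A_pref)·sqrt(1 − s²)` chosen so the
configured `s` is simultaneously the regression slope and the Pearson
correlation of the amplitude pairs.  Unpreferred amplitudes may be
negative (transient suppression below baseline), which real
cross-hemispheric responses show; rates are floored at zero.  A separate
light-on coupling slope reuses the same per-unit residual so
light-on/light-off pairs stay linked within units, and an optional
`opto_distractor_boost` adds a fraction of each unit's preferred
amplitude to its unpreferred amplitude on light-on trials — the
"un-gating" configuration used in the decoder studies.

Note that the across-unit slope measured in d′ units is not numerically
identical to the amplitude-space slope: the amplitude→d′ map saturates,
and shared baseline variability couples the two axes.  Parameter-recovery
tests therefore compare fitted slopes against the generator's
*sampling-free expected d′* (below), not against the amplitude slope.

**Opto gain.**  The light multiplies a unit's rate by
`1 + (g − 1)·w(t)` with `w` the triangular waveform: `g < 1` for putative
excitatory units (suppressed via GABAergic drive; default 0.3 for direct
local suppression) and `g > 1` for putative inhibitory units (directly
driven; default 2.5).  Remote (projection-source) suppression scenarios
use milder excitatory gains (~0.65–0.9).

**Mask contamination.**  The visual mask light can leak 10 Hz
(onset-locked) and 20 Hz rhythms into recordings.  The generator
multiplies the rate by `1 + d₁₀ sin(2π·10(t−t₀)) + d₂₀ sin(2π·20(t−t₀))`,
phase re-locking at each mask onset, *before* Poisson emission; depths
default to 0.

**Sampling-free expectations.**  For any unit/stimulus/light condition
the exact epoch-mean spike counts are obtained by integrating the floored
rate profile on a 0.5 ms grid, and the exact fixed-window AUROC follows
by direct pmf summation over the implied Poisson mixtures
(`poisson_mixture_auroc`).  These expectations are the ground truth for
slope-recovery and feature-calibration tests and involve no sampling.

## Analysis conventions

- **Time.** All event times are seconds from session start; trial-aligned
  quantities are seconds from stimulus onset; bins are half-open
  `[edge, edge + 5 ms)`, so an edge spike belongs to the later bin.
- **Log-linear correction** is applied to every trial type always, not
  only to degenerate counts, keeping all Z-transforms finite.
- **Engagement** is computed from lick times alone; the longest qualifying
  epoch trims the trial table before *any* behavioral or neuronal
  analysis, so both use identical trials.  Abort trials are excluded from
  rate denominators and from the ≥ 5-trial inclusion rule.
- **Fixed-window d′** treats each trial's two 50 ms epochs as separate
  samples (2N per class); a `pooled=False` switch sums them to one 100 ms
  count per trial instead.  AUROC is clipped to
  `[1/(4N), 1 − 1/(4N)]` before the Z-transform so d′ stays finite but the
  bound tightens with evidence; the clip is configurable.
- **Sliding d′** uses the fixed last-100 ms pre-stimulus span, tiled into
  five 20 ms windows, identical for every post window; the ×5 pre-sampling
  is balanced by weighting post samples ×5 inside a weighted AUROC, which
  the suite proves identical to literal 5-fold duplication.
- **Mask filtering** is a second-order Butterworth band-stop (9–11 Hz and
  19–21 Hz) applied forward-and-backward (zero-phase).  The filter is
  specified by its behavior — ≥ 20 dB notch attenuation, < 10% distortion
  at 3 Hz, DC gain 1 ± 1% — rather than coefficient identity, because
  those properties are what downstream statistics rely on.
- **Cell typing** uses Welch's unequal-variance t-test (robust default; α
  = 0.1 configurable) on per-trial mean rates inside the light window with
  its first and last 100 ms excluded, on suppression trials by default.
- **Alignment QC** passes when the multi-unit PSTH peak within 50 ms
  post-stimulus reaches ≥ 1.4× the 100 ms pre-stimulus mean; a zero
  baseline fails with an explicit flag.
- **Selectivity fits** are OLS with t-based 95% intervals (n − 2 df).
  The rotation/shift verdict compares slope CIs, and compares the fitted
  line's *height at the pooled preferred-d′ centroid* rather than the
  x = 0 intercept: a rotation about the population center moves the
  extrapolated intercept even when no unit is displaced, so the centroid
  height is the displacement measure that separates the two mechanisms.
  A permutation test on the slope difference is available as a stricter
  alternative.
- **Reader.** "Diagonal covariance" means one pooled per-feature variance
  shared by both classes with equal priors — a linear rule; class-specific
  variances would make it quadratic and are rejected.  Trial features are
  baseline-subtracted rates using the first 50 ms post-stimulus and a
  100 ms baseline (length configurable; no source value exists).
  Reconstruction duplicates whole trial sets while they fit and fills the
  remainder by sampling without replacement; each unit's trial order is
  then shuffled independently.  Pseudo-ensembles therefore contain no
  noise correlations by construction — intended, not a bug.  A master
  seed spawns one child seed per iteration, so a single iteration equals
  one train/test call on the same chain.  Units are ranked by target d′
  with deterministic unit-id tie-breaks; the "top half" is the smaller
  half for odd counts (197 → 98).
- **Whisker motion.** "Normalized (squared)" frame differencing is read
  as squared differences with no per-pixel normalizer.  Z-scoring uses
  pre-stimulus mean and SD only, so post-stimulus inflation survives
  standardization.  The immediately-pre-stimulus reference is literally
  one frame.  Frame times are stored explicitly; no constant frame rate
  is assumed.  High-motion exclusion keeps `ceil(n/2)` trials with
  trial-index tie-breaks.
- **Cross-session coupling.** The encoding delta per session is the
  population sliding d′ for distractor stimuli averaged over windows
  starting 30–80 ms (i.e. spanning 30–100 ms post-stimulus), light-on
  minus light-off; R² against each behavioral delta is squared Pearson
  correlation from OLS.

## Problem sizes

Simulation-backed tests use sizes large enough for their binomial or
t-based tolerances to be meaningful and no larger: 1000 null sessions of
50 trials (plus 170 groups of 17 for the type-I check), 100 populations of
200 units × 300 trials for slope-CI coverage, 98-unit pseudo-ensembles
with 200–300 reader iterations, and 10⁴-sample classes for the Gaussian
d′ identity.  The full pipeline demonstrations run 2–3 sessions of
250–300 trials and 8–24 units.

## What the generator does not emulate

Poisson emission has no refractoriness, bursting, or spike-sorting
artifacts; units are conditionally independent given their rates, so
within-session noise correlations are absent; the opto gain is
multiplicative and instantaneous with no network dynamics; whisker traces
are generated directly as motion-energy values (outcome-locked ramps plus
noise), not rendered frames; lick statistics beyond the response model
and reward bouts are not modeled.  Passing parameter-recovery tests
therefore demonstrates that the *analysis* is correct and calibrated
under the stated stochastic model — not that the model captures every
property of cortical data.  Widefield imaging d′ maps, choice
probability, spike sorting and video decoding are out of scope.
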