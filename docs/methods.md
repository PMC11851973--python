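# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where more than one
reasonable option existed.

## The behavioral decomposition

A search trial begins at display onset and ends with a button press. The
eye-tracking record splits the reaction time (RT) at the start of the first
fixation on the target:

* **search time, ST** — onset → first target fixation (attentional,
  peripheral-selection component);
* **target identification time, TIT** — first target fixation → press
  (perceptual, foveal component), with RT = ST + TIT exactly for every
  included trial.

ST is further decomposed into **DS** (how many distractors were visited
before the target) and **DRT** (mean dwell on those distractors —
distractor *rejection* time), and each trial records **FFT**, whether the
very first item fixated was the target. Consecutive fixations on the same
item are merged into a single visit before counting, so a micro-refixation
does not inflate DS; a visit's dwell is the summed duration of its
fixations. "First fixation" always means the first fixation landing on a
display item: the fixation the trial starts with sits at the central cross
and belongs to no item, so it cannot carry item-level information.

Correctness is gaze-determined: a trial counts as correct only if a press
occurred within the 5 s deadline *and* the item fixated at press time is
the target. This mirrors the gaze-contingent feedback a live session gives
and is stricter than merely requiring a prior target fixation.

### Exclusions

Trials are filtered sequentially: (1) incorrect trials; (2) RT < 100 ms or
more than 2 SD from the participant's mean RT; (3) the same 2-SD rule on
ST over the survivors; (4) the same on TIT. Each stage recomputes its
mean/SD over the previous stage's survivors only — the procedure is
order-dependent by design and not idempotent (re-running it can remove
trials newly outside 2 SD of the tightened distribution). SD uses the n−1
denominator; participants with fewer than 3 surviving trials skip the SD
rule at that stage, with a warning in the exclusion log.

## Fixation detection

A dispersion (I-DT-family) detector: a candidate fixation grows while the
next valid sample lies within `radius_deg` (default 2.5°, read as Euclidean
distance — a circle) of the running centroid of the candidate's samples;
a violating sample closes the candidate, which is kept only if its duration
is *strictly* greater than `min_duration_ms` (default 100 ms). Invalid
samples are skipped without closing the candidate; a gap longer than
`max_gap_ms` (default 75 ms, config-exposed) does close it, which is the
blink rule. AOI assignment tests the fixation centroid against each item's
drawn rectangle (2.5° × 4.5° by default, padding configurable).

The detector is validated against an independent, deliberately naive
restatement of the same rule on 1,000 random streams, and against the
generator's planted scanpaths (≥ 99% mean interval overlap; the residual
~0.3% is 300 Hz sample-grid quantization at fixation edges, not detector
error).

## Image features

The 2-D FFT magnitude spectrum of a grayscale image is summed into
24 spatial-frequency × 16 orientation bins → 384 nonnegative energies.
Choices:

* **Frequency bands**: log-spaced edges from 1 cycle/image (the lowest
  non-DC frequency) to the spectrum corner, matching standard practice for
  natural-image statistics; edges are emitted in the output metadata so
  alternative spacings remain testable.
* **Orientation bands**: 16 bins of 11.25° on [0°, 180°), first bin
  centered on 0°. Orientation is folded modulo 180°, so a conjugate pair
  of coefficients always lands in the same bin and the 384 values sum
  *exactly* to the total non-DC magnitude (energy conservation, tested to
  1e-9 relative error).
* **DC excluded** (mean luminance, matched across stimuli at blending);
  **no window** applied before the FFT (recorded in metadata).
* Phase is discarded, so the description is translation-invariant; for
  square odd-sized images a 90° rotation permutes the orientation bins by
  exactly 8 (even sizes break exact equivariance at the unpaired Nyquist
  row/column).

Low-frequency bins may contain no exact integer wavevector — the discrete
spectrum is sparse at small radii — so the grating-based texture generator
refuses unrepresentable bins rather than silently leaking energy into a
neighbor.

## Mixed models

Each of the six measures gets a 2 × 2 generalized linear mixed model with
target emotion (happy vs. angry, reference angry) and search task
(find-specific vs. find-both, reference find-both) as crossed fixed factors
plus interaction, and a random intercept per participant:

| response | family | link | units |
|---|---|---|---|
| RT, ST, TIT, DRT | gamma | inverse | seconds |
| DS | Poisson | log | count |
| FFT | binomial | logit | probability |

Fitting is delegated to `glmmTMB` through `Rscript` (there is no
frequentist gamma GLMM in the scientific Python stack); the gamma/inverse
fit falls back to a log link only on documented non-convergence and the
summary flags it. DRT models automatically drop direct-hit trials (DS = 0,
dwell undefined), which is why their N is smaller.

**Effect scale.** Estimates are reported multiplicatively: exp(coefficient)
for Poisson/binomial (incidence-rate and odds ratios), and ratios of
back-transformed cell means for the gamma models (emotion ratio at the
reference task, task ratio at the reference emotion, and the
ratio-of-ratios interaction), with delta-method CIs on the log-ratio scale
and Wald p-values on the raw terms. Because the 2 × 2 fixed part is
saturated, the four cell means do not depend on the link, so a
multiplicative effect planted on the mean is the estimand itself — this is
what makes parameter recovery well-defined. ICC and marginal/conditional R²
use latent-scale distribution-specific residual variances (trigamma for
gamma, log-normal approximation for Poisson, π²/3 for logit) and should be
read as descriptive.

## The synthetic generator

The generator emulates the paradigm's structure exactly: 12 blocks × 32
trials in the palindromic condition order X-Y-Z-X-Y-Z-Z-Y-X-Z-Y-X with
counterbalanced assignment; per block every one of the 16 sub-quadrant
positions serves as target position exactly twice; the 7 distractors split
{3, 2, 2} over the three non-target main quadrants; positions jitter ±1°
in x and ±0.23° in y.

Per trial, latent behavior is sampled first: a distractor visiting order by
softmax (Gumbel-max) over planted selection scores
(`feature_selection_betas · band energies + noise`), a uniform 0–7 count of
distractors inspected before the target, gamma-distributed dwells whose
log-mean carries `feature_dwell_betas · energies` plus the task/emotion
multipliers and a log-normal participant effect (SD 0.10), and a
gamma-distributed identification time scaled by `emotion_tit_ratio` for
happy targets and `task_ratio` for single-target blocks. Gamma shapes are
10 (CV ≈ 0.32, typical for fixation durations); base dwell 250 ms, base
TIT 550 ms, initial saccade latency 200 ms, saccade flight 25 ms. Dwells
are floored at 110 ms so a planted visit cannot be erased by the > 100 ms
fixation-duration rule. About 8% of trials end with a press on a distractor
and trials passing the 5 s deadline become timeouts.

Gaze rendering places 300 Hz samples at each planted fixation location with
isotropic Gaussian noise (SD 0.3°, the fixture's stand-in for ~0.5°
tracker accuracy) and linear interpolation during saccades. Because the
latent timing is sampled before rendering, `render_gaze=False` returns the
same per-trial measures without the sample stream; large parameter-recovery
simulations use this path and the rendered path is validated separately by
the round-trip test. Sub-quadrant centers are ≥ 5° apart while the
dispersion radius is 2.5°, so planted fixations are separable by
construction.

**What the generator does not emulate**: photorealistic faces (features are
drawn i.i.d. normal rather than extracted from face images), oculomotor
dynamics (main-sequence velocities, undershoot, drift), inter-item
dependencies in selection beyond the planted linear scores, and
participant-level variation in the planted effect sizes. Passing tests
therefore certify the *analysis machinery* — that planted structure of the
stated form is recovered at the stated sizes — not that real faces carry
such structure.

## Decoding

For each behavioral metric (first-eye-movement rate, selection rate, mean
dwell per image, z-scored within task): 10 cross-validation iterations,
each holding out a random third of the images (splits drawn independently
per iteration; the protocol does not require disjoint folds). On the
training two-thirds a bidirectional stepwise linear model selects features
(entry p ≤ 0.05, removal p > 0.10 — the classic defaults — plus a
config-exposed cap of 30 features per iteration, which bounds the
well-known overselection of stepwise procedures when 384 candidates meet a
0.05 entry criterion). Holdout predictions are Spearman-correlated with the
true scores; the LDA arm (scikit-learn, svd solver — robust to the
collinear subsets stepwise can select) classifies the metric's quartile
labels (rank-based, stable tie-break, remainder to the lower quartiles).

Nulls: the regression null re-correlates the fixed holdout predictions
against shuffled true scores (1,000 draws total by default), the decoding
null shuffles holdout labels (10,000 draws); draws are split evenly over
iterations and pooled before z-scoring. The observed statistic is the mean
over the 10 iterations; z = (observed − null mean)/null SD and p is the
upper normal tail. Because a mean over iterations is compared against
single-iteration null draws, the p-values are conservative under the null
(they concentrate toward 0.5 rather than being exactly uniform); the joint
rule — *both* p_rho < 0.001 and p_decode < 0.001 — is therefore at most,
and in practice well below, its nominal type-I level, which the calibration
test verifies at α = 0.05 over 100 replicates.

Cross-condition transfer applies the source condition's iteration-averaged
betas and intercept to the target condition's features (regression arm) and
trains an LDA on the source data restricted to features selected in more
than one iteration (classification arm), with nulls built by shuffling the
target condition's data. If no feature recurs across iterations the
classification arm is skipped with an explicit status rather than silently
reporting chance.

Label decoding (e.g. emotion category from band energies) uses the same LDA
machinery with group-held-out folds: each level of a nuisance grouping
factor (such as the gender split of a stimulus set whose images share
blended parts within gender) is tested once while the other levels train,
preventing leakage through shared image content.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed and derives
per-trial/per-iteration substreams deterministically (`SeedSequence`
spawning); identical seed + config + data give bit-identical results. The
shipped validation uses the sizes at which the statistical claims are
stated: 1,000 streams for detector-oracle equivalence, 200 images for
binning exactness, 100 pure-noise replicates for calibration, 20 runs of
300 images at variance-SNR 2 for signal recovery, and 20 cohorts of 20
participants × 384 trials for recovery of a planted 0.84 TIT emotion ratio
(accepted when ≥ 90% of estimates fall in [0.80, 0.88]). The acceptance
script reports a 5-cohort mean for the same quantity.

## Known limitations

* The stats stage requires an R installation with `glmmTMB`; it is a
  backend, not a Python dependency, and the package raises a structured
  error when `Rscript` is absent.
* Stepwise selection at liberal entry criteria overfits its training split
  by construction; all performance claims rest on the held-out third and
  the permutation nulls, never on training fit.
* The inverse-link gamma model's random intercept lives on the inverse
  scale while the generator's participant effect is log-normal on the mean;
  at the simulated effect sizes (SD 0.10) the induced bias in the cell-mean
  ratios is far below the recovery tolerance, but the mismatch is real and
  intentional (it reflects what an analyst fitting the standard model to
  unknown data would do).
* Quartile labels are computed on raw metric values within task; any
  monotone standardization (including the z-scoring) yields identical
  labels, so the order of those two steps is immaterial.
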