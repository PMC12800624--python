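# Methods

## The question and the pipeline

A call type produced across several behavioral contexts may still carry
context information in its acoustic microstructure.  The pipeline
quantifies this in three stages: (1) measure a panel of acoustic
features per call; (2) keep the features whose between-context variation
exceeds their within-context variation (PCC screen) and that meet the
distributional assumptions of a linear discriminant; (3) classify
contexts with leave-one-out cross-validation and test the correct count
against chance.  A second, independent arm analyzes how listeners react
to played-back calls, with mixed models over a small repeated-measures
field design.

## Acoustic feature extraction

Calls are framed (1024 samples, 50% hop, Hann).  Intensity is frame RMS
in dB re full scale 1.0 — absolute SPL calibration is out of scope.
Spectral shape statistics (moments, quantiles, normalized entropy,
flatness) come from the Welch average periodogram rather than per-frame
averages, so a table is bit-reproducible for fixed settings.  f0 is
tracked per frame as the inverse of the lag maximizing the normalized
autocorrelation inside [40, 1200] Hz, with parabolic interpolation; a
frame is voiced iff the peak reaches 0.45.  Formants are LPC roots
(autocorrelation method, order sr/1000 + 2) on the signal resampled to
10 kHz; resampling keeps the prediction order matched to the formant
band and stabilizes root estimates.  Candidate roots must have
bandwidth < 1000 Hz and spectral energy within 60 dB of the frame peak
— the energy gate rejects the narrow numerical poles an unfiltered tone
produces, and the admissible-frame fraction is reported as a confidence
flag.  The lowest four ascending candidates are F1–F4; per-call values
are frame medians.

The panel (31 features) covers every family a context analysis draws
on: duration, intensity, spectral shape, dominant frequency, f0
statistics and slope, voicing fraction, formants and formant
dispersion.  The downstream statistics are panel-agnostic: any labeled
feature table works.

## PCC screen and selection

CVw uses the small-sample correction factor (1 + 1/(4n)) and sd with
denominator n − 1; CVb is the pooled CV; PCC = CVb / unweighted mean of
the per-context CVw.  Features with nonpositive means (e.g. dB-scaled
intensity) have undefined CVs and are flagged and excluded rather than
silently transformed.  The selection defaults are: PCC ≥ 1.0 (the
threshold is a parameter because "greater than 1" and "≥ 1" both appear
in common usage), Shapiro–Wilk on pooled values at α = 0.05 (a
per-context mode is available; pooled is stricter against strongly
shifted features and is the documented default), redundancy pruning at
|r| ≥ 0.9 with single linkage, representative = the median-type variant
of a {mean, median, sd} family when present, else the highest-PCC
member.  The report accounts for every input feature exactly once with
a per-step rationale.

A consequence worth knowing: under a pure null the PCC gate alone
passes ~1/3 of features (the null PCC distribution is centered just
below 1).  Selecting features on the full dataset and cross-validating
only the classifier therefore leaks the held-out call into the panel
choice: in our zero-shift simulations that workflow rejects the pooled
chance hypothesis in ~12% of datasets at α = 0.05, while the same
pipeline with a fixed panel rejects in ~3%.  The package's end-to-end
entry point (`nested_select_classify_loocv`) re-runs the three-step
screen on every training fold, restoring calibration; the select-once
path remains available for comparability with workflows that use it,
with this caveat documented.

## Discriminant classification and assessment

The classifier is the canonical LDA: pooled within-class covariance
(denominator N − g), axes from eig(W⁻¹B) scaled to unit within-class
variance, assignment by Mahalanobis distance adjusted by log prior
(uniform priors by default; proportional available).  A ridge of
1e-8 · mean(diag) is added only when the correlation-scaled covariance
has condition number above 1e10; ties in the posterior break toward the
lowest class index.  LOOCV refits the model for every held-out call.
Assessment is always against proportional chance — per class the class's
sample proportion, pooled 1/g — with exact binomial tail sums computed
via log-gamma (the two-sided version uses the minimal-likelihood
convention with a 1 + 1e-7 comparison tolerance, matching standard
exact-test implementations).  Contributions are Pearson correlations of
features with discriminant scores; scores come from the full-data fit by
default because held-out scores are not comparable across folds, and a
`loocv` scores option exists for the stricter variant.

## Playback simulation

The synthesizer is not a model of any species' vocal anatomy; it is a
source–filter surrogate in which each feature family is independently
manipulable: duration (envelope length), intensity (SNR), source (f0
base, slope, jitter CV, harmonic rolloff), filter (four resonator
centers/bandwidths).  Context effects are field-wise additive or
multiplicative shifts; the defaults put the high-intensity social
context furthest from the non-social baseline (f0 × 1.18, duration
× 1.15, formants × 1.06, steeper slope), with the low-intensity social
context halfway — an arousal-gradient pattern.  Caller profiles are
log-normal multiplicative offsets (f0 6%, formants 3%, duration 5%)
drawn once per (caller, seed).

Stimuli are triples of same-condition calls from distinct callers with
pauses uniform on [5, 10] s (the protocol specifies only "randomized")
and peak-equalized amplitudes.  The scheduler enforces the protocol
constraints listed in the README; "≥ 24 h spacing" is modeled as a
day-index difference ≥ 1, and the ≤ 3/day cap is global across subjects
(a per-subject cap would contradict the per-subject one-day spacing).
An independent validator re-checks every constraint on any design.

Trial responses: gaze differences are zero-inflated Poisson on the log
scale with a subject random intercept; the default mechanism adds a
nonnegative ZIP draw to the pre-stimulus count so the after − before
difference is the ZIP variate itself (`gaze_mode="raw"` instead draws
the after count independently, allowing negative differences — both
exist because the response definition admits either reading, and the
mixed-model fitter directs negative responses to the floored mode).
Yawn responses are Bernoulli on the logit scale mixed with a
spontaneous floor 1 − exp(−rate × 3 min); with the default rate of
0.25/min the floor is ≈ 0.53, so evoked probabilities can only raise it
— the conservative reading of a reported maximum spontaneous rate.
Default coefficient values are realistic field-scale effects (gaze:
intercept 1.19, social-trigger advantage ≈ +1 log unit over non-social;
yawn: receiver-grooming advantage +3.16 logits; subject SD 0.19).

## Mixed models

The four presets are: (1) gaze difference ~ sex + receiver context +
trigger context + trial order (control), ZIP; (2) the same for
self-directed-behavior differences; (3) yawn occurrence ~ sex +
receiver context + trigger context + trial order + gaze difference
(controls), Bernoulli; (4) yawn occurrence on the grooming subset
restricted to high-social-yawn vs grunt stimuli, with sex and trial
order as controls.  Models 1–3 use only yawn-stimulus trials (54 of 72
sessions at the 9-subject scale); dummy coding baselines are
high-social for the trigger factor (grunt when present, i.e. model 4),
female for sex, non-social for the receiver context.

Estimation maximizes the marginal likelihood with *adaptive*
Gauss–Hermite quadrature (order 20 default): nodes are recentered at
each group's conditional posterior mode and rescaled by its curvature,
found by damped Newton with analytic first/second derivatives
(including the zero-inflation mixture term).  Plain fixed-order GH is
measurably inaccurate here — with 8 observations per subject the group
posteriors are narrow relative to the random-intercept scale and the
order-20 error reaches ~0.2 log-likelihood units, whereas the adaptive
scheme is stable to < 1e-4 between orders 20 and 40.  σ is optimized
directly with a [0, ∞) bound so boundary (singular) fits land exactly
at σ = 0; zero inflation is intercept-only on the logit scale.
Optimization is L-BFGS-B from GLM starting values with two jittered
restarts; fixed-effect covariance comes from the numeric Hessian at the
optimum.  Complete separation is flagged when any |β| exceeds 15 — the
expected symptom on degenerate subsets such as model 4's 18 rows.

LRTs compare full vs control fits (χ² with df = parameter-count
difference, floored at 0).  Pairwise contrasts report z statistics with
Bonferroni (default) or studentized-range (Tukey) adjustment — both are
offered because protocols often name both.  VIFs use the correlation-
determinant form of the generalized VIF with the 1/(2·df) exponent for
multi-column factors.

## What the synthetic data does and does not show

The generator reproduces the statistical *structure* the analysis
assumes — context shifts with caller random effects, ZIP counts,
floored Bernoulli responses, the exact design constraints — not the
acoustics of any real species, colony noise, recording-chain variation,
or coder error.  Passing tests therefore demonstrate that the pipeline
recovers known structure at field-realistic sizes and controls its
error rates under the null; they say nothing about whether any
particular real dataset contains such structure.

## Problem sizes and numerical choices

Simulation-based tests run at desk scale, chosen once: calls of
0.25–0.4 s at 16–22 kHz; 30–45 calls per replicate dataset for
calibration (200 replicates) and the 4-point shift-sweep power check
(12 replicates/point); 500 replicates for LRT null calibration and
ZIP effect recovery at the 9 × 8 design (quadrature order 12, single
start, which the stability checks justify).  The acceptance script uses
the full 88-call pool split 41/26/21.  Tie-breaks, ridge and separation
thresholds, and the quadrature scheme are described above; degenerate
inputs (all-unvoiced calls, constant features, emptied LOOCV classes,
infeasible designs) are flagged or excluded with explicit reasons
rather than patched.

## Known limitations

Per-frame spectral statistics are summarized from the average
periodogram, so transient within-call dynamics beyond the f0 slope are
not captured.  The formant tracker assumes four resonances below 5 kHz.
The ZIP zero-inflation structure is intercept-only.  Model 4's subset
is small by design (2 sessions × subjects) and routinely produces
separation warnings; its fit is reported with flags rather than
suppressed.  The scheduler uses randomized greedy construction with
restarts — it finds feasible designs quickly at field scale but is not
a completeness proof; infeasibility errors name the binding constraint
from counting arguments where one exists.
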