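# callcontext

Context coding in animal vocalizations: does the social situation in
which a call is produced leave a measurable imprint on its acoustics,
and do listeners react to that imprint?  `callcontext` packages the full
analysis workflow used to answer this question for derived
vocalizations such as the yawn calls of gelada monkeys — from call audio
to classification statistics, and from playback-experiment trial tables
to mixed-model inference — together with a synthetic-data generator so
the whole pipeline runs and is testable without any field recordings.

## What it computes

**Acoustic side.** For every call, a ~31-feature panel (duration, frame
RMS intensity, spectral shape, f0 contour, LPC formants).  Features are
screened by the Potential of Contextual Coding,

    CVw = 100 · (sd/mean) · (1 + 1/(4n))      (within-context, small-sample corrected)
    CVb = 100 · (sd/mean)                     (pooled sample)
    PCC = CVb / mean(CVw over contexts)

followed by a Shapiro–Wilk normality screen and redundancy pruning
(|Pearson r| ≥ 0.9 single-linkage clusters, one representative kept —
the median-type variant when present).  Surviving features enter a
linear discriminant analysis; classification is assessed by
leave-one-out cross-validation and exact binomial tests of the correct
count against class-proportion chance (per class) and 1/g (pooled).
Feature contributions are the Pearson correlations between each feature
and the discriminant scores.

**Behavioral side.** Playback responses are modeled with generalized
linear mixed models with a subject random intercept, fitted by adaptive
Gauss–Hermite maximum likelihood: zero-inflated Poisson for
gaze-count differences (after − before the stimulus), Bernoulli-logit
for yawn occurrence in the 3-minute window.  Model significance is the
likelihood-ratio test of the full model against the control model;
pairwise contrasts use delta-method SEs with Bonferroni or Tukey
adjustment, and collinearity is checked with (generalized) VIFs.

**Synthetic data.** A source–filter synthesizer (harmonic source with
linear f0 contour and per-period jitter, four formant resonators,
attack/decay envelope, additive noise) produces call pools with
context-dependent shifts and per-caller random offsets; a scheduler
builds playback designs honoring the field protocol (8 sessions per
subject = 4 stimulus conditions × 2 receiver contexts, ≤ 3 playbacks per
day, ≥ 1 day between a subject's sessions, call reuse ≤ 2, no repeated
three-call combination); a trial generator emits gaze/SDB counts and
yawn responses under stated effect sizes with a spontaneous-yawning
floor of 1 − exp(−rate × 3 min).

## Worked example

```python
from callcontext import simulate, features, coding, discriminant

cfg = simulate.SynthCallConfig(sample_rate_hz=22050, duration_s=0.35)
waveforms, manifest = simulate.generate_call_dataset(
    base_config=cfg, n_callers=5, calls_per_caller_per_context=3, seed=11)
table = features.extract_table(waveforms)

feats = [c for c in table.columns if c in features.FEATURE_NAMES]
report = coding.select_features(table, feats)
selected = report.loc[report.retained, "feature"].tolist()

loocv = discriminant.classify_loocv(table, selected)
print(selected)
print(round(loocv.total_correct, 3))
print(discriminant.assess_classification(loocv))
```

prints

```
['dur_s', 'spec_centroid_hz', 'spec_sd_hz', 'spec_q25_hz', 'spec_q75_hz', 'spec_entropy', 'spec_flatness', 'domfreq_median_hz', 'f0_median_hz', 'f2_median_hz']
0.644
          test   k   n        p0 alternative   p_value
0  high_social  12  15  0.333333     greater  0.000285
1   low_social   8  15  0.333333     greater  0.088232
2   non_social   9  15  0.333333     greater  0.030828
3       pooled  29  45  0.333333     greater  0.000019
```

i.e. on a 45-call synthetic pool with the default context shifts, ten
features survive the three-step screen and the cross-validated
classifier assigns 29/45 calls (64%) to the right context, well above
the 1/3 pooled chance (exact binomial p ≈ 2e-5).

The same flow is available from the shell:

```sh
callcontext simulate-calls --out-dir calls --seed 11
callcontext features --manifest calls/manifest.csv --out features.csv
callcontext select --features features.csv --out-dir out
callcontext dfa --features features.csv --selected out/selection_report.csv --out-dir out
callcontext simulate-trials --out trials.csv --seed 11
callcontext fit --data trials.csv --model 1 --out-dir out
```

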