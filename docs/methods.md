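# Methods

`somnostat` implements a complete analysis chain for studying the
relationship between *subjective* sleepiness (questionnaires) and
*objective* sleepiness (resting-state EEG vigilance dynamics) in cohorts
stratified by obesity (BMI >= 30 kg/m^2) and depression (BDI-II >= 14),
together with a synthetic-data layer that stands in for a clinical
cohort whose raw data is not publicly deposited.

## EEG-vigilance staging

Each non-overlapping 1-second segment of an eyes-closed resting
recording is assigned one of seven vigilance stages, ordered from high
alertness to sleep onset and scored 7..1:

| stage | score | characteristic |
|-------|-------|----------------|
| 0     | 7     | low-voltage EEG, no alpha, no slow eye movements |
| A1    | 6     | predominant occipital alpha |
| A2    | 5     | high temporal/parietal alpha |
| A3    | 4     | predominant frontal alpha |
| B1    | 3     | low-voltage EEG with slow horizontal eye movements |
| B2/3  | 2     | increased delta and theta power |
| C     | 1     | sleep spindles and K-complexes |

Features per segment come from a Hann-tapered periodogram averaged
within three scalp regions (frontal / temporal-parietal / occipital)
using conventional clinical bands: delta 1-4 Hz, theta 4-8 Hz, alpha
8-12 Hz, spindles 11-16 Hz, total 1-30 Hz.  The classifier is a fixed
decision cascade:

1. spindle or K-complex detected -> **C**;
2. delta+theta power at least 1.5x the recording's unmasked median
   *and* at least 40% of the segment's total power -> **B2/3** (the
   share condition stops spectral leakage from a strong alpha or
   spindle second from mimicking slow-wave drowsiness);
3. alpha below 30% of total power: **B1** if the EOG shows a slow
   (<= 0.6 Hz) deflection above 25 uV peak-to-peak, else **0**;
4. otherwise **A1/A2/A3** by the region of maximal alpha power, ties
   broken occipital > temporal-parietal > frontal (favoring the higher
   stage).

These thresholds are deliberately transparent stand-ins for the opaque
internals of clinical vigilance classifiers (which additionally use
source localization and adaptive alpha bands); they are tunable through
`StagingSettings` and their defaults are chosen so that noiseless
single-characteristic segments reproduce the stage table exactly.
Detector details: the SEM detector low-passes the EOG at 0.6 Hz
(2nd-order zero-phase Butterworth, constant padding — at so low a
cutoff the padding mode dominates edge leakage, and constant padding
keeps a 10 Hz 120 uV oscillation below 4 uV residual); the spindle
detector requires the 11-16 Hz analytic envelope to stay above 10 uV
for 0.3 s; the K-complex detector requires a > 75 uV peak-to-peak slow
transient correlating with a biphasic template.  Seconds in which any
scalp channel exceeds +-100 uV are masked as artifacts and excluded
from every downstream summary (the threshold is a declared default; the
source protocol states exclusion but no rule).

Recordings shorter than 60 s are rejected: the B2/3 criterion needs a
within-recording baseline.

## Arousal metrics

From a staged sequence (unmasked seconds only):

* **stage proportions** for 0, A (A1+A2+A3), B (B1+B2/3) and C;
* **MVV**, the mean of the per-second scores, range 1-7, reported
  unrounded;
* **ASS**, the arousal stability score, range 1-11, from a precedence
  cascade: any C second scores 3/2/1 by the 5-minute bin (11-15 / 6-10
  / 1-5) of the first C; else a B2/3 share >= 1/3 scores 6/5/4 by first
  B2/3; else a B share >= 1/3 scores 9/8/7 by first B; else 11 if only
  0/A1 occur, 10 if only 0/A occur.

Design choices where the published rule table is ambiguous: the
criteria overlap (every B2/3 second is a B second), so the cascade
applies the least-stable applicable level first, matching the score
ordering; minute bins use wall-clock position (masked seconds keep
their place) while shares use unmasked seconds; first emergence after
minute 15 maps to the 11-15 bin; a B share below one third with other
stages present scores 10 and is flagged (`sub_threshold_b`); sequences
shorter than 15 minutes are scored with the same rules and flagged
rather than rejected, so short-recording pipelines complete.

## Questionnaires

ESS (8 items, 0-3 each; total > 10 flags excessive daytime sleepiness),
KSS 1-10 and SSS 1-7 single items, VAS 0-100, each administered before
and after the recording with change scores post - pre; ASLEEP 1
(definitely fell asleep) .. 4 (surely not); SSQ = mean of the 8
restedness items (1-5); SSD in minutes.  Records with missing or
out-of-range items are rejected with row-numbered messages — no
imputation.  Group labels are recomputed from BMI/BDI-II; BMI exactly
30 counts as obese (WHO cut-point convention) and BDI-II >= 14 as
depressed.

## Synthetic cohort generator

The generator defines the study conditions under which the statistical
battery is validated.  Per subject:

* a latent trait sleepiness `z ~ N(0,1)`;
* a first-order Markov chain over the seven stages at 1 Hz.  From
  stage `s` the chain steps down with probability
  `p_down[s] * exp(g * c * z)` and up with `p_up[s] * exp(-g * c * z)`
  (drift gain `g = 0.7`, coupling `c in [-1, 1]`, default 0.4), so
  higher trait sleepiness accelerates the descent when coupling is
  positive and the trajectory is trait-free at `c = 0`.  Default rates
  were chosen once so that a default cohort shows a realistic profile —
  roughly 5/44/49/2% of time in stages 0/A/B/C, mean MVV ~3.8, mean ASS
  ~4.5, and about two thirds of subjects reaching a brief sleep-onset
  episode within 20 min;
* questionnaire latents `0.8 z + shift(group) + 0.6 eps` (unit
  variance), discretized to each instrument's scale.  Group shifts
  (HC 0, OB 0.15, DEP 0.75, OBDEP 0.90 latent SD) are calibrated so the
  depressed groups report visibly higher situational sleepiness while
  objective measures stay similar — the qualitative pattern of the
  cohorts this emulates.  Post-recording scores add a small group-level
  change (HC +0.35 ... OBDEP -0.25) driving the delta scores;
* ASLEEP derives from a latent `c * z_BC + sqrt(1 - c^2) * eps`, where
  `z_BC` is the standardized true share of drowsy/sleep (B+C) seconds:
  the self-report of having slept tracks the actual trajectory exactly
  to the degree the coupling allows, and is independent of it at
  `c = 0` so that null-calibration studies are honest;
* BMI/BDI-II are drawn within the subject's group stratum, so group
  labels are recomputable; age and gender distributions differ by group
  as in comparable clinical samples;
* the EEG signal realizes each second's stage characteristic on a
  12-channel 10-20 montage plus one EOG channel at 200 Hz (1 kHz
  supported): region-weighted 10 Hz alpha for A stages, a 100 uV
  half-sine EOG sweep for B1, 2.3 Hz delta + 5.7 Hz theta for B2/3, a
  0.65 s 13 Hz spindle burst (frontally accentuated, occasionally with
  a K-complex template) for C, over 4 uV white background noise.

Default recording length is 1200 s; the default sampling rate is 200 Hz
rather than the 1 kHz of typical acquisition hardware to keep
desk-scale runtimes (1 kHz is selectable, and file readers decimate
with an anti-alias filter).  Cohorts carry per-subject recording seeds
instead of materialized signals (a full default cohort's signals would
occupy ~5 GB); `synthesize_recording` reproduces any subject's EEG
bitwise on demand.

What the generator does *not* emulate: real EEG's 1/f background,
artifacts other than amplitude spikes, within-second stage transitions,
adaptive individual alpha frequencies, and any nonlinearity in the
subjective-objective link.  Passing recovery tests therefore shows the
chain is internally consistent at realistic SNR, not that the staging
thresholds are clinically validated.

## Statistical battery

* Kruskal-Wallis (tie-corrected) for group location differences;
  chi-square contingency tests for categorical descriptives.
* Spearman correlations with a small-sample p-value ladder: exact
  enumeration of all rank permutations for n <= 8 without ties, a
  seeded 9999-replication permutation approximation for n <= 13, the t
  approximation otherwise.
* Correlation differences between independent groups via Fisher's z:
  `(z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))`, two-sided normal p.
* Global association via canonical correlation between the subjective
  block (SSS/KSS/VAS pre, post, deltas, ASLEEP as 1-4 codes) and the
  objective block (proportions 0/A/B/C, MVV, ASS).  Columns are
  standardized; because the change scores are exact linear combinations
  of pre and post, each block is reduced to its effective column space
  by rank-revealing QR before the singular-value step (constant columns
  are an error naming the block).  The Pillai-Bartlett trace (sum of
  squared canonical correlations) is tested against a resampling null:
  rows of one block are permuted, preserving within-block structure
  while breaking the between-block link; p uses the add-one rule over
  9999 replications by default.  This avoids the Gaussianity the
  closed-form trace test would assume.
* For metric outcomes (VAS, ESS): OLS of the outcome on age, gender,
  SSQ, depression, obesity, an objective measure (MVV or ASS), all
  two-way interactions among {depression, obesity, objective} and the
  three-way term, with type-II (marginality-respecting) ANOVA F-tests
  per term.  Rank-deficient designs raise an error listing the aliased
  columns.
* For ordinal outcomes (KSS, SSS, ASLEEP): proportional-odds cumulative
  logit models with shared slopes across thresholds, fitted by maximum
  likelihood (BFGS); each interaction term is tested by a
  likelihood-ratio chi-square against the model without it, excluding
  higher-order terms containing it from both models.  Non-convergence
  raises an explicit fit failure (possible separation) rather than
  returning numbers.  The predictor-free model's thresholds equal the
  logits of cumulative frequencies, which is used as a closed-form
  check.
* Wilcoxon rank-sum with exact enumeration for tie-free combined
  n <= 20, the tie-corrected normal approximation otherwise.

P-values are reported without multiplicity correction, which the
report's manifest flags; a correcting consumer can apply any procedure
to the machine-readable tables.  Complete-case analysis throughout.

## Problem sizes in the test suite

The validation suite runs the battery at sizes chosen to make
Monte-Carlo error small relative to each assertion: null calibration of
the CCA bootstrap uses 200 simulated cohorts of n = 100 at 499
replications (Kolmogorov-Smirnov uniformity at the 1% level);
interaction F and LR sizes use 500 replicates at n = 400 (acceptance
band 0.05 +- 0.02, i.e. +- 2 Monte-Carlo SE); proportional-odds slope
recovery uses 200 replicates at n = 500 (slope within +-0.2 in >= 90%);
the correlation-difference size uses 1000 replicates at n = 60 per
group.  Staging recovery runs one full-length (1200 s) recording at
default SNR plus a five-point slow-wave amplitude ladder on 300 s
recordings; the ASS cascade is checked exhaustively against an
independent rule table on all 7^4 sequences of four five-minute blocks.

## Known limitations

The staging thresholds are package-defined operationalizations, not a
reproduction of any clinical tool's internals; results on real EEG
depend on preprocessing not modeled here (reference scheme, filtering,
ocular artifact correction).  The ASS's sub-threshold-B combination and
post-minute-15 emergences are flagged because the published rule table
does not define them.  The generator's group shifts are point choices
on a latent scale, not fits to any dataset.  EDF files are read (via
the optional `mne` dependency) but not written; the delimited signal
table is the round-trip format.
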