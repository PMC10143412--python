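# Methods

This note records the models, conventions and design choices behind
`bpfusion`, in the order the pipeline runs. Throughout, sample indices
are 0-based and the time of index *i* is *i/fs* seconds; the nominal
sampling rate is 125 Hz.

## Signal model and preprocessing

ECG denoising follows the standard zero-phase chain: subtract the
mean, 4th-order Butterworth low-pass at 35 Hz (high-frequency noise;
the 35 Hz corner also subsumes 50/60 Hz mains, so no notch filter is
used), then 2nd-order Butterworth high-pass at 0.9 Hz (baseline
wander). PPG is mean-subtracted and low-passed at 10 Hz (order 4,
chosen for symmetry with the ECG low-pass, which is otherwise
unconstrained), then detrended by subtracting a natural cubic spline
through the detected pulse-onset (valley) samples — valleys track the
baseline by construction, which is why they serve as knots; a first
coarse valley pass supplies the anchors before final delineation. All
filters are applied forward-backward (`sosfiltfilt` with odd signal
extension), so the stated orders are one-pass design orders and the
effective attenuation is squared; zero phase matters because every
downstream feature is a landmark *time*. With fewer than 4 spline
anchors a linear trend is subtracted instead (a natural cubic spline
is underdetermined below 4 knots) and a warning is logged. Natural end
conditions leave a small boundary-layer residual when the true
baseline has curvature at the record edges; this is accepted in
exchange for not inventing end slopes.

## Fiducial delineation

R peaks come from Pan-Tompkins: five-point derivative, squaring,
150 ms moving-window integration, adaptive dual thresholds with a
200 ms refractory period and search-back at half threshold, and
refinement of each decision to the local ECG maximum within half an
integration window plus 25 ms (an upright R, as in lead II, is
assumed). PPG systolic peaks use a double-threshold scheme: candidates
are local maxima above an adaptive amplitude threshold (0.5 of the
rolling 5-s max–min range above the rolling minimum), and among
candidates closer than 0.4 s the larger survives. These two defaults
cover 40–180 bpm and are exposed in the function signature.

The pulse foot (valley) is found by searching *backward in time* from
each peak over 0.4 peak intervals for the first-difference zero
crossing from negative to positive nearest the peak, falling back to
the window minimum when no sign change exists (monotone ascent). The
maximum-slope point is the argmax of the first difference on
[valley, peak), earliest index on ties — the tie-break convention used
everywhere. The dicrotic landmark is the largest interior local
maximum of the descending branch, else the first negative-to-positive
zero crossing of the second difference (the descending inflection),
else absent — absence is a valid outcome and simply leaves the
peak-to-peak time (PPT) missing for that beat.

Beats are paired by matching each R peak to the earliest PPG valley
within 0.6 s; beats with another R before the matched valley, or a
PAT outside the physiological [0.05, 0.6] s band, are rejected and
counted. SBP/DBP labels from an arterial channel are the mean (median
via option) of per-beat systolic peaks and diastolic valleys found
with the same double-threshold scheme; a pulse pressure below
10 mmHg is rejected as unusable.

## Features

Twenty-five features per record: Gender, Age, Weight, and 22 waveform
features (see the table order in `bpfusion.features.FEATURE_NAMES`).
Per-beat definitions: PATx = (landmark − R)/fs for the peak, valley
and max-slope landmarks; HR = 60·fs/RR; PP, AT, DT, PPT from landmark
differences; PIR_x = PI_x/PI_v; PIavg/PIsd/PImax/PImin over the cycle
[valley_i, valley_{i+1}); K = (P_m − PI_v)/(PI_p − PI_v) with P_m the
discrete mean of the cycle (rectangle rule — the simplest consistent
discretization at 125 Hz, also used for the branch sums); slopes
AS/DS as positive magnitudes (rise or fall per second); branch sums
and averages SA/AA/SD/AD and the ratio SR = SA/SD.

Intensities are computed on a positively offset copy of the filtered
PPG: after mean subtraction the valley value can be ≤ 0, which would
break PIR and K. The record minimum is mapped to a floor of 0.25× the
record's peak-to-peak range. A *range-proportional* floor (rather
than a fixed additive constant) keeps every intensity ratio invariant
to amplitude scaling — the natural requirement, since PPG amplitude
units are arbitrary — while K is affine-invariant by construction.
PIsd uses the population (1/n) convention, matching the evaluation
formulas. DS uses the *next* beat's valley, consistent with DT being
the time from peak to next valley.

The record-level feature is the mean over beats carrying the feature
(median via option); a feature absent in every beat stays missing and
is never zero-filled. Records with fewer than 2 valid beats are
rejected. Gender is encoded male=1 / female=0 (an explicit,
overridable convention); missing weight propagates as NaN.

## Gaussian-copula MI and backward elimination

Each column is rank-transformed (average ranks on ties) and mapped
through Φ⁻¹(r/(n+1)), making the estimator invariant to any strictly
monotone marginal transform. The MI of the normalized blocks is
½·log2(|Σ_X||Σ_Y|/|Σ_XY|) bits with 1/(n−1) covariances, clipped
below at 0; a singular joint covariance receives a 1e-10 diagonal
ridge with a warning. No small-sample bias correction is applied in
the selection path (a corrected variant exists for diagnostics only).

Selection: features whose univariate MI with the target is ≤
`zero_tol` are dropped first; then the feature whose removal loses
the least group MI is eliminated repeatedly until the minimum loss
exceeds 0.002 bits, keeping the set before that removal. The
trajectory shows the expected shape: a plateau while redundant
features leave at ~no cost, then decay once unique information is
lost. The target is copula-normalized too (symmetric treatment,
disableable), and a `keep_k` override reproduces fixed-size subsets.

Two numerical facts matter at small n, and both are documented
because they shaped the experiment designs below. First, the plug-in
estimator's univariate null distribution is 2n·ln2·Î ~ χ²(1), so
"zero MI" must be read against the null quantile at the cohort's n
(`null_mi_threshold`); the default `zero_tol = 1e-3` bits corresponds
to the bias floor at n ≈ 900. Second, the group-MI estimate carries a
per-dimension bias of roughly 1/(2n·ln2) bits, so leave-one-out
losses are understated by about that much per step; at n ≈ 900 this
is well below the 0.002-bit stop rule, but at n ≈ 100–300 it makes
the rule over-prune. The 0.002-bit threshold is therefore treated as
calibrated for cohorts near a thousand records.

## Regression and calibration

`BPRandomForest` wraps a 100-tree forest, max depth 50,
`min_samples_split=2`, `min_samples_leaf=1`, bootstrap aggregation,
prediction = mean over trees; no hyperparameter search. Inputs are
name-keyed: column order is irrelevant and a name mismatch is a
schema error. `max_features` defaults to 1.0 (every feature scanned
at every split) and is exposed because per-split feature subsampling
is the other canonical forest ingredient; the selection experiment
below relies on it. A missing PPT among selected features is imputed
with the training-set mean (dropping a record for one optional
feature wastes data); records missing any other selected feature are
dropped with a logged count.

Calibration personalizes a population model with a small labeled
sample from the test subjects. The quarter split is per-subject:
⌈0.25·k⌉ of each subject's k test records go to calibration
(deterministic under seed; single-record subjects stay in
evaluation), so every test subject contributes personal data. Two
strategies: *augment-retrain* (default) refits the forest on training
plus calibration records, the latter weighted 5× so a handful of
personal records can bend the model; *offset* adds the mean
calibration residual to predictions. "Fine-tuning" is not natively
defined for forests, so both interpretations ship and the applied
strategy is recorded in the model's training summary.

## Evaluation

MAE is the mean absolute error. STD is the standard deviation of the
signed errors about their mean (population 1/N) — the BP-validation
convention that makes "MAE ± STD" describe the error distribution; a
literal variant (SD of the reference pressures) exists behind
`std_mode="reference"` for audit. Cumulative proportions of |error|
at 5/10/15 mmHg feed BHS grading (A: 60/85/95, B: 50/75/90,
C: 40/65/85, all inclusive; below C is reported as D). Bland-Altman
reports mean difference and mean ± 1.96·SD limits.

## Synthetic data

`generate_record` builds 30-s, 125-Hz records. ECG: three Gaussian
waves (P, QRS, T) per beat at jittered beat times. PPG: per beat, a
raised-cosine systolic upstroke starting exactly at the onset (R time
plus the true PAT), an exponential diastolic decay (τ = 0.18 s), and
a delayed dicrotic Gaussian (25% amplitude, 0.25 s after the apex).
The raised-cosine ascent gives the pulse a sharp foot at the onset,
so the waveform's measured foot-PAT equals the configured value —
with purely Gaussian pulses the inter-beat minimum floats freely and
"true PAT" would be ill-defined. Sinusoidal drift (0.3 Hz) and white
noise (absolute SD or target SNR in dB) are added per channel; an
optional ABP channel is a monotone remap of the clean pulse to
[DBP, SBP] — crude, but sufficient to exercise label extraction (its
diastolic tail does not fully settle, so extracted DBP sits ~1 mmHg
above the nominal floor). Ground truth (every landmark to sample
precision) is measured numerically on the clean waveforms.

Cohorts draw per-subject latents (age 20–40 uniform, mirroring a
young screening cohort; weight N(65, 12²) kg; subject-level PAT and
HR with between/within-subject spread) and labels from
SBP = 40 + 15/PAT + 0.2·HR + 0.5·Age + subject offset + ε,
DBP = 20 + 9/PAT + 0.1·HR + 0.3·Age + offset + ε, with offset SD
5 mmHg and ε SD 3 mmHg by default; pulse pressure is floored at
20 mmHg. The inverse-PAT term encodes the physiological direction
(shorter transit ⇒ higher pressure) with a nonlinearity a forest can
exploit but a linear baseline cannot. `generate_feature_cohort` draws
the same latents but emits the 25-feature table directly — timing
features from the latents plus measurement noise of about half a
sample, morphology/intensity features at plausible scales but
unrelated to the targets, plus optional iid-normal distractor columns
— which keeps multi-seed model-level experiments fast while the
waveform path is exercised end to end elsewhere.

What the generator does *not* emulate: real PPG morphology classes
(ageing, arrhythmia, motion artifact), sensor saturation, and the
dataset shift between a public training corpus and a self-collected
device. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not clinical performance.

## Experiment designs

Two direction-of-effect experiments back the pipeline's headline
claims; their settings are package defaults in
`bpfusion.experiments`.

*Selection benefit.* 15 training subjects × 6 records (90 records —
the scale of a self-collected validation set) with 150 iid-normal
distractor columns on top of the 25 features; 60 disjoint test
subjects for a sharp paired comparison; both forests use
`max_features="sqrt"`; the prefilter uses the χ² null quantile at
n = 90. The subsampling forest is essential to the phenomenon under
study: when split candidates are drawn at random, irrelevant columns
are forced into splits and degrade the ensemble, and removing them
helps. A forest that scans every feature at every split is largely
insensitive to independent distractors (verified across cohort sizes
from 90 to 900 records), so the comparison is uninformative in that
configuration. Under the frozen design the selected forest wins in
roughly 16–19 of 20 seeds with a mean held-out MAE gain near 1 mmHg.

*Calibration benefit.* 40 training subjects; 15 test subjects × 8
records with per-subject pressure offsets of SD 10 mmHg; quarter
split; augment-retrain with weight 5. Personal offsets are exactly
what the population model cannot know, and the forest can key
calibration records to a subject through the individual features, so
calibration reduces held-out MAE in essentially every seed (20/20 in
development runs, mean gain ≈ 3 mmHg).

## Problem sizes

Defaults throughout are chosen so the full test suite and the
acceptance script each run in well under a minute on one CPU: 30-s
records at 125 Hz (≈ 37 beats), 90–480-record cohorts for model-level
experiments, n = 2000–5000 for estimator checks, and 20–50 seeds for
stochastic properties. These sizes are stated here as the package's
own study conditions.

## Known limitations

- The Pan-Tompkins refinement assumes upright R waves; inverted-lead
  records would need a polarity option.
- The WFDB reader covers single-segment, single-file records in
  formats 16/80/212 — the layout of MIMIC-III waveform exports — not
  multi-segment or multi-frequency records.
- The 0.002-bit stop rule inherits the estimator's dimension bias at
  small n (see above); cohorts far below ~900 records should pass an
  n-aware `zero_tol` and read selected-set sizes cautiously.
- ABP synthesis is a shape remap, not a hemodynamic model; it is only
  meant to exercise label extraction.
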