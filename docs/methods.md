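# Methods

This note documents the model and procedure implemented by `wristahi`, the
parameter defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical conventions a user relying on
the outputs should know.

## Signal model and pulse analysis

The wrist rPPG (nominally 32 Hz) is treated as a train of cardiac pulses
whose timing carries heart-rate variability and whose amplitude is modulated
by respiration. All time is measured in seconds from the recording start;
scoring uses half-open 30-s epochs `[30k, 30(k+1))`, with a trailing partial
epoch discarded.

**Segmentation.** The signal is band-passed to 0.4–8 Hz (2nd-order
Butterworth, zero-phase). Peaks are found with a 0.3-s refractory distance
and a prominence threshold of 0.3 × the 90th percentile of the absolute
band-passed signal — amplitude-adaptive, so a flat or near-flat signal yields
no pulses rather than noise-triggered detections. Each pulse foot is the
trough preceding its peak; the pulse time is the foot time and the amplitude
is peak minus foot. On clean synthetic trains the mean absolute timing error
is below one sample period.

**Quality index.** Each pulse, resampled foot-to-foot to 50 points and
linearly detrended, is compared to the point-wise median of the pulses in
its non-overlapping one-hour block (anchored at the recording start; a
recording shorter than one hour forms a single block). The index is the
Pearson correlation with the block template, negatives clipped to zero — so
it is invariant to global amplitude scaling. Blocks with fewer than 30
pulses give their pulses index 0: with no meaningful template, the honest
statement is "quality unknown", which downstream behaves as unusable.

**IBIs.** Inter-beat intervals form only between consecutive pulses that
both reach the quality threshold (default 0.6) and whose gap lies in the
physiological band 0.3–2.0 s. The ectopic rule then rejects *both* members of
any contiguous pair (sharing a pulse) whose ratio exceeds 1.5 in either
direction, since ectopy produces both short–long and long–short patterns.
Contiguity matters: two surviving IBIs separated by a rejected one never
share a pulse and are not compared, which makes the filter idempotent.
Abutting same-type respiratory events are likewise merged before epoch
labelling — without the merge, splitting one event into two abutting halves
would invent an interior "event end" and spuriously trigger the post-event
rule.

**Respiratory surrogate.** Amplitudes of good-quality, non-ectopic pulses
are interpolated to 4 Hz, band-limited to 0.1–0.5 Hz (the adult respiratory
range), and cut into breaths at upward zero crossings. A cycle counts as a
breath only if (i) its span stays within 5 s of a contributing pulse, (ii)
its length lies in [2 s, 20 s], and (iii) its peak-to-trough excursion clears
both 10 % of the median pulse amplitude (beat-sampling jitter produces ~2 %
spurious amplitude variation) and 25 % of the median cycle excursion (which
rejects filter ringing inside apnoeic or signal-loss gaps). The absolute
floor means genuinely very shallow amplitude modulation (< 10 % of the pulse
height) is not scored as breathing; for wrist rPPG this is the right side of
the trade-off, since such modulation is indistinguishable from jitter.

## Epoch features

Features are computed over feature-specific windows centred on each epoch's
centre; a window that leaves the recording makes the feature undefined for
that epoch. An HRV feature is undefined when accepted IBIs cover less than
half its window; a respiratory feature when fewer than three breaths fall in
its window. The default registry covers: IBI time statistics (mean, SDNN,
RMSSD, pNN50; 300-s windows with 30-s short variants), spectral powers from
a 4-Hz resampled tachogram (VLF/LF/HF/total/LF:HF and peak frequency at
300 s; LF/HF/ratio at 120 s without VLF, whose period does not fit a 2-min
window), detrended fluctuation exponents α1/α2 (360 s), sample entropy
(m = 2, r = 0.2 σ; 300 s and 30 s), breath amplitude statistics (150 s),
breath length statistics, dominant respiratory frequency and surrogate
variance (30 s), and per-epoch accelerometer activity counts (band-passed
dynamic magnitude, rectified and integrated). Further families (visibility
graphs, multi-scale entropy, phase coordination, high-frequency pole
analysis) have registry slots but no default implementation; the registry is
the extension point.

Sleep-stage probabilities (W, N1/N2, N3, REM) come from a pluggable stager;
the reference implementation is a multinomial logistic regression on a
declared subset (30-s mean IBI, SDNN, RMSSD, 120-s LF:HF, activity counts).
It is a stand-in adequate for sleep/wake separation when wake shows movement
and faster heart rate; any model exposing `predict_proba` over epochs can be
substituted. Epochs whose entire subset is undefined get uniform
probabilities. The percentage of undefined features per epoch ("coverage")
is itself a feature, and epochs with coverage > 80 % get weight 0: excluded
from the training loss and from the AHI count.

**Normalization.** Per feature, a Tukey-ladder exponent is selected from
{−2, −1, −½, 0 (log), ½, 1, 2} by minimising the absolute skewness of the
transformed *defined training* values (ties resolve toward the identity),
followed by a z-score with the post-transform mean and sample SD (ddof = 1).
For non-identity exponents values are clamped to the smallest positive
training value before the power/log; out-of-domain values at apply time are
clamped to that edge with a logged warning. Constant or nearly-empty
features are excluded and stay excluded at apply time. Undefined entries are
set to exactly 0 after normalization and never enter any fit — hold-out data
cannot influence the parameters.

**Truncation.** Leading and trailing runs of ≥ 4 consecutive epochs with
activity counts above the recording's 90th percentile are trimmed (their
epochs get weight 0); interior movement is untouched. This isolates the
portion where the wearer plausibly intended to sleep without touching the
epoch grid alignment.

## Sequence classifier

The RE-epoch detector is a dilated temporal convolutional network
implemented directly in NumPy (forward, backprop, Adam): Gaussian input
noise (train only, σ = 0.05), a kernel-5 convolution to 16 filters, two
stacked kernel-5 convolutions with dilation 2, dropout 0.1, and a per-epoch
16-unit dense head with a sigmoid output. At this problem size (tens of
nights × hundreds of epochs × ~30 features) explicit NumPy is faster to
audit than a GPU framework and keeps the masking semantics under direct
test: hidden activations are multiplied by the real-epoch mask after every
layer, so padded positions are exactly zero everywhere and the probabilities
of real epochs are bit-identical for any padding length. The loss is
weighted binary cross-entropy; padded and zero-weight epochs carry weight 0
and provably contribute nothing (flipping their labels leaves the loss
trajectory and the learned parameters bit-identical). Training is
full-batch Adam (lr 0.01, ≤ 150 iterations) with early stopping on the
validation loss (patience 15) and best-parameter restoration; all
randomness derives from one config seed, so runs are reproducible.

The probability threshold is selected on training recordings by a 0.01-step
grid search, by default maximising the linearly weighted κ between reference
and estimated OSA severity (ties to the lowest threshold); an F1 mode
maximises mean per-recording epoch F1 instead. Severity-based selection
deliberately trades epoch sensitivity for correct severity classification —
the clinically relevant output.

## AHI estimation

`AHI = c · P / TST[h]`, where `P` counts epochs that are asleep (stage
argmax ≠ W), have weight 1, and exceed the threshold; `TST = 0.5 min ×`
(number of sleep epochs). Recordings with under 30 min of estimated sleep
are rejected. The correction coefficient `c` is the through-origin
least-squares slope of reference AHI on the epoch-based AHI computed from
*reference* labels over training recordings — through the origin because the
correction is multiplicative by construction (zero positive epochs must map
to zero AHI); a with-intercept variant exists for sensitivity analysis. The
regression direction (reference on raw) was chosen so that applying `c` to a
raw epoch rate yields an unbiased event rate on the training set.

Recording-level quality gating uses six metrics, each computed per epoch and
averaged over the night: accepted-IBI coverage (%), mean/median/25th/75th
percentile pulse quality, and the percentage of pulses with quality > 0.6.
Thresholds are the 10th percentile of training recordings' means (linear
interpolation between closest ranks); failing any single metric fails the
recording. The constants shipped in `REFERENCE_QUALITY_THRESHOLDS` are the
published minimums for a clinically trained system and are reference values,
not claims about synthetic data.

## Evaluation conventions

The AHI estimation error is *reference minus estimated* everywhere.
Correlation uses Spearman's ρ (the estimate's variability grows with the
reference — heteroscedasticity is checked with a Breusch–Pagan test and
reported, never used for gating). ICC(2,1) (two-way random effects, absolute
agreement, single rater) is computed from the ANOVA mean squares with the
F-distribution confidence interval; Bland–Altman limits are bias ± 1.96 ×
sample SD of the differences. Cohen's κ comes with its marginal-constrained
maximum (for weighted κ the maximum is found exactly by a small
transportation LP; the binary case reduces to the sum-of-minimum-marginals
closed form) plus prevalence and bias indexes. "Considerable" over- and
under-estimation use piecewise-linear bounds in the reference AHI (e.g.
overestimation when est > 2·AHI + 5 below 15 events/h); a reference below 5
can only be over-flagged. Error attribution uses an elastic net on z-scored
recording characteristics with penalty and L1/L2 mix chosen by 5-fold CV.

## Synthetic generator

The generator emulates the statistical structure the estimator relies on: a
per-epoch hypnogram from a stage-transition chain (~80–85 % sleep
efficiency); stage-dependent mean IBI (0.78 s in wake to 0.98 s in N3) with
slow autonomic drift, beat jitter (10 ms) and respiratory sinus modulation
(30 ms) at a per-recording breathing rate drawn from 0.2–0.3 Hz;
pulse-amplitude respiratory modulation of depth 25 %; respiratory events
placed only during sleep (durations 10–60 s, ≥ 10 s gaps, hypopnea-dominant
mix 84/8/4/4 % reflecting the clinical predominance of hypopneas), each
imposing a 30 % reduction of the amplitude-modulation depth during the event
and a 15 % IBI shortening for 10 s after it — the event-locked signature the
classifier must learn; limb movements and wake add accelerometer bursts;
artefact intervals replace the waveform with noise, degrading the quality
index. The true AHI equals the number of generated events divided by the
true total sleep time, and the ground-truth epoch labels use the same
RE-epoch rule as the labeller.

It does **not** emulate raw-PPG optics, realistic motion spectra, arrhythmia
morphology, oximetry, or obstruction mechanics (central/mixed/obstructive
events share one waveform signature and differ only in annotation type).
Passing tests on synthetic cohorts therefore demonstrates that the pipeline
recovers the AHI when the assumed cardiorespiratory signatures are present
at the configured strength — not clinical performance, which depends on how
strongly real physiology expresses those signatures and on confounders the
generator does not model (arrhythmias, medication, comorbid sleep
disorders).

## Problem sizes and numerical choices

The shipped end-to-end study uses 40 nights of 2 h at 32 Hz with a 28/12
train/validation split — large enough to span all four severity classes and
to fit the correction and threshold stably, while keeping a full run in the
minutes range on one CPU; night length and cohort size are flags on
`scripts/acceptance.py`. Percentiles use linear interpolation between
closest ranks (NumPy default). Standard deviations are sample SDs
(ddof = 1). Epoch-rule boundaries are ≥ 10 s (inclusive) and < 5 s (strict),
evaluated with a 1 ns tolerance against floating-point representation error;
the zero-weight rule is strict (> 80 %). Severity ties go to the higher
class at exact cut-offs (5 → mild, 15 → moderate, 30 → severe). The
threshold grid tie-break picks the lowest threshold.

## Known limitations

- The reference sleep stager is deliberately simple; its TST is reliable
  when wake is accompanied by movement, which real insomnia may violate.
- Sample entropy on 30-s windows (~35 IBIs) is frequently undefined; it is
  kept because the undefined-rate itself is informative through coverage.
- The ectopic filter's pairwise rule can discard runs of valid beats around
  isolated ectopy; this is intentional conservatism inherited from the
  method's design.
- The EDF codec writes classic EDF (16-bit, 1-s records, integer sampling
  rates); EDF+ annotations and vendor dialects are out of scope.
- Correction coefficient and probability threshold are population-level
  fits; transferring them to a cohort with different event-duration
  statistics requires refitting.
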