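# Methods

This note documents the models, parameter choices and numerical
conventions behind `seatecg`, and what the synthetic benchmark does and
does not demonstrate about real seat-acquired thigh ECG.

## Synthetic session model

**Beat morphology.** Each heartbeat is a sum of five Gaussian bumps — P,
Q, R, S, T — parameterised by amplitude (relative to R = 1), latency from
the R peak (s) and width (s). The canonical beat uses normal adult
timings (PR ≈ 0.16 s, QT ≈ 0.36 s at rest); a subject is a draw of
per-wave multiplicative amplitude/width jitter (±15–50% depending on the
wave) and additive latency jitter (up to ±40 ms) around that canonical
beat, together with a mean heart rate in 55–95 BPM and a heart-rate sd of
1–5 BPM. Draws are redrawn until all pairwise template correlations in a
cohort are below 0.999, so no two subjects are morphological twins. This
Gaussian-bump simplification reproduces what the downstream analyses
consume — a repeating subject-specific waveform with a dominant R wave —
but it is not an electrophysiological model: it has no respiratory
modulation of morphology, no volume-conductor projection, and no
pathology-specific shapes.

**Rhythm.** RR intervals are i.i.d. Gaussian with mean 60/HR and an sd
obtained from the heart-rate sd by the delta method
(`sd_RR = 60·sd_HR/HR²`), floored at 0.3 s. This gives directly
controllable time-domain HRV (a programmed 50 ms RR spread is recovered
as SDNN within 20%) but, being white, it has no realistic NN spectrum —
spectral HRV quantities on synthetic data are placeholders, not
physiology.

**Thigh-channel degradation.** The EXP channel is
`gain·REF + white noise + baseline wander + powerline`, hard-clipped to
the recorder full scale (±1 a.u.), pinned to the rail inside saturation
episodes and before the usable onset. The subject's `sex_hair_factor`
(0–1) scales the noise floor by up to 3×, emulating degraded dry-electrode
contact through body hair; it deliberately does not touch the attenuation
gain, so zero degradation leaves EXP an exact scaled copy of REF. The
default *typical* profile (gain 0.4, noise sd 0.06 a.u., 0.1 a.u. wander
at 0.25 Hz, 0.03 a.u. mains pickup, two saturation episodes totalling
25 s, 2 s onset delay) was calibrated so a 5-minute session lands at the
operating point reported for seat-acquired thigh ECG: QRS ratio around
75–85%, roughly 15% excluded signal, heart-rate deviations of a few BPM,
and valid-template counts of order 10².

**Sampling.** The generator defaults to 1000 Hz (no device rate is
published for this class of hardware); the test-suite and acceptance
benchmarks run sessions at 250 Hz / 5 min — templates of 151 samples —
which keeps classifier training and 30-repetition sweeps desk-scale
without changing any conclusion drawn from them.

## Preprocessing

The band-pass is a windowed-sinc (Hamming) FIR of order 300 with a
3–45 Hz passband; the output is shifted by order/2 samples so R-peak
locations live on the input time axis. At ECG sampling rates the Hamming
transition band (~3.3·fs/301) is wide relative to a 3 Hz edge and leaves
~−13 dB of residual DC gain, so the taps' mean is subtracted to place an
exact null at DC; the mid-band response is unaffected (25 Hz passes
within 0.1%) and a 0.5 Hz drift component is attenuated by >40 dB.

The R-peak detector follows Hamilton's design: absolute first difference,
80 ms moving-window integration, candidate local maxima classified
against an adaptive threshold `noise + 0.3125·(signal − noise)` where
signal/noise levels are medians of the last 8 peaks of each class; a
200 ms refractory period; T-wave discrimination (candidates within 360 ms
of the last beat are rejected if their maximal slope is below half the
previous beat's); and search-back at 1.66× the running median RR with the
same slope test. Two start-up/robustness details matter in practice and
are part of this implementation: the threshold bootstraps from the
tallest integrated peak of the first two seconds (otherwise an early
P wave can seed the beat history and drag the running RR estimate into
perpetual false search-back), and a candidate at least 1.5× taller than
an acceptance inside its refractory window supersedes it (otherwise a
P wave accepted ~0.2 s before the true R blocks it). Fiducials are
refined to the filtered-signal maximum within −75/+25 ms. On clean
synthetic sessions across 250–1000 Hz the detector scores ≥99%
sensitivity and PPV against ground truth.

Out-of-range detection reports maximal runs of samples at or beyond the
recorder limits lasting ≥0.1 s (single clipped samples are not
saturation). Channel clock alignment is the mean pairwise difference of
the optical sync events (seat LED vs reference LUX sensor).

## Quality statistics

Beats are matched one-to-one between channels greedily by time proximity
within 150 ms. QRS ratio is matched/REF·100. Heart-rate deviation and
the Welch t-test both use instantaneous rates (60/NN) over beat pairs
that are consecutive in *both* channels — the only pairs where 60/NN is
simultaneously a heart rate on each side; comparing raw per-channel NN
series instead lets spurious detections on noisy stretches dominate. The
signal-detection error counts as excluded both the out-of-range runs and
2 s windows containing no detectable beat, since saturation and noise
corruption are operationally the same loss. TB is the delay from the
first reference beat to the first matched thigh beat (0 for a session
usable from the start). The t-test is the unequal-variance (Welch) form.

## HRV conventions

Sample (n−1) standard deviations throughout. NN20 counts successive
differences strictly greater than 20 ms. SD1 is derived as SDSD/√2 (the
Poincaré identity); `HRVSummary` enforces it for computed summaries and
can carry externally reported rows that quote SD1 independently. The
spectral peak is taken from a Welch periodogram of the NN series linearly
resampled at 4 Hz with 120 s segments. The radar comparison reports
`100·(EXP − REF)/REF` per parameter, flagging (not raising) parameters
whose reference value is zero.

## Morphology

Templates span 0.2 s before to 0.4 s after the R peak — enough to cover
P-QRS-T at normal resting rates. Thigh cycles are extracted at
reference-anchored beats and screened against the mean reference cycle;
the default outlier threshold is a Pearson correlation of 0.8. Where a
fixed per-subject count is needed (identification protocols), the
rank-based `select_best_templates` keeps the n best-correlated cycles in
temporal order instead of applying the hard threshold. NRMSE is
normalised by the reference waveform's range and reported in percent.
Cohort aggregates are the arithmetic mean and sample sd over per-subject
means.

## Identification

All four classifiers consume flattened templates standardized with
train-fitted parameters; the binarized CNN additionally sees its input
quantized per-template to uint8 (min→0, max→255; constant templates map
to 128 by convention) before standardization. The SVM is a linear-kernel
C=1 machine in an explicit one-vs-all arrangement; naive Bayes is
Gaussian; k-NN uses k=3 with scikit-learn's tie handling.

The BCNN architecture is Conv1D(16, k=7) → ReLU → maxpool2 →
Conv1D(32, k=5, binarized) → ReLU → maxpool2 → flatten →
Dense(64, binarized) → ReLU → Dense(classes) → softmax, trained with Adam
(lr 10⁻³, batch 32, default 30 epochs) on cross-entropy. Interior
weights are binarized as `α·sign(W)` with per-filter α = mean|W|, with
the clipped straight-through estimator for gradients; following standard
binary-network practice the first and last layers stay full-precision.
Training is bit-for-bit reproducible given its seed, and each evaluation
repetition retrains from a fresh seeded initialisation.

Protocols: *random* holds out a third of each subject's templates,
re-drawn per repetition; *static* trains on the first 30 and tests on the
last 30/20/15, a fixed temporal split probing morphology drift.
Population sweeps draw a fresh seeded subject subset per repetition, so
metrics average over household composition; accuracy, macro recall and
macro precision are aggregated as mean ± sd over repetitions (30 by
default).

## What the synthetic benchmark shows — and what it does not

Passing tests demonstrate that the analysis chain is correct and
internally consistent: exact statistics against brute-force oracles,
lossless behaviour on clean sessions, graceful and monotone degradation
with noise, chance-level accuracy for morphological twins, and declining
identification accuracy with population size. They do *not* demonstrate
performance on real thigh recordings: synthetic subjects differ by
construction in stationary morphology, with no intra-subject drift,
posture effects, motion artefacts or electrode repositioning — precisely
the factors that make real static-protocol identification harder. The
published cohort aggregates reproduced by the acceptance script (PCC
0.91 ± 0.06; radar percentages) are arithmetic over reported per-subject
values, not a re-analysis of raw recordings, which were never deposited.

## Benchmark problem sizes

The acceptance script uses 10 clean and 8 typically-degraded 5-minute
sessions at 250 Hz, 90 templates per subject, a 4-subject clean cohort
for the classifier comparison (3 repetitions; 1 for the BCNN) and a
17-subject degraded cohort for the population-sweep end points (30
repetitions).
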