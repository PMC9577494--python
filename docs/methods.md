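# Methods

`emofuse` implements an end-to-end pipeline for binary arousal/valence
recognition from three peripheral physiological channels — electrocardiography
(ECG), electrodermal activity (EDA) and respiration (RSP) — together with a
synthetic-data generator that stands in for a laboratory dataset of
video-elicited emotion trials with 1–9 self-report scores. This note records
the models, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Synthetic trial generator

Each trial consists of three synchronously started channels (defaults: ECG
250 Hz, EDA 25 Hz, RSP 25 Hz — configurable), a trial duration of 34–201 s
(default 60 s), and integer arousal/valence scores. Every subject additionally
contributes one 60-s neutral baseline recording used for per-subject feature
compensation.

**ECG.** A template PQRST beat (sum of five Gaussians, unit R wave in mV) is
placed at R-times generated from a stochastic RR process: a white component
plus an AR(1) component (coefficient 0.9), with the two variance scales solved
so the series hits the requested SDNN and RMSSD. For a stationary process
RMSSD ≤ 2·SDNN; requested pairs outside the AR(1)-reachable cone are clipped
to the nearest attainable correlation, and pairs beyond 2·√2·SDNN are rejected
as infeasible. Baseline wander is a 0.15 Hz sinusoid; measurement noise is
white Gaussian. True R-times are returned exactly — ground truth is the test
surface, which is why template superposition was chosen over a dynamical ECG
model.

**EDA.** Tonic level with a slow (per-record) sinusoidal drift, plus Poisson
skin-conductance responses (SCRs): each event convolves a unit driver with a
two-exponential Bateman kernel, `exp(-t/2.0) − exp(-t/0.75)` seconds, whose
peak is below the driver amplitude.

**RSP.** Trough-to-trough cosine arcs with per-cycle period and amplitude
jitter; the cycle boundaries are the ground truth.

**Emotion encoding.** Score effects are linear in (score − 5), scaled by the
`arousal_effect` / `valence_effect` multipliers. At effect 1, each arousal
point adds 5 bpm of heart rate, 0.3 µS of tonic level, 1.5 SCR/min and
1.2 breaths/min, and shrinks SDNN/RMSSD by 6%; valence tilts the RMSSD/SDNN
balance and breathing regularity. These slopes are generator design choices in
the physiologically plausible range — the underlying study reports that such
modulation exists but never quantifies it, so effect sizes are free simulator
parameters, not empirical claims. Subject-level offsets are additive Gaussians
(HR sd 5 bpm, tonic sd 0.4 µS, SCR rate sd 0.8/min, breath rate sd 1/min)
drawn once per subject from the dataset seed. Scores are uniform on 1–9, so
the mid-scale binarization (score ≤ 5 → low) produces the 5:4 class imbalance
that motivates the balanced-subset protocol.

Everything is a pure function of `(SimulationConfig, seed)`: the on-disk
dataset (manifest + per-channel CSVs + ground-truth JSON) is reproducible
byte-for-byte.

## Preprocessing

* **ECG filtering**: linear-phase windowed-sinc FIR band-pass, 3–45 Hz,
  default 0.5 s of taps, applied forward-backward (zero phase) so R-peak
  latency is preserved.
* **QRS detection** follows the classic adaptive-envelope recipe:
  differentiate → rectify → 80 ms moving average → adaptive threshold at
  noise + 0.3125·(signal − noise) with running peak estimates (smoothing
  0.125) and a 200 ms refractory period → back-search (−100/+60 ms) for the
  filtered-ECG maximum as the R point. No-peak inputs return an empty series
  with a warning, never an exception.
* **NN intervals**: successive R-R differences in ms; intervals outside
  (250, 3000) ms or deviating more than 30% from the running median of the
  last 11 accepted intervals are rejected. Both rules are configurable
  constants at the top of the module.
* **EDA decomposition** solves a sparse nonnegative deconvolution on a 4 Hz
  working grid: tonic initialised from a smoothed rolling 10th percentile
  (8 s window), the residual fit as Bateman-kernel ⊛ driver with an
  L1-penalised nonnegative least squares (alpha 5e-4) followed by an
  unpenalised nonnegative refit on the support to undo the L1 amplitude
  shrinkage. SCR events are driver local maxima (≥ 0.5 s apart) whose
  conductance deflection exceeds 0.01 µS. This is the same model class as the
  convex-optimisation decomposition common in the field, restricted to a
  regularised least-squares form whose ground-truth recovery we can test; the
  exact quadratic program is out of scope. Optimisation failure falls back to
  a high-/low-pass split with a warning.
* **Breath segmentation**: detrend → 1 Hz low-pass → alternating extrema with
  minimum period 1 s and prominence 0.1·SD, cycles taken trough-to-trough
  (edges padded so boundary troughs are kept).
* **Baseline compensation** subtracts (or divides by) the subject's neutral
  baseline feature vector; subtraction is the default.

Analysis is whole-trial; windowed analysis is available simply by slicing the
input, but no windowing is applied by default.

## The 58-feature vector

47 ECG features (14 time-domain, 4 frequency-domain, 29 non-linear) + 4 EDA +
7 RSP. Conventions for entries whose literature definitions vary:

* TINN uses the 7.8125 ms-bin NN histogram and a least-squares triangular fit
  with the apex pinned at the modal bin; HTI is total count over modal count.
* Frequency features interpolate the tachogram cubically to 4 Hz and
  integrate a Welch periodogram over HF = [0.15, 0.4] Hz, VHF = [0.4, 0.5] Hz;
  HFn normalises by total power in [0.04, 0.5] Hz; LnHF floors the band power
  at 1e-12 ms² before the logarithm. Low-frequency summaries are deliberately
  omitted from the registry.
* Poincaré axes use T = 4·SD1, L = 4·SD2: CSI = L/T, CVI = log10(L·T),
  CSI-modified = L²/T; S is the ellipse area π·SD1·SD2.
* Fragmentation (PIP, IALS, PSS, PAS) works on the signs of successive NN
  differences; alternation segments require length ≥ 4.
* Asymmetry: decelerations are Poincaré points above the identity line. GI,
  SI and AI weight off-diagonal points by distance, angle, and sector area
  respectively; PI is the acceleration percentage. SD1d/SD1a, SD2d/SD2a and
  SDNNd/SDNNa are the standard deceleration/acceleration partitions of SD1,
  SD2 and SDNN, with C1d/C1a, C2d/C2a, Cd/Ca their normalised contributions.
* ApEn/SampEn use m = 2, r = 0.2·SDNN of the analysed series, Chebyshev
  distance; SampEn counts both template lengths over the first N−m windows
  (so a constant-increment ramp scores exactly 0), and degenerate
  zero-variance series return the documented sentinel 0.
* The EDA set is {SCR rate/min, mean SCR amplitude, tonic mean, phasic SD};
  the RSP set is {cycle amplitude mean/max/variance, mean breath rate, cycle
  duration mean/SD, amplitude CV}. Only the counts (4 and 7) are externally
  fixed; the identities are pinned here so the 58-length contract holds.

The registry is closed-world: extraction can only emit these 58 names, and
non-finite values are flagged rather than dropped.

## Evaluation protocol

Labels binarize at the scale midpoint (score ≤ 5 → low; configurable). Because
the classes are unbalanced, five fully balanced subsets are drawn, each
keeping every minority row plus an equal-size majority sample without
replacement. Within each subset a stratified 5-fold cross-validation realises
the 80/20 train/test split; feature standardization and the hyperparameter
grid search (SVM C/γ, forest size/depth, KNN k — small fixed grids) are
fitted on the training 80% only, avoiding the selection-leakage variant of
the protocol. The reported value is the mean over subsets. Random and
majority reference classifiers are included; on any balanced binary test set
the majority classifier scores exactly 50% accuracy and macro F1 = 1/3.
Paired two-sided t-tests compare matched subset-level results, with explicit
zero-variance handling (all-zero differences → p = 1; constant shift →
p = 0).

**Subject-identity leakage.** Trial-level folds let a model score above
chance even on permuted labels by memorising subjects (each subject's trials
share physiological offsets, and any permutation leaves learnable per-subject
label majorities — expected majority fraction ≈ 0.62 for 10 trials/subject).
Both evaluators therefore accept a `groups` argument that switches to
subject-disjoint stratified folds; permutation nulls in the test suite always
use it, while headline accuracies use trial-level folds to mirror the
standard protocol. This distinction matters when interpreting any result
obtained with subject overlap between train and test.

## The multi-input network

Implemented entirely in NumPy (forward and backward passes, Adam, softmax
cross-entropy): 1-D convolutions (im2col, TF-style "same" padding with output
length ⌈L/stride⌉), ReLU, batch normalization (per-channel over batch and
time, ε = 1e-5, running-statistics momentum 0.9, batch ≥ 2 in training),
non-overlapping max-pooling with floor semantics, global average pooling,
dense layers with He initialisation. Gradients are verified against central
finite differences in the test suite.

Each branch is three blocks of [conv → ReLU → BN] × 2 followed by max-pool 2,
then GAP; filters are never shared across branches. The default
parameterization is branch 1 (ECG) 128×32 / 128×32 / 128×16 with per-block
strides (2,2)/(2,1)/(1,1); branch 2 (EDA) 64×16 / 64×16 / 32×4, strides
(2,2)/(3,3)/(1,1); branch 3 (RSP) 128×16 / 64×16 / 64×8, strides
(3,3)/(2,2)/(1,1) — GAP widths 128/32/64, concatenated width 224 — followed
by a 64-unit hidden layer and a 2-way softmax. The slash-separated stride
triplets in the source table are read per input branch; the two bracketed
filter rows per block are read as two conv layers. Both readings are
configurable if a different interpretation is wanted.

Network inputs are the raw channels linearly resampled to each branch's fixed
input length; a branch may restrict itself to the first `window_s` seconds so
fast channels keep their morphology (the reduced desk-scale architecture uses
a 16-s ECG window at 1024 samples). No per-trial standardization is applied —
absolute levels such as tonic skin conductance are informative. The
single-input comparison model is one branch-1-shaped trunk; its multi-modal
variant resamples all channels to that single grid and stacks them as input
channels, so one set of filters, one kernel size and one stride schedule must
serve all modalities — the compromise the multi-input design removes.

Training: Adam (lr 1e-3 generic, 2e-3 at desk scale), batch 8 at desk scale
(small balanced subsets need several updates per epoch), cross-entropy,
optional early stopping on validation accuracy. Desk-scale experiments use a
reduced architecture (8–16 filters per layer, inputs 1024/128/128) with the
same shape algebra; the full default parameterization is used for the
architecture audit and is buildable and trainable but not exercised at scale
in the test suite.

## What the synthetic benchmark shows — and does not

Passing tests establish that the pipeline recovers known ground truth
(R-peaks, SCR events, breath cycles), that the feature definitions satisfy
their algebraic identities, that the learners detect an encoded
arousal signal when it is strong (> 90% balanced accuracy) and stay at chance
under zero effect or subject-disjoint permutation nulls, and that the
directional fusion claims hold on average (fusion features not worse than the
best single modality within 5 points; multi-input ≥ stacked single-input when
channel scales differ strongly). They do not establish performance on real
recordings: the generator's channels are far cleaner than laboratory data
(no motion artifacts, no electrode drift, no ectopy), its emotion encoding is
exactly linear and monotone, and its subject variability is a simple additive
offset. Absolute accuracies on the synthetic benchmark are therefore not
comparable to accuracies on human datasets.

## Problem sizes used by the test suite and acceptance script

Simulated studies run at 10–12 subjects × 8–10 trials of 40–45 s, with 1–2
balanced subsets and 2–3 folds, 8–15 training epochs, and the reduced
architecture; detector checks use 60-s single-channel records. These sizes
are the package's chosen desk-scale defaults: large enough for the
qualitative properties to be stable, small enough to iterate quickly.
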