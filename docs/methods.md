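# Methods

`windeeg` is a fully synthetic, end-to-end testbed for decoding the
momentary pleasantness of wind from EEG. It couples a generator that
emulates a wind-exposure experiment (trial design, self-reports, and
multichannel EEG with a controllable pleasantness effect) to the complete
analysis chain used on such data: preprocessing, distributed source
estimation, band-power feature extraction, a confound-controlled
classification protocol, and group statistics. Because every stage sees
data whose ground truth is known, each scientific claim of the analysis
(chance calibration, confound immunity, signal recovery, exact point
localization) is testable.

## The simulated experiment

A participant completes 3 sessions of 40 trials (120 total). Each trial is
2 s rest, 10 s of wind at one of four velocities (0.44, 1.0, 2.0, 4.0 m/s),
and 6 s for the pleasantness report, i.e. an 18 s trial clock. Velocities
are balanced (30 trials each) and pseudo-randomised with no two consecutive
trials sharing a velocity; the schedule is built by seeded sequential
sampling proportional to remaining counts with restart on dead ends.

Pleasantness reports live on a 1.0–9.0 visual-analog scale in 0.1 steps.
The report for a trial at velocity v is

    score = clip( round_0.1( mu_v + b_i + eps ), 1.0, 9.0 )

with condition means mu_v = (4.3, 5.5, 6.9, 5.3) for the four velocities
(most pleasant at 2 m/s, a non-monotonic profile), participant offset
b_i ~ N(0, 0.5) across a cohort, and trial noise eps ~ N(0, 1.0). The trial
noise default of 1.0 gives each participant a realistic spread of reports
within a condition and, together with the offsets, naturally produces the
occasional participant whose pleasant or unpleasant class is starved — the
situation the protocol's exclusion rules exist for.

## Head model, source space and atlas

The head is a three-shell concentric spherical conductor (brain/skull/scalp
radii 8.7/9.2/10 cm, conductivities 0.33/0.0042/0.33 S/m). The lead field
is the exact series solution of the layered-sphere boundary-value problem:
for each spherical-harmonic degree the radial coefficients solve a 5x5
linear system, and scalp potentials are accumulated as a Legendre series
(80 terms; the homogeneous limit reproduces the textbook (2n+1)/n
coefficient, and boundary-condition residuals are machine-precision —
both are asserted in tests). 64 electrodes are taken from the template
10/10 montage and projected to the scalp sphere.

Each cortical hemisphere is a recursively subdivided octahedron (4^l + 2
vertices at subdivision level l; level 6 gives 4098 per hemisphere)
projected onto a sphere of radius 3.8 cm placed inside the brain shell.
Dipole orientations are the outward mesh normals. A surrogate 68-region
parcellation assigns vertices to the nearest of 34 seed directions per
hemisphere; the three pleasantness regions (rostral anterior cingulate,
medial and lateral orbitofrontal, both hemispheres) and the confound
region (postcentral) are pinned to fixed canonical directions, the
remaining names are placed by a seeded shuffle, and empty regions are
repaired deterministically so all 68 regions are non-empty down to the
66-vertex-per-hemisphere space used in the fast cohort tests.

## Signal model

Per trial the sensor data are the sum of

1. a pleasantness carrier: band-limited Gaussian noise (default alpha,
   8–13 Hz), coherent within each ROI patch with the patch's mean
   lead-field column as its sensor pattern (so the injected amplitude does
   not grow with mesh resolution), amplitude
   `roi_amp * (1 + effect_beta * (score - 5))` (floored at 0);
2. a velocity confound: a band-limited process (default beta, 14–30 Hz) in
   the postcentral region with amplitude `confound_gamma * velocity`;
3. 1/f background at every vertex plus white sensor noise (2 uV).

Amplitudes are in units of the per-vertex background standard deviation,
so `roi_amp = 2` reads "the ROI patch oscillates at twice the background
sigma per vertex". The mean channel RMS is normalised to 10 uV.

The background is sampled directly at the sensors: independent
unit-variance pink sources at all vertices projected through the lead
field form a Gaussian process with spatial covariance L L^T and a 1/f
temporal spectrum, which is reproduced exactly by Cholesky-mixing 64
independent pink-noise series. This is an identical distribution at a
fraction of the cost of materialising thousands of per-vertex series; the
structured sources (ROI carriers, confound) still pass through explicit
lead-field columns.

Defaults (`effect_beta = 0.15`, `roi_amp = 2.0`) produce a strong, clearly
decodable effect — single-participant accuracies around 0.85–0.95 on the
small source space — i.e. a positive control, deliberately stronger than
the modest effect sizes reported for real wind-pleasantness EEG. The
generator is the instrument for verifying the pipeline's discriminative
machinery, not a quantitative model of scalp EEG: it has no ocular or
muscle artifacts by default (the peak-to-peak rejection and regression
stages are exercised by injecting artifacts in tests), no line noise, a
spherical rather than realistic head, and report-period EEG is plain
background. Passing tests therefore demonstrate correctness of the
analysis chain, not expected accuracy on real recordings.
`confound_gamma` defaults to 0.5 (amplitude 2 sigma at the top velocity,
comparable to the pleasantness carrier); the confound-immunity checks use
1.0, twice that, as their "strong" condition.

## Preprocessing

Fixed stage order, asserted by the orchestrator: band-pass filter → epoch
extraction → bad-channel interpolation → artifact-epoch rejection →
(optional ocular regression) → average re-reference → analysis-window
crop.

The band-pass (0.5–45 Hz) applies the squared magnitude response of a
Butterworth cascade (high-pass order 4, low-pass order 10) spectrally on
the reflect-padded recording. This is the zero-phase response of a
forward–backward pass, meets the passband/stopband spec (<1 dB ripple in
1–40 Hz, ≥20 dB at 0.1 and 60 Hz — asserted in tests), and is an order of
magnitude faster on half-hour recordings than sample-domain forward–
backward IIR filtering.

Epochs span −1 to +10 s around wind onset (5632 samples at 512 Hz). Bad
channels are those whose robust z-score (median/MAD across channels) of
log variance exceeds 5; they are rebuilt by spherical-spline interpolation
(spline order m = 4, Legendre series truncated at degree 7), with a
quality error above 20% flagged channels. Epochs with peak-to-peak
amplitude above 150 uV on any channel are flagged rejected — an automatic
surrogate for visual inspection, and a config knob. The optional ocular
stage regresses a synthetic EOG reference out of every channel; it is off
by default because default synthetic data contain no ocular activity. The
analysis window is 2–10 s of wind (the first 2 s are discarded as the
velocity ramp-up); the −1–0 s baseline feeds the noise covariance.

## Inverse solution

Fixed-orientation eLORETA. The baseline covariance is pooled over all
retained trials (pooling across sessions; per-session covariances would
need ~3x more baseline data for the same stability) and shrunk by
lambda = 0.1 toward a scaled identity, which guarantees positive
definiteness with 512-sample baselines. Data and lead field are whitened
by the inverse matrix square root and average-referenced; the weights
iterate

    w_i <- sqrt( l_i^T (L W^-1 L^T + alpha P)^+ l_i )

to a fixed point (tolerance 1e-6, typically ~20 iterations, residual
decreasing monotonically), where P projects onto the rank-(n-1)
average-reference subspace and alpha = trace(L W^-1 L^T) / (n_chan *
alpha_snr^2) with alpha_snr = 3 by default — the usual SNR-based
regularization convention, exposed as a config knob. The kernel
W^-1 L^T M^+ (whitener) applies to baseline-corrected epochs. The
defining eLORETA property — zero localization error for noiseless point
sources at any regularization — is verified by exhaustive sweep.

## Features

Welch PSD per source vertex (1 s Hann windows, 50% overlap → exactly 1 Hz
bins; one-sided density scaling verified via Parseval). The implementation
averages modified periodograms with a vectorised strided-segment FFT and
is asserted equal to `scipy.signal.welch` to float precision; it exists
because the scipy path does not vectorise well over tens of thousands of
short epoch-vertex signals. Vertex powers are averaged (in linear power
units) over each atlas region, then over inclusive integer frequency bins
per band: theta 4–7, alpha 8–13, beta 14–30, gamma 31–45 Hz (bin counts
4/6/17/15). The natural log of the six ROI x four band powers forms the
24-column feature table; the log base only shifts/scales features and is
immaterial under the later z-scoring.

## Classification protocol

Labels: pleasant (score > 5.0) vs unpleasant (score < 5.0); reports of
exactly 5.0 are excluded (the class definitions are strict inequalities
and silent on equality). A participant with fewer than 30 trials in either
class is excluded from group analysis.

Folds leave one velocity out: train on three velocities, test on the
fourth, four folds per participant. A fold is skipped when either class
has fewer than 30 trials in the original training partition. The majority
training class is undersampled to balance; across the five repetitions the
discarded subsets are kept distinct whenever the surplus permits
(bounded retry, falling back to a fresh draw with a warning). Features are
z-scored with the undersampled-training statistics only — test statistics
are never touched, and the train/test velocity disjointness is asserted at
run time.

Hyperparameters are tuned per (repetition, fold, family) by seeded random
search over: C (log-uniform 1e-3..1e3) for logistic regression and both
SVMs, gamma (same range) for the RBF SVM, and hidden units {4..64}, batch
size {8,16,32}, learning rate (1e-4..1e-1), weight decay (1e-6..1e-2) and
epochs {10..200} for the network — evaluated on a stratified 20%
validation split of the undersampled training data, default budget 50
evaluations (5 in the fast cohort tests). Random search stands in for a
Bayesian sampler behind the same interface; tuning is re-done per
repetition. Logistic regression uses the L2 penalty; SVMs are scikit-learn
SVC. The ANN is a small numpy network — one ReLU hidden layer, sigmoid
output, binary cross-entropy, minibatch AdamW with true decoupled weight
decay (applied to weights, not biases), He initialisation — because the
scikit-learn MLP exposes Adam but not AdamW; it is cross-checked against
the scikit-learn MLP on separable data.

Per participant, accuracy is averaged over feasible folds within each
repetition, then over the five repetitions. The master seed expands into
per-(repetition, fold, family) child seeds via `SeedSequence` spawn keys,
recorded in the output, so runs are bit-reproducible. Undersampling draws
are shared across families within a (repetition, fold), mirroring the
protocol order (undersample once, then train all classifiers).

## Statistics

* One-tailed one-sample t-tests: accuracy against chance (0.5) and band
  importance against 0.
* Holm–Bonferroni step-down adjustment (verified against a brute-force
  sequential-rejection oracle and statsmodels).
* One-way repeated-measures ANOVA with Greenhouse–Geisser correction;
  epsilon from the eigenvalues of the double-centred sample (1/n)
  covariance of conditions, clipped to [1/(k-1), 1]; verified against
  pingouin and the paired-t equivalence F = t^2 at k = 2.
* Band-ablation importance: the RBF-SVM protocol re-run with one band's
  six columns removed from training and test data, under the same master
  seed as the full run so undersampling draws and tuning streams are
  identical and the drop isolates the removed features.

## Problem sizes and runtime

The test suite and the acceptance script run the cohort experiments on the
level-3 source space (66 vertices per hemisphere), tuning budget 5, which
preserves every stage of the protocol while keeping a 20-participant
cohort to a few minutes of CPU; the localization sweep uses level 4 (258
per hemisphere), and the level-6 (4098 per hemisphere) geometry is built
to verify the vertex-count law and atlas partition. Larger spaces are a
config knob (`source_level`).

## Numerical choices and degenerate inputs

* Pseudo-inverses use a 1e-10 relative eigenvalue cutoff; the shrunk
  covariance is eigendecomposed for whitening and must be positive
  definite (a rank-deficient unshrunk covariance raises an error that
  points at the shrinkage knob).
* Pink noise is synthesised in the frequency domain with an analytic
  unit-variance normalisation; recordings are float32 end to end.
* Ties in the random search resolve to the first-sampled configuration;
  the undersampling retry cap is 50 draws.
* Degenerate inputs raise typed errors: non-positive band power
  (upstream bug), zero-variance feature columns (named), all epochs
  rejected, >20% bad channels, unsatisfiable schedules, dipoles outside
  the inner shell.

## Known limitations

* The spherical head and surrogate parcellation are stand-ins for a
  template MRI head model and anatomical atlas; region geometry (sizes,
  adjacency) is not anatomically faithful.
* Source leakage between the confound region and the frontal ROIs is
  geometry-dependent; confound immunity is demonstrated for the default
  placement (postcentral vs inferior-frontal), not for arbitrarily
  adjacent regions.
* The generator's effect model is a single-band amplitude modulation;
  real pleasantness correlates would be spatially and spectrally more
  diffuse.
* With the balanced velocity design and the default score model, the fold
  testing the lowest velocity is frequently infeasible (its complement is
  unpleasant-starved), as the per-fold 30-trial rule intends; per-
  participant means therefore often average three feasible folds.
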