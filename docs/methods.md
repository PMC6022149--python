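# Methods

This note documents the models, the parameter choices, the synthetic data
generator, and the numerical decisions behind `uahar`, in the order the
pipeline runs.

## Signal model and preprocessing

Input streams are fixed-rate (default 50 Hz) sequences of tri-axial
acceleration (g) and angular velocity (deg/s), as produced by a waist-worn
MPU6050-class IMU.  Calibration is per-channel affine, `x = raw/k + b`,
with sensitivities `k > 0` and zero-drift offsets `b`.  Zero drift on
consumer MEMS parts is small relative to the signals of interest, so `b`
defaults to 0 and `k` to 1 (data already in physical units).  The CSV
dialect is fixed: columns `ax,ay,az,wx,wy,wz[,label]`, optional header
auto-detected by a non-numeric first row.

Gravity is separated from body acceleration with a low-pass Butterworth
filter at 0.3 Hz — gravity has only near-DC content, while voluntary
movement sits above ~0.5 Hz.  We use **order 3, applied forward-backward**
(zero-phase), so the gravity estimate has no lag; the filter order and
phase handling are our choices (standard in activity-recognition work),
the cutoff is the protocol value.  Body acceleration is defined as the
residual, so gravity + body reconstructs the input identically.  Gyroscope
channels are never filtered.

Windows are 1 s long (50 samples) with 50% overlap: window *k* (1-based)
starts at sample 25·(k−1).  A fall transient lasts about 300 ms, and
15 < 50 with hop 25 guarantees every transient lies entirely inside at
least one window — the reason for the 50% overlap.  Incomplete trailing
windows are dropped (no padding).  When a per-sample label track exists, a
window's ground-truth label is the majority vote, with ties resolved
toward the label occurring latest in the window (falls sit at window
ends).

## Features

Two magnitude tracks per window: ‖body acceleration‖ and ‖angular
velocity‖.  From each: mean, standard deviation, energy, mean-crossing
rate, maximum, minimum; plus the tilt angle, for 13 features total.
Definitions that needed fixing (the names alone are ambiguous):

- energy = mean of squares, `(1/L) Σ s_t²`;
- mean-crossing rate = fraction of consecutive pairs whose values straddle
  the window mean (strict sign change), normalized by L−1, hence in [0, 1];
- standard deviation uses the population (1/L) convention;
- tilt angle `TA = √((Σ ωx Δt)² + (Σ ωz Δt)²)` with rectangular
  integration, Δt = 1/rate; integration restarts at every window (windows
  are the classification unit, so no carry-over).  x and z are the
  transverse and sagittal axes of a waist-mounted sensor; rotation about
  either indicates a posture change, while axial (y) rotation does not.

Acceleration features use the **body** (gravity-removed) magnitude:
intensity statistics should not be dominated by the constant 1 g, and the
gravity separation step would otherwise be pointless.  An independent
straight-loop oracle in the test suite pins these definitions to 1e-12.

Feature normalization is per-feature min–max to [0, 1], fitted on training
data only and stored inside the classifier; test values are not clamped.
A feature constant on the training set maps to 0.

## Seeded K-Means annotation

K = 3 clusters (LIA/MIA/VIA); falls are never a cluster because adaptation
sessions contain no falls.  Initial centroids are the labeled class means
of a pre-collected dataset; Lloyd iterations (squared-Euclidean
assignment, mean update) run to an assignment fixpoint (max 100
iterations, warning on non-convergence).  Distance ties go to the lowest
cluster index; a cluster that loses all members keeps its previous
centroid, preserving the labeled anchor.  The within-cluster
sum-of-squares is non-increasing across iterations (tested property).

**Normalization for annotation is per-dataset**: the seed centroids are
computed in the seed data's own min–max space and the user's windows are
clustered in theirs.  Each dataset is normalized within its own processing
pipeline, and this choice makes the seeding robust to per-subject gain: a
subject whose signal amplitudes are uniformly, say, 25% lower than the
seed cohort's still has their clusters land near the seed centroids,
because min–max cancels a common scale factor.  (Fitting one joint
normalizer instead leaves that gain in place and can collapse a cluster
for subjects far from the cohort mean.)

## Label-based LOF filtering

After annotation, every sample's local outlier factor is computed with the
neighbor search restricted to its own cluster; restricted to one cluster
this is exactly the textbook LOF (tested against an independent
enumeration oracle to 1e-9).  The k-neighborhood is tie-inclusive at the
k-th rank, so |N_k| can exceed k.  Degenerate duplicate densities (0/0)
score 1, the non-outlier value.  Filtering is a single pass: scores are
computed once on the original set, samples above ε₁ are dropped.  A
cluster with ≤ k members passes through unfiltered with a warning.

Defaults: k = 20 neighbors, ε₁ = 1.5.  Neither is dictated by theory; LOF
literature uses k in 10–20 and scores near 1 inside tight clusters, so 1.5
separates "typical" from "outlying" with margin.  Both are config keys.

## Gaussian class models and the fall rule

One multivariate Gaussian per class, maximum-likelihood fit (covariance
divisor m).  Covariances can be near-singular at small m; whenever the
smallest eigenvalue is below 1e-10 of the largest, λI is added with
λ = max(1e-6·trace/n, 1e-8), repeated up to 10 times.  All density work is
done in log space via the Cholesky factor — 13-dimensional densities
under- and overflow the linear scale routinely.

Classification: `i′ = argmax_i log p_i(x)` with ties broken toward the
lower-intensity class.  If i′ is LIA or MIA, that is the output.  If i′ is
VIA, the window is a **fall** exactly when `p₃(x) ≤ ε₂` **and** the raw
tilt angle ≥ ε₃; otherwise VIA.  Combinations where only one fall
condition holds are deliberately resolved to VIA — a fall alarm requires
both an anomalous density and a large posture change, which keeps the
false-alarm rate conservative.  The tilt angle is thresholded in raw
degrees (not normalized), since ε₃ has physical meaning.

ε₂ is calibrated per classifier as the q-th percentile (default q = 1) of
the VIA model's density over the VIA training windows: falls resemble
vigorous activity in argmax terms but are far rarer events under the VIA
density.  With fewer than 20 VIA windows the threshold falls back to a
config override or, absent one, to the density on the 99.9% chi-square
Mahalanobis contour of the fitted Gaussian.  ε₃ defaults to 60°: a fall
rotates the trunk by roughly 70–100°, while gait oscillation integrates to
nearly zero over a window, so 60° splits the two with margin on both
sides.

The full training pipeline (`train_personalized`): preprocess → window →
features → seeded annotation → LLOF filter → refit the min–max normalizer
on the retained windows → fit three Gaussians → calibrate ε₂.  It returns
the classifier plus a report (iterations, removal count, class sizes) and
fails loudly if any class is empty after filtering.

## Synthetic cohort generator

The generator's role is to realize the study conditions — class structure,
subject shift, fall transients — not biomechanical realism.  Per class:

- **LIA**: gravity vector (1 g, rotated by the subject's baseline pitch)
  plus white noise, σ = 0.02 g (accel) / 1.5 deg/s (gyro);
- **MIA**: gait-like quasi-periodic oscillation near 2 Hz, base amplitude
  0.40 g / 30 deg/s, with ~15% stride-to-stride amplitude modulation and
  ~5% frequency wobble (real gait is not a pure sinusoid; without this
  variability the feature covariances become quasi-singular along
  deterministic constraints and density comparisons degenerate);
- **VIA**: the same model near 3.1 Hz at 0.85 g / 70 deg/s;
- **Fall**: 2.5 s quiet standing, a 300-ms transient whose gyro pulse
  integrates to a 70–100° tilt about the x or z axis with a free-fall dip
  and a 2.2–3.2 g impact spike, 0.7 s still lying (transient + this lying
  carry the `Fall` label), 2.5 s further lying (`LIA` label), then a 4-s
  smooth stand-up labeled `Transition`.  The stand-up rotation is gradual
  so gravity returns upright without a step discontinuity, and its
  worst-case per-window gyro integral stays below the 60° threshold.

Subject shift is a shared per-subject strength multiplier drawn in
±30% with small (±10%) per-class jitter, plus baseline-pitch, gait-frequency
and noise-level variation.  The shared multiplier is the point: classes
stay separable **within** a subject (so self-annotation can succeed) while
class boundaries overlap **across** subjects (so a pooled generic model
genuinely degrades).  The generator guarantees, and the tests check, that
between-subject spread of class means exceeds within-subject window
scatter for at least one class.

The default cohort is 10 subjects; each stream is a 240-s fall-free
adaptation session (80 s per class) followed by a 59-s held-out session
(9 s per class + 4 fall events), a 4:1 train:test split.  Everything is
reproducible from a master seed via spawned per-subject seeds.

What the simulator does **not** emulate: real sensor artifacts (saturation,
quantization, axis misalignment), diverse activity types within a
category, near-fall confounders (sitting down hard, lying down
voluntarily), or genuinely unscripted falls.  Passing tests on this cohort
show the pipeline's mechanics and its relative personalized-vs-generic
behavior under controlled shift; they say nothing about absolute accuracy
on real recordings.

## Evaluation protocol

Per-class one-vs-rest precision/recall/F-measure; degenerate 0/0 ratios
report 0 with a warning so per-subject tables aggregate.  The
leave-one-out comparison trains, per subject, (a) a personalized
classifier on the subject's own unlabeled fall-free session, with the
other subjects' pooled labeled data contributing only seed centroids, and
(b) a generic classifier whose Gaussians are fitted on that pooled labeled
data directly, both evaluated on the subject's held-out session including
falls.

Evaluation is **clip-based**: each contiguous same-activity segment is
preprocessed and windowed on its own, mirroring a protocol of per-activity
recordings and separately captured fall clips.  No evaluated window spans
an activity change, every fall clip contains its whole transient, and the
`Transition` stand-up segments are not evaluated (the protocol has no such
clips; they remain in the continuous stream for CLI use).  Windowing a
continuous stream across posture changes is still supported — but then
windows adjacent to falls mix classes and the zero-phase gravity filter
rings around posture steps, which depresses absolute scores for any
classifier.

Fisher's exact test (two-sided, summing hypergeometric probabilities ≤ the
observed table's) is provided for 2×2 tables such as
above/below-mean-improvement × normal/abnormal BMI; it delegates to
`scipy.stats.fisher_exact` and is verified against a full enumeration
oracle in the tests.  The SS/IS split utility builds that table from any
per-subject delta vector and a binary covariate.

## Problem sizes and determinism

Default sizes (10 subjects × ~300 s at 50 Hz, ~480 training windows per
subject, LLOF at k = 20 over ~160-window clusters) keep a full LOO run
within a few seconds on one core while leaving every per-class estimate
based on dozens of windows.  All randomness flows from explicit seeds:
the same configuration and seeds produce bit-identical classifiers and
prediction files.  Per-stage seeds are derived from the global seed by
combining it with a CRC32 of the stage name through `numpy` seed
sequences.

## Known limitations

- The fall rule assumes falls win the argmax as vigorous-like anomalies;
  a fall whose window features happen to sit closer to the MIA model is
  missed.  Tight, well-separated class models make this rare but it is
  structural.
- Seeded annotation needs the seed cohort to resemble the new user after
  per-dataset scaling; users whose class *structure* (not just gain)
  differs can still be mis-annotated, and LLOF only removes point-wise
  outliers, not systematically mislabeled clusters.
- ε₂'s scale depends on the normalized feature space; the percentile
  calibration makes it self-adjusting, but transferring a serialized
  classifier to data normalized differently invalidates it.
- Thresholds ε₁/ε₃ are fixed defaults, not learned; the config exposes
  them for sensitivity analysis.
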