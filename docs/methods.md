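# Methods

## Problem and approach

Remote photoplethysmography (rPPG) estimates heart rate from the subtle
cardiac color modulation of facial skin in ordinary video. Under motion the
estimates degrade sharply, and in monitoring applications an inaccurate
reading is worse than no reading: it triggers false alarms. This package
implements a *motion-based confidence score*: instead of judging quality from
the extracted pulse signal itself, it measures how much the scene and the
face move, and trains a classifier to predict — from motion alone — whether
the HR estimate of a given analysis window can be trusted.

The processing chain, per 12-s window advanced every second:

1. **ROI**: the convex hull of the facial landmarks, rasterized (a pixel
   belongs to the ROI when its center is inside or on the hull), minus the
   convex hulls of the eye and mouth point sets. Pixel coordinates are
   0-based, x = column, y = row, origin top-left.
2. **RGB trace**: the arithmetic mean of the ROI pixels per channel per
   frame. No detrending or artifact removal is applied.
3. **BVP extraction**: `GREEN` (mean-subtracted green channel), `CHROM`
   (X = 3R − 2G, Y = 1.5R + G − 1.5B on mean-normalized channels,
   S = X − (σ_X/σ_Y)·Y) or `POS` (S1 = G − B, S2 = G + B − 2R,
   h = S1 + (σ_S1/σ_S2)·S2). CHROM/POS are applied over the whole 12-s
   window; when the denominator σ vanishes the first component is used
   alone.
4. **HR**: zero-phase Butterworth bandpass (order 6, 0.65–4.0 Hz ≙ 39–240
   bpm), multiplication by a Hann window, zero-padded periodogram (≥ 8192
   points), in-band peak with three-point parabolic refinement, × 60.
5. **Motion features**:
   - `TI` — max over consecutive frame pairs of the *population* standard
     deviation of the BT.601-luminance difference image, computed on the
     **full frame** (so background motion registers; a config switch
     restricts it to any cropped sequence if desired);
   - `FM_X`, `FM_Y` — mean absolute landmark displacement per axis,
     normalization 1/(l·(n−1)), raw pixel units;
   - `FSM` — mean absolute change of the ROI pixel count between
     consecutive frames.
6. **Labels**: absolute HR error < 2 bpm → reliable (1); > 6 bpm →
   unreliable (0); the closed band [2, 6] bpm is discarded from training and
   testing (boundary values 2.0 and 6.0 fall in the discarded band — the
   defining inequalities are strict). Windows without an estimate or
   reference are discarded with a distinct reason code.
7. **Confidence model**: by default a bagged-trees ensemble — 30 bootstrap
   trees, each capped at 10 leaf nodes (the "9 maximum splits" convention:
   a binary tree with s splits has s+1 leaves), all four features available
   at every split. The score is the ensemble's class-1 probability (mean of
   per-tree votes), in [0, 1]. Nine alternative classifiers (fine tree, LDA,
   logistic regression, Gaussian naive Bayes, linear/RBF SVM with small-grid
   inner-CV tuning, 1-NN, AdaBoost trees, a 3×10 ReLU network) sit behind
   the same configuration enum; scale-sensitive ones are wrapped with a
   standardizer.
8. **Evaluation**: threshold-free, via the ROC curve and its area. Folds are
   *subject-stratified*: a greedy balancer (subjects seeded-shuffled, stably
   sorted by record count, each assigned to the lightest fold) guarantees
   all windows of a subject share a fold. Three schemes: k-fold CV within
   each dataset, train-on-two/test-on-one cross-dataset, and k-fold CV over
   the pooled datasets. Reported AUCs are pooled out-of-fold AUCs; per-fold
   values accompany them.

## Synthetic data generator

Real rPPG benchmarks are request-gated, so the package carries a generator
that renders face-like clips with known ground truth: an elliptical
skin-colored region (green-dominant pulsatile modulation, R:G:B =
0.33:1:0.5 of `pulse_amplitude`, default 3 8-bit counts), analytic landmarks
on the ellipse boundary, eye/mouth exclusion ellipses, a 60 Hz oximeter-style
reference trace (waveform + instantaneous HR), controlled x/y translation
(sinusoid or mean-reverting random walk — AR(1), ρ = 0.98, so the face
cannot drift out of frame), z-scale oscillation, an optional drifting
textured background patch, Gaussian pixel noise, and Gaussian landmark
jitter emulating keypoint-detector noise.

Motion must *corrupt* the HR estimate for the confidence problem to exist.
Tracking is analytic here (the ROI never slips), so corruption is injected
explicitly: a motion-coupled color artifact added to the face, with a
normalized drive combining translation (in face-height units) and scale
change. The artifact has two color directions with distinct time courses —
one linear in the drive (shading-like), one driven by the rectified drive
(specular-like). Two independent components make the disturbance rank-2,
which the single-α projections of CHROM and POS cannot annihilate
completely; the directions were chosen to span the chrominance plane so that
each extractor is genuinely challenged: the linear direction projects onto
the green channel and POS's S1, the rectified one onto CHROM's X. GREEN
degrades first, CHROM next, POS last — reproducing the published robustness
ordering of the three extractors.

### The study corpus

`pipeline.synthetic_study` renders three pseudo-datasets with disjoint
subjects (default 6 each), echoing the structure of the public benchmarks:

* **stillset** — still sessions, a noisy still session, a background-motion
  session, and a mild "game" fidgeting session (webcam-benchmark style);
* **transset** — controlled sinusoidal head translations at ~7 % and ~14 %
  of the face height per second (the documented slow/fast scenarios of the
  controlled-motion benchmark this emulates) plus a z-scale session;
* **freeset** — talking/exercise-like sessions mixing random-walk drift with
  an in-band head-wobble sinusoid, plus one still session.

Clips are 24 s at 30 fps, rendered at 96×72: window statistics (ROI means,
features, spectra) are resolution-invariant once the ROI holds a few
thousand pixels, and this size keeps the full 66-clip study around 1–2
minutes on one core. Subjects carry constant or ramped HR trajectories drawn
from 76–116 bpm; motion magnitudes get a per-clip multiplier in [0.8, 1.25]
(people move by different amounts). Motion frequencies (1.0–1.15 Hz) sit
inside the analysis passband but outside the HR range, *as do their second
harmonics* (2.0–2.3 Hz): when the artifact captures the spectral peak the
resulting error is ≥ 7 bpm, so corrupted windows are decisively unreliable
rather than accidentally "correct" — without this the corpus contains
windows whose label depends on the subject's HR coinciding with an artifact
line, which no motion feature can predict.

### What the generator does not emulate

Photorealistic appearance, illumination changes, skin-tone diversity,
detector tracking failures (landmarks are analytic plus i.i.d. jitter),
compression artifacts, and pulse-waveform morphology beyond a sinusoid with
an optional second harmonic. Passing the synthetic study therefore
demonstrates that the *pipeline and model mechanics* are correct and that
the confidence score separates motion-corrupted from clean windows under a
controlled corruption mechanism — not that the same AUCs would be reached on
any particular real dataset.

## Numerical choices

* Luminance uses BT.601 weights (0.299, 0.587, 0.114), kept unrounded.
* TI uses the population (not sample) standard deviation.
* The Butterworth filter is applied zero-phase (`sosfiltfilt`); the passband
  0.65–4.0 Hz and order 6 follow the conventions of the open rPPG framework
  this pipeline mirrors, and are config-exposed.
* Parabolic peak refinement operates on the three power values around the
  in-band maximum; the offset is clipped to ±½ bin and skipped at spectrum
  edges or for a degenerate (flat) vertex.
* Windows are (t−12, t] for every whole second t; the reference HR is the
  mean of the 60 Hz instantaneous-HR samples inside the window, falling back
  to the same spectral estimator on the reference waveform when an HR
  channel is absent.
* A frame with an empty or degenerate ROI invalidates its whole window
  ("no-estimate") rather than being interpolated.
* ROC/AUC, Pearson r (with t-approximation p-value) and the classifier
  implementations come from scikit-learn/SciPy behind the package's own
  interfaces; the test suite checks them against brute-force oracles
  (exhaustive pairwise AUC, direct covariance-formula r).
* All randomness flows from explicit integer seeds; scene rendering is
  bit-deterministic given its config.

## Known limitations

* The corpus's unreliable rates (≈ 30–55 % of windows, method-dependent) are
  far above those of mostly-still real datasets; the corpus is deliberately
  motion-heavy so that both classes are well populated at desk scale.
* SVM hyperparameters are tuned on an inner split without subject grouping;
  with few subjects per fold this can leak identity into the tuning
  objective (the default bagged-trees model does no tuning and is
  unaffected).
* Cross-dataset AUC is undefined for a held-out dataset whose windows are
  single-class; such datasets are reported with a null AUC and excluded from
  the cross-dataset mean.
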