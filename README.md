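# rppg-confidence

Motion-based confidence scores for remote photoplethysmography (rPPG)
heart-rate measurements.

rPPG reads heart rate from face video: each heartbeat subtly modulates the
color of facial skin, and the dominant frequency of that modulation is the
pulse. The technique works well while the subject sits still and falls apart
under head or scene motion — which is exactly when remote monitoring systems
produce false alarms. This package implements a *confidence score* that
predicts, for every HR measurement, how trustworthy it is — using only
motion information from the video, never the pulse signal itself. It is
aimed at people building or evaluating camera-based vital-sign monitoring:
the score lets downstream logic suppress or down-weight readings taken while
the face was moving.

## What it computes

For each 12-s window (advanced every second) of a face video with landmark
coordinates:

* an HR estimate via one of three standard BVP extractors — **GREEN** (raw
  green channel), **CHROM** (chrominance projection) or **POS**
  (plane-orthogonal-to-skin) — followed by a 0.65–4 Hz Butterworth bandpass,
  a Hann window and a quadratically interpolated spectral peak;
* four motion features:
  - **TI** — temporal perceptual information, `max_i σ[L_i − L_{i−1}]`, the
    peak spatial spread of the luminance difference between consecutive
    frames;
  - **FM_X, FM_Y** — mean absolute landmark displacement per axis,
    `1/(l(n−1)) Σ_i Σ_j |D_ij|`;
  - **FSM** — mean absolute change of the ROI pixel count, `1/(n−1) Σ
    |N_i − N_{i−1}|` (a proxy for motion toward/away from the camera);
* a continuous reliability score in [0, 1] from a bagged-trees classifier
  (30 bootstrap trees, ≤ 10 leaves each) trained on those four features,
  where windows with |HR error| < 2 bpm are labeled reliable, > 6 bpm
  unreliable, and the ambiguous band in between is discarded. Evaluation is
  threshold-free (ROC/AUC) under subject-stratified cross-validation.

Because the public rPPG benchmarks are request-gated, the package ships a
deterministic synthetic generator: face-like clips with a known embedded
pulse, controlled translation/scale/background motion, and motion-coupled
color artifacts that genuinely corrupt the HR estimate. See
`docs/methods.md` for the model and generator details.

## Worked example

Render a clip whose face oscillates sideways (1 px at 1.1 Hz) while the true
heart rate is 84 bpm, and extract window records:

```python
from rppg_confidence import SceneConfig, MotionSpec, generate_scene, label_windows
from rppg_confidence.pipeline import analyze_scene

cfg = SceneConfig(width=96, height=72, fps=30.0, duration_s=20.0,
                  hr_trajectory=84.0, pulse_amplitude=3.0, pixel_noise_sd=1.0,
                  artifact_gain=300.0,
                  motion_x=MotionSpec("sinusoid", amplitude_px=1.0, freq_hz=1.1),
                  seed=42)
records = label_windows(analyze_scene(generate_scene(cfg)))
print(records[["method", "window_end_s", "TI", "FM_X",
               "hr_bpm", "hr_ref_bpm", "abs_err_bpm", "label"]].head(3).round(3))
```

```
method  window_end_s   TI  FM_X  hr_bpm  hr_ref_bpm  abs_err_bpm  label
 GREEN          12.0  6.3 0.147  66.011        84.0       17.989    0.0
 CHROM          12.0  6.3 0.147  66.009        84.0       17.991    0.0
   POS          12.0  6.3 0.147  66.020        84.0       17.980    0.0
```

The motion artifact has captured the spectral peak at the motion frequency
(66 bpm instead of the true 84), the absolute error is ~18 bpm, and the
windows are labeled unreliable (class 0) — high TI and FM_X are what the
confidence model learns to flag. On a still scene the same pipeline recovers
the embedded HR to within a few hundredths of a bpm and labels every window
reliable.

The same steps are available from the shell:

```bash
rppg-confidence simulate --out scene/ --width 96 --height 72 --duration 20 --hr 84 --seed 42
rppg-confidence extract  --scene scene/ --out windows.csv
rppg-confidence train    --windows windows.csv --out model.joblib
rppg-confidence score    --model model.joblib --windows windows.csv --out scored.csv
rppg-confidence evaluate --synthetic --out report.json   # full synthetic study
```

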