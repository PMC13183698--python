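"""Synthetic face-video generator with a known embedded pulse.

Renders an elliptical skin-colored "face" whose interior pixels are modulated
by a pulse waveform at a prescribed heart-rate trajectory, moving under
controlled x/y translation, z-scale oscillation and optional background
motion.  Landmarks are analytic (placed on the ellipse boundary), never
detected, so every downstream stage can be tested deterministically without
any real dataset.

The generator emulates the recording conditions of public rPPG benchmarks
(30 fps, 8-bit RGB, pulse-oximeter reference sampled at 60 Hz) at a
configurable resolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "MotionSpec",
    "SceneConfig",
    "ReferenceTrace",
    "FrameSequence",
    "LandmarkTrack",
    "SyntheticScene",
    "constant_hr",
    "ramp_hr",
    "generate_pulse_waveform",
    "generate_scene",
    "generate_feature_table",
    "write_scene",
    "read_scene",
]

HR_MIN_BPM = 40.0
HR_MAX_BPM = 240.0

#: Canonical order of the four motion features throughout the package.
FEATURE_NAMES = ("TI", "FM_X", "FM_Y", "FSM")

# Relative pulsatile amplitude per RGB channel (green-dominant pulsatility).
DEFAULT_CHANNEL_RATIOS = (0.33, 1.0, 0.5)

# Two motion-artifact color directions: a shading-like component that is
# linear in the displacement drive and a specular-like component driven by the
# rectified drive.  Two independent time courses make the disturbance rank-2,
# which a single-alpha chrominance projection cannot cancel completely; the
# directions span the chrominance plane (rather than the intensity axis), the
# way specular reflections shift color balance when the head moves.
ARTIFACT_RATIOS_LINEAR = (1.42, 1.50, 0.40)
ARTIFACT_RATIOS_RECTIFIED = (2.13, 0.50, 0.80)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionSpec:
    """One translation trajectory: ``none``, ``sinusoid`` or ``random_walk``.

    ``sinusoid`` uses ``amplitude_px`` and ``freq_hz``; ``random_walk`` draws
    per-frame Gaussian steps of ``step_sd_px`` with mild mean reversion
    (rho = 0.98) so the face stays in frame over long clips.
    """

    kind: str = "none"
    amplitude_px: float = 0.0
    freq_hz: float = 0.5
    step_sd_px: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "sinusoid", "random_walk"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.amplitude_px < 0 or self.step_sd_px < 0:
            raise ValueError("motion amplitudes must be >= 0")

    def trajectory(self, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(times)
        if self.kind == "sinusoid":
            return self.amplitude_px * np.sin(2 * np.pi * self.freq_hz * times)
        steps = rng.normal(0.0, self.step_sd_px, size=times.size)
        out = np.empty_like(steps)
        acc = 0.0
        for i, s in enumerate(steps):
            acc = 0.98 * acc + s
            out[i] = acc
        return out


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic clip.

    ``hr_trajectory`` maps time in seconds to heart rate in bpm and must stay
    within [40, 240] bpm.  ``pulse_amplitude`` is the peak green-channel
    modulation in 8-bit counts; the other channels are scaled by
    ``channel_ratios``.  ``artifact_gain`` injects a motion-coupled color
    disturbance into the face (8-bit counts per unit normalized displacement),
    emulating shading/specular changes as the head moves.
    ``landmark_jitter_sd`` adds detector-style per-frame Gaussian noise to the
    reported landmark coordinates without moving the rendered face.
    """

    width: int = 640
    height: int = 480
    fps: float = 30.0
    duration_s: float = 60.0
    hr_trajectory: Callable[[np.ndarray], np.ndarray] | float = 72.0
    pulse_amplitude: float = 3.0
    channel_ratios: tuple[float, float, float] = DEFAULT_CHANNEL_RATIOS
    second_harmonic: float = 0.0
    motion_x: MotionSpec = field(default_factory=MotionSpec)
    motion_y: MotionSpec = field(default_factory=MotionSpec)
    scale_motion: float = 0.0
    scale_freq_hz: float = 0.25
    background_motion: bool = False
    background_amplitude: float = 25.0
    pixel_noise_sd: float = 0.0
    artifact_gain: float = 0.0
    landmark_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.pulse_amplitude < 0 or self.pixel_noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.scale_motion < 0 or self.background_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")

    def hr_at(self, times: np.ndarray) -> np.ndarray:
        if callable(self.hr_trajectory):
            hr = np.asarray(self.hr_trajectory(np.asarray(times, dtype=float)), dtype=float)
            hr = np.broadcast_to(hr, np.shape(times)).astype(float)
        else:
            hr = np.full(np.shape(times), float(self.hr_trajectory))
        if hr.size and (hr.min() < HR_MIN_BPM or hr.max() > HR_MAX_BPM):
            raise ValueError(
                f"hr_trajectory leaves [{HR_MIN_BPM:g}, {HR_MAX_BPM:g}] bpm "
                f"(range {hr.min():.1f}-{hr.max():.1f})"
            )
        return hr


def constant_hr(bpm: float) -> Callable[[np.ndarray], np.ndarray]:
    """Constant heart-rate trajectory."""
    return lambda t: np.full(np.shape(t), float(bpm))


def ramp_hr(start_bpm: float, end_bpm: float, duration_s: float) -> Callable[[np.ndarray], np.ndarray]:
    """Linear heart-rate ramp from ``start_bpm`` to ``end_bpm`` over the clip."""

    def traj(t: np.ndarray) -> np.ndarray:
        frac = np.clip(np.asarray(t, dtype=float) / duration_s, 0.0, 1.0)
        return start_bpm + (end_bpm - start_bpm) * frac

    return traj


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTrace:
    """Oximeter-style ground truth: pulse waveform plus instantaneous HR."""

    time_s: np.ndarray
    ppg: np.ndarray
    hr_bpm: np.ndarray
    sample_rate: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "ppg": self.ppg, "hr_bpm": self.hr_bpm})


@dataclass
class FrameSequence:
    """Ordered 8-bit RGB frames with their frame rate."""

    frames: np.ndarray  # (n, H, W, 3) uint8
    fps: float

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps


@dataclass
class LandmarkTrack:
    """Per-frame (x, y) landmark coordinates, shape (n_frames, l, 2)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 3 or pts.shape[2] != 2:
            raise ValueError("landmark points must have shape (n_frames, l, 2)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        self.points = pts

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[1]


@dataclass
class SyntheticScene:
    """Rendered clip + analytic landmarks + reference trace + ground truth."""

    frames: FrameSequence
    landmarks: LandmarkTrack
    exclusions: dict[str, np.ndarray]  # name -> (n_frames, m, 2)
    reference: ReferenceTrace
    config: SceneConfig
    truth: dict


# ---------------------------------------------------------------------------
# pulse waveform
# ---------------------------------------------------------------------------

def generate_pulse_waveform(
    hr_trajectory: Callable[[np.ndarray], np.ndarray] | float,
    sample_rate: float,
    duration_s: float,
    second_harmonic: float = 0.0,
) -> ReferenceTrace:
    """Synthesize a pulse waveform s(t) = sin(2*pi*Integral f dt) at a given rate.

    The instantaneous frequency f(t) = hr(t)/60 is integrated numerically so
    arbitrary (piecewise-constant or ramped) trajectories produce a phase-
    continuous waveform.  An optional second harmonic adds a crude systolic
    notch.  The returned trace also carries the instantaneous HR channel, the
    way an oximeter reference file does.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    cfg_probe = SceneConfig(hr_trajectory=hr_trajectory, duration_s=duration_s,
                            fps=sample_rate)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    hr = cfg_probe.hr_at(t)
    fmax = hr.max() / 60.0
    if sample_rate < 2 * fmax:
        raise ValueError("sample_rate below Nyquist for the pulse trajectory")
    freq = hr / 60.0
    phase = 2 * np.pi * np.cumsum(freq) / sample_rate
    ppg = np.sin(phase)
    if second_harmonic:
        ppg = ppg + second_harmonic * np.sin(2 * phase)
    return ReferenceTrace(time_s=t, ppg=ppg, hr_bpm=hr, sample_rate=float(sample_rate))


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

_SKIN_BASE = np.array([182.0, 128.0, 102.0])     # light skin tone, RGB
_BACKGROUND = np.array([68.0, 66.0, 64.0])
_EYE_COLOR = np.array([46.0, 34.0, 30.0])
_MOUTH_COLOR = np.array([140.0, 62.0, 60.0])

_N_FACE_LANDMARKS = 16
_N_EXCL_POINTS = 8

# Face geometry in normalized face coordinates (u, v in the unit disc).
_EYE_OFFSETS = ((-0.40, -0.32), (0.40, -0.32))
_EYE_AXES = (0.16, 0.10)
_MOUTH_OFFSET = (0.0, 0.48)
_MOUTH_AXES = (0.28, 0.12)


def _ellipse_points(cx: float, cy: float, ax: float, ay: float, n: int) -> np.ndarray:
    theta = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + ax * np.cos(theta), cy + ay * np.sin(theta)])


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render a synthetic clip from ``config``.

    Deterministic: identical config (including seed) reproduces bit-identical
    frames, landmarks and reference.  Raises ``ValueError`` if the face would
    leave the frame bounds under the configured motion.
    """
    w, h, fps = config.width, config.height, config.fps
    n_frames = int(round(config.duration_s * fps))
    times = np.arange(n_frames) / fps

    cx0, cy0 = w / 2.0, h / 2.0
    ax0, ay0 = 0.28 * w, 0.36 * h  # face semi-axes

    rng_x, rng_y, rng_noise, rng_jitter = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(4))
    dx = config.motion_x.trajectory(times, rng_x)
    dy = config.motion_y.trajectory(times, rng_y)
    scale = 1.0 + config.scale_motion * np.sin(2 * np.pi * config.scale_freq_hz * times)

    # bounds check: the whole face ellipse must stay inside the frame
    if (np.any(cx0 + dx - ax0 * scale < 0) or np.any(cx0 + dx + ax0 * scale > w - 1)
            or np.any(cy0 + dy - ay0 * scale < 0) or np.any(cy0 + dy + ay0 * scale > h - 1)):
        raise ValueError("configured motion drives the face out of the frame")

    hr_frames = config.hr_at(times)
    pulse = generate_pulse_waveform(config.hr_trajectory, fps, config.duration_s,
                                    config.second_harmonic).ppg

    # motion-coupled color artifact (shading + specular-like), face pixels only
    drive = (dx + dy) / (2 * ay0) + 2.0 * (scale - 1.0)
    art_lin = config.artifact_gain * drive
    art_rect = 0.8 * config.artifact_gain * np.abs(drive)
    ratios = np.asarray(config.channel_ratios, dtype=float)
    art_colors = (np.outer(art_lin, ARTIFACT_RATIOS_LINEAR)
                  + np.outer(art_rect, ARTIFACT_RATIOS_RECTIFIED))  # (n, 3)
    pulse_colors = np.outer(config.pulse_amplitude * pulse, ratios)  # (n, 3)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    landmarks = np.empty((n_frames, _N_FACE_LANDMARKS, 2))
    excl_names = ("left_eye", "right_eye", "mouth")
    exclusions = {name: np.empty((n_frames, _N_EXCL_POINTS, 2)) for name in excl_names}

    bg_speed = 18.0  # px/s drift of the textured background patch
    for i in range(n_frames):
        cx, cy = cx0 + dx[i], cy0 + dy[i]
        axs, ays = ax0 * scale[i], ay0 * scale[i]

        frame = np.broadcast_to(_BACKGROUND, (h, w, 3)).copy()
        if config.background_motion:
            # drifting textured patch on the left quarter of the frame
            patch_w = w // 4
            u = xx[:, :patch_w] - bg_speed * times[i]
            tex = (config.background_amplitude
                   * np.sin(2 * np.pi * u / 9.0) * np.cos(2 * np.pi * yy[:, :patch_w] / 13.0))
            frame[:, :patch_w, :] += tex[:, :, None]

        u = (xx - cx) / axs
        v = (yy - cy) / ays
        inside = u * u + v * v <= 1.0
        # fixed texture in face coordinates: moves with the face and dithers
        # the 8-bit quantization of the uniform pulse modulation
        tex_face = 4.0 * np.sin(3.1 * u[inside] + 1.0) * np.cos(2.3 * v[inside] - 0.7)
        face_color = _SKIN_BASE + pulse_colors[i] + art_colors[i]
        frame[inside] = face_color + tex_face[:, None]

        for (ex, ey), color, ax_e, ay_e in (
            (_EYE_OFFSETS[0], _EYE_COLOR, _EYE_AXES[0], _EYE_AXES[1]),
            (_EYE_OFFSETS[1], _EYE_COLOR, _EYE_AXES[0], _EYE_AXES[1]),
            (_MOUTH_OFFSET, _MOUTH_COLOR, _MOUTH_AXES[0], _MOUTH_AXES[1]),
        ):
            ecx, ecy = cx + ex * axs, cy + ey * ays
            ue = (xx - ecx) / (ax_e * axs)
            ve = (yy - ecy) / (ay_e * ays)
            frame[ue * ue + ve * ve <= 1.0] = color

        if config.pixel_noise_sd > 0:
            frame = frame + rng_noise.normal(0.0, config.pixel_noise_sd, size=frame.shape)

        frames[i] = np.clip(np.round(frame), 0, 255).astype(np.uint8)

        landmarks[i] = _ellipse_points(cx, cy, axs, ays, _N_FACE_LANDMARKS)
        for name, (ox, oy), (axe, aye) in zip(
            excl_names,
            (*_EYE_OFFSETS, _MOUTH_OFFSET),
            (_EYE_AXES, _EYE_AXES, _MOUTH_AXES),
        ):
            exclusions[name][i] = _ellipse_points(cx + ox * axs, cy + oy * ays,
                                                  axe * axs, aye * ays, _N_EXCL_POINTS)

    if config.landmark_jitter_sd > 0:
        # detector-style keypoint noise: the rendered face is unaffected but
        # the reported landmarks (and hence the ROI) jitter frame to frame
        landmarks += rng_jitter.normal(0.0, config.landmark_jitter_sd, landmarks.shape)
        for name in excl_names:
            exclusions[name] += rng_jitter.normal(
                0.0, config.landmark_jitter_sd, exclusions[name].shape)

    reference = generate_pulse_waveform(config.hr_trajectory, 60.0, config.duration_s,
                                        config.second_harmonic)
    truth = {
        "hr_bpm_per_frame": hr_frames,
        "has_motion": (config.motion_x.kind != "none" or config.motion_y.kind != "none"
                       or config.scale_motion > 0),
        "has_background_motion": bool(config.background_motion),
        "artifact_injected": config.artifact_gain > 0,
    }
    return SyntheticScene(
        frames=FrameSequence(frames=frames, fps=fps),
        landmarks=LandmarkTrack(points=landmarks),
        exclusions=exclusions,
        reference=reference,
        config=config,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# classifier fixture
# ---------------------------------------------------------------------------

def generate_feature_table(n_per_class: int, separation_d: float, seed: int) -> pd.DataFrame:
    """Balanced 4-D Gaussian feature table for classifier tests.

    Class 1 (reliable) is N(0, I); class 0 (unreliable) is shifted by
    ``separation_d`` along the unit direction (1,1,1,1)/2 — motion features
    increase together when measurements degrade.  With unit spherical
    covariance the Bayes AUC is Phi(d / sqrt(2)).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if separation_d < 0:
        raise ValueError("separation_d must be >= 0")
    rng = np.random.default_rng(seed)
    direction = np.full(4, 0.5)  # unit vector
    x1 = rng.normal(size=(n_per_class, 4))
    x0 = rng.normal(size=(n_per_class, 4)) + separation_d * direction
    df = pd.DataFrame(np.vstack([x1, x0]), columns=list(FEATURE_NAMES))
    df["label"] = np.concatenate([np.ones(n_per_class, dtype=int),
                                  np.zeros(n_per_class, dtype=int)])
    return df


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def _landmarks_to_frame(points: np.ndarray) -> pd.DataFrame:
    n, l, _ = points.shape
    cols: dict[str, np.ndarray] = {"frame_index": np.arange(n)}
    for j in range(l):
        cols[f"x_{j + 1}"] = points[:, j, 0]
        cols[f"y_{j + 1}"] = points[:, j, 1]
    return pd.DataFrame(cols)


def _frame_to_landmarks(df: pd.DataFrame) -> np.ndarray:
    l = (len(df.columns) - 1) // 2
    pts = np.empty((len(df), l, 2))
    for j in range(l):
        pts[:, j, 0] = df[f"x_{j + 1}"].to_numpy()
        pts[:, j, 1] = df[f"y_{j + 1}"].to_numpy()
    return pts


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> Path:
    """Write frames as zero-padded PNGs plus landmark/reference CSVs and a JSON sidecar."""
    out = Path(out_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(scene.frames.frames):
        iio.imwrite(frames_dir / f"frame_{i:06d}.png", frame)
    _landmarks_to_frame(scene.landmarks.points).to_csv(out / "landmarks.csv", index=False)
    for name, pts in scene.exclusions.items():
        _landmarks_to_frame(pts).to_csv(out / f"exclusion_{name}.csv", index=False)
    scene.reference.to_frame().to_csv(out / "reference.csv", index=False)
    cfg = dataclasses.asdict(scene.config)
    cfg["hr_trajectory"] = (scene.config.hr_trajectory
                            if isinstance(scene.config.hr_trajectory, (int, float))
                            else "callable")
    sidecar = {
        "fps": scene.frames.fps,
        "n_frames": len(scene.frames),
        "seed": scene.config.seed,
        "reference_sample_rate": scene.reference.sample_rate,
        "exclusions": sorted(scene.exclusions),
        "config": cfg,
    }
    (out / "scene.json").write_text(json.dumps(sidecar, indent=2, default=str))
    return out


def read_scene(scene_dir: str | Path) -> tuple[FrameSequence, LandmarkTrack, dict[str, np.ndarray], ReferenceTrace | None]:
    """Load a scene directory written by :func:`write_scene` (or hand-assembled)."""
    d = Path(scene_dir)
    sidecar = json.loads((d / "scene.json").read_text())
    fps = float(sidecar["fps"])
    frame_paths = sorted((d / "frames").glob("frame_*.png"))
    if not frame_paths:
        raise FileNotFoundError(f"no frames under {d / 'frames'}")
    frames = np.stack([iio.imread(p) for p in frame_paths])
    landmarks = LandmarkTrack(points=_frame_to_landmarks(pd.read_csv(d / "landmarks.csv")))
    exclusions = {}
    for name in sidecar.get("exclusions", []):
        exclusions[name] = _frame_to_landmarks(pd.read_csv(d / f"exclusion_{name}.csv"))
    reference = None
    ref_path = d / "reference.csv"
    if ref_path.exists():
        rf = pd.read_csv(ref_path)
        reference = ReferenceTrace(
            time_s=rf["time_s"].to_numpy(),
            ppg=rf["ppg"].to_numpy(),
            hr_bpm=rf["hr_bpm"].to_numpy(),
            sample_rate=float(sidecar.get("reference_sample_rate", 60.0)),
        )
    return FrameSequence(frames=frames, fps=fps), landmarks, exclusions, reference
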