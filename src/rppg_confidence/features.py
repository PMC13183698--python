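"""Per-window motion features: TI, FM_X, FM_Y and FSM.

Four scalar descriptors of how much a video window moves, used to predict
whether the rPPG heart-rate estimate from that window can be trusted:

* **TI** (temporal perceptual information, ITU-T P.910 style): the maximum
  over consecutive frame pairs of the spatial standard deviation of the
  luminance difference image.  Computed on the full frame, so background
  motion registers even when the face is still (exposed via ``full_frame``).
* **FM_X / FM_Y** (face motion): the mean absolute per-frame displacement of
  the facial landmarks along x / y, in pixels per frame step.
* **FSM** (face size motion): the mean absolute per-frame change in the ROI
  pixel count, a proxy for motion along the camera axis.

All four are non-negative; a perfectly static window scores exactly zero on
each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import FrameSequence, LandmarkTrack

__all__ = [
    "MotionFeatureVector",
    "luminance",
    "temporal_information",
    "luminance_diff_sigmas",
    "face_motion",
    "face_size_motion",
    "window_features",
]

#: BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class MotionFeatureVector:
    TI: float
    FM_X: float
    FM_Y: float
    FSM: float

    def as_array(self) -> np.ndarray:
        return np.array([self.TI, self.FM_X, self.FM_Y, self.FSM])


def luminance(frame: np.ndarray) -> np.ndarray:
    """Per-pixel BT.601 luminance of an 8-bit RGB frame, unrounded floats."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected an RGB frame of shape (H, W, 3)")
    r, g, b = LUMA_WEIGHTS
    f = frame.astype(float)
    return r * f[:, :, 0] + g * f[:, :, 1] + b * f[:, :, 2]


def luminance_diff_sigmas(frames: np.ndarray | FrameSequence) -> np.ndarray:
    """Population std of each successive luminance difference image.

    Returns an array of length n-1; ``temporal_information`` is its running
    window maximum.  Exposed separately so a pipeline can compute it once per
    video instead of once per (heavily overlapping) window.
    """
    arr = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    prev = luminance(arr[0])
    sigmas = np.empty(arr.shape[0] - 1)
    for i in range(1, arr.shape[0]):
        cur = luminance(arr[i])
        sigmas[i - 1] = np.std(cur - prev)  # population std over all pixels
        prev = cur
    return sigmas


def temporal_information(frames: np.ndarray | FrameSequence) -> float:
    """TI = max_i sigma[L_i - L_{i-1}] over successive full frames."""
    return float(np.max(luminance_diff_sigmas(frames)))


def face_motion(landmarks: LandmarkTrack | np.ndarray, axis: str) -> float:
    """Mean absolute landmark displacement along ``axis`` ('x' or 'y').

    Averages |displacement| over all l landmarks and all n-1 consecutive
    frame pairs, i.e. normalization 1 / (l * (n - 1)).
    """
    pts = landmarks.points if isinstance(landmarks, LandmarkTrack) else np.asarray(pts_check(landmarks))
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 frames of landmarks")
    try:
        col = {"x": 0, "y": 1}[axis]
    except KeyError:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}") from None
    disp = np.abs(np.diff(pts[:, :, col], axis=0))
    return float(disp.mean())


def pts_check(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 3 or pts.shape[2] != 2:
        raise ValueError("landmarks must have shape (n_frames, l, 2); "
                         "ragged per-frame landmark counts are not supported")
    if not np.all(np.isfinite(pts)):
        raise ValueError("landmark coordinates must be finite")
    return pts


def face_size_motion(roi_pixel_counts: np.ndarray) -> float:
    """FSM = mean absolute change in ROI pixel count between consecutive frames."""
    counts = np.asarray(roi_pixel_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 ROI pixel counts")
    if np.any(counts < 0):
        raise ValueError("ROI pixel counts must be >= 0")
    return float(np.mean(np.abs(np.diff(counts))))


def window_features(
    frames: np.ndarray | FrameSequence,
    landmarks: LandmarkTrack | np.ndarray,
    roi_pixel_counts: np.ndarray,
) -> MotionFeatureVector:
    """Bundle the four motion features for one analysis window.

    The three inputs must cover the same frame range.
    """
    arr = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    pts = landmarks.points if isinstance(landmarks, LandmarkTrack) else pts_check(landmarks)
    counts = np.asarray(roi_pixel_counts)
    if not (arr.shape[0] == pts.shape[0] == counts.shape[0]):
        raise ValueError("frames, landmarks and ROI counts must be aligned")
    return MotionFeatureVector(
        TI=temporal_information(arr),
        FM_X=face_motion(LandmarkTrack(points=pts), "x"),
        FM_Y=face_motion(LandmarkTrack(points=pts), "y"),
        FSM=face_size_motion(counts),
    )
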