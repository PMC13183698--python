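"""rPPG core: ROI masking, BVP extraction (GREEN/CHROM/POS) and HR estimation.

The pipeline mirrors the standard camera-pulse processing chain: rasterize
the convex hull of the facial landmarks (minus eye/mouth hulls) into a binary
skin mask, average the masked pixels per RGB channel per frame, project the
RGB trace onto a 1-D blood-volume-pulse signal, band-limit it to plausible
heart rates, and read the heart rate off the spectral peak with quadratic
(three-point parabolic) interpolation.  Analysis runs on 12-s windows hopped
every second; no detrending or artifact removal is applied between channel
averaging and BVP projection.

Coordinate conventions: 0-based pixel coordinates, x = column, y = row,
origin at the top-left; a pixel belongs to a hull when its center lies
strictly inside or on the hull boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.spatial import ConvexHull, QhullError

from .synthetic import ReferenceTrace

__all__ = [
    "DegenerateROIError",
    "NoEstimateError",
    "ROIMask",
    "BVPSignal",
    "HREstimate",
    "DEFAULT_BAND_HZ",
    "rasterize_roi",
    "channel_means",
    "extract_bvp_green",
    "extract_bvp_chrom",
    "extract_bvp_pos",
    "bandpass_filter",
    "estimate_hr",
    "sliding_windows",
    "reference_hr",
]

#: Heart-rate passband in Hz (39-240 bpm).
DEFAULT_BAND_HZ = (0.65, 4.0)
DEFAULT_FILTER_ORDER = 6
WINDOW_S = 12.0
HOP_S = 1.0
_MIN_NFFT = 8192


class DegenerateROIError(ValueError):
    """Face landmarks do not span a 2-D region (collinear or too few)."""


class NoEstimateError(RuntimeError):
    """No usable spectral peak (empty ROI window or all-zero in-band spectrum)."""


@dataclass
class ROIMask:
    mask: np.ndarray  # (H, W) bool

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class BVPSignal:
    samples: np.ndarray
    fps: float
    method: str  # GREEN | CHROM | POS


@dataclass(frozen=True)
class HREstimate:
    window_end_s: float
    hr_bpm: float
    method: str


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------

def _hull_contains(points: np.ndarray, qx: np.ndarray, qy: np.ndarray,
                   tol: float = 1e-9) -> np.ndarray:
    """Vectorized test: query points inside or on the convex hull of ``points``."""
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise DegenerateROIError(f"degenerate hull: {exc}") from exc
    # hull.equations: outward normals, A @ p + b <= 0 inside
    a = hull.equations[:, :2]
    b = hull.equations[:, 2]
    vals = a[:, 0][:, None] * qx[None, :] + a[:, 1][:, None] * qy[None, :] + b[:, None]
    return np.all(vals <= tol, axis=0)


def rasterize_roi(
    face_points: np.ndarray,
    exclusions: Sequence[np.ndarray] = (),
    frame_shape: tuple[int, int] | None = None,
) -> ROIMask:
    """Rasterize the skin ROI: face hull minus each exclusion hull.

    ``face_points`` is an (l, 2) array of (x, y) landmarks; ``frame_shape``
    is (H, W).  Pixel centers strictly inside or on the face hull boundary are
    included, then pixels inside-or-on any exclusion hull are removed.
    Raises :class:`DegenerateROIError` for collinear landmarks.
    """
    pts = np.asarray(face_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateROIError("need >= 3 face landmarks of shape (l, 2)")
    if frame_shape is None:
        h = int(np.ceil(pts[:, 1].max())) + 1
        w = int(np.ceil(pts[:, 0].max())) + 1
    else:
        h, w = frame_shape
    mask = np.zeros((h, w), dtype=bool)

    x0 = max(0, int(np.floor(pts[:, 0].min())))
    x1 = min(w - 1, int(np.ceil(pts[:, 0].max())))
    y0 = max(0, int(np.floor(pts[:, 1].min())))
    y1 = min(h - 1, int(np.ceil(pts[:, 1].max())))
    if x1 < x0 or y1 < y0:
        return ROIMask(mask=mask)

    gy, gx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    qx = gx.ravel().astype(float)
    qy = gy.ravel().astype(float)
    inside = _hull_contains(pts, qx, qy)
    for excl in exclusions:
        epts = np.asarray(excl, dtype=float)
        if epts.shape[0] >= 3:
            try:
                inside &= ~_hull_contains(epts, qx, qy)
            except DegenerateROIError:
                continue  # degenerate exclusion hull has zero area
    mask[gy.ravel()[inside], gx.ravel()[inside]] = True
    return ROIMask(mask=mask)


def channel_means(frame: np.ndarray, mask: ROIMask | np.ndarray) -> tuple[float, float, float]:
    """Arithmetic mean of each RGB channel over the masked pixels."""
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise NoEstimateError("empty ROI mask: no skin pixels in frame")
    sel = np.asarray(frame, dtype=float)[m]
    return tuple(sel.mean(axis=0))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# BVP extraction
# ---------------------------------------------------------------------------

def _as_rgb_trace(trace: np.ndarray) -> np.ndarray:
    arr = np.asarray(trace, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("RGB trace must have shape (n_frames, 3)")
    if arr.shape[0] < 2:
        raise ValueError("RGB trace must have at least 2 frames")
    return arr


def extract_bvp_green(trace: np.ndarray, fps: float) -> BVPSignal:
    """Baseline BVP: the mean-subtracted green channel."""
    arr = _as_rgb_trace(trace)
    g = arr[:, 1]
    return BVPSignal(samples=g - g.mean(), fps=fps, method="GREEN")


def extract_bvp_chrom(trace: np.ndarray, fps: float) -> BVPSignal:
    """Chrominance-based BVP (CHROM).

    Channels are normalized by their window means; the two chrominance
    combinations X = 3R - 2G and Y = 1.5R + G - 1.5B are mixed with
    alpha = sigma(X)/sigma(Y) to suppress the dominant distortion direction:
    S = X - alpha * Y.  Falls back to S = X when sigma(Y) = 0.
    """
    arr = _as_rgb_trace(trace)
    mean = arr.mean(axis=0)
    if np.any(mean <= 0):
        raise ValueError("CHROM requires strictly positive per-channel means")
    rn, gn, bn = (arr / mean).T
    x = 3.0 * rn - 2.0 * gn
    y = 1.5 * rn + gn - 1.5 * bn
    sy = np.std(y)
    s = x - (np.std(x) / sy) * y if sy > 0 else x
    return BVPSignal(samples=s - s.mean(), fps=fps, method="CHROM")


def extract_bvp_pos(trace: np.ndarray, fps: float) -> BVPSignal:
    """Plane-orthogonal-to-skin BVP (POS).

    With temporally mean-normalized channels, projects onto the plane
    orthogonal to the average skin tone: S1 = G - B, S2 = G + B - 2R, then
    h = S1 + (sigma(S1)/sigma(S2)) * S2.  Falls back to h = S1 when
    sigma(S2) = 0.  Applied over the full analysis window.
    """
    arr = _as_rgb_trace(trace)
    mean = arr.mean(axis=0)
    if np.any(mean <= 0):
        raise ValueError("POS requires strictly positive per-channel means")
    rn, gn, bn = (arr / mean).T
    s1 = gn - bn
    s2 = gn + bn - 2.0 * rn
    sd2 = np.std(s2)
    hsig = s1 + (np.std(s1) / sd2) * s2 if sd2 > 0 else s1
    return BVPSignal(samples=hsig - hsig.mean(), fps=fps, method="POS")


_EXTRACTORS = {
    "GREEN": extract_bvp_green,
    "CHROM": extract_bvp_chrom,
    "POS": extract_bvp_pos,
}


def extract_bvp(trace: np.ndarray, fps: float, method: str) -> BVPSignal:
    """Dispatch to one of the GREEN / CHROM / POS extractors."""
    try:
        return _EXTRACTORS[method.upper()](trace, fps)
    except KeyError:
        raise ValueError(f"unknown BVP method {method!r}") from None


# ---------------------------------------------------------------------------
# filtering and spectral HR
# ---------------------------------------------------------------------------

def bandpass_filter(
    samples: np.ndarray,
    fps: float,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass followed by a Hann taper.

    The Hann window of the full signal length suppresses the spectral leakage
    of the subsequent periodogram.
    """
    x = np.asarray(samples, dtype=float)
    low, high = band_hz
    if not 0 < low < high < fps / 2:
        raise ValueError(f"passband {band_hz} infeasible at fps {fps}")
    sos = sps.butter(order, band_hz, btype="bandpass", fs=fps, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    return filtered * sps.windows.hann(x.size)


def _parabolic_refine(power: np.ndarray, k: int) -> float:
    """Three-point parabolic interpolation of the peak position around bin k."""
    if k <= 0 or k >= power.size - 1:
        return float(k)
    y0, y1, y2 = power[k - 1], power[k], power[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(k)
    delta = 0.5 * (y0 - y2) / denom
    return k + float(np.clip(delta, -0.5, 0.5))


def estimate_hr(
    bvp: BVPSignal | np.ndarray,
    fps: float | None = None,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    window_end_s: float = float("nan"),
    nfft: int | None = None,
) -> HREstimate:
    """Heart rate from the spectral peak of a conditioned BVP signal.

    Power spectral density is taken as a zero-padded periodogram (>= 8192
    points); the in-band maximum is refined by quadratic interpolation on the
    power values of the three bins around the peak, then converted to bpm.
    """
    if isinstance(bvp, BVPSignal):
        x, fs, method = bvp.samples, bvp.fps, bvp.method
    else:
        if fps is None:
            raise ValueError("fps required when passing a raw sample array")
        x, fs, method = np.asarray(bvp, dtype=float), float(fps), "RAW"
    if nfft is None:
        nfft = _MIN_NFFT
        while nfft < x.size:
            nfft *= 2
    spec = np.fft.rfft(x, n=nfft)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not band.any() or not np.any(power[band] > 0):
        raise NoEstimateError("no spectral power inside the heart-rate band")
    k = int(np.flatnonzero(band)[np.argmax(power[band])])
    k_ref = _parabolic_refine(power, k)
    hr = 60.0 * k_ref * fs / nfft
    return HREstimate(window_end_s=window_end_s, hr_bpm=float(hr), method=method)


# ---------------------------------------------------------------------------
# windowing and reference
# ---------------------------------------------------------------------------

def sliding_windows(
    n_frames: int,
    fps: float,
    window_s: float = WINDOW_S,
    hop_s: float = HOP_S,
) -> list[tuple[int, int, float]]:
    """(start_frame, end_frame_exclusive, window_end_s) for each whole second.

    One window per integer second t >= window_s, covering (t - window_s, t].
    Videos shorter than one window yield an empty list.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if window_s <= hop_s or hop_s <= 0:
        raise ValueError("need window_s > hop_s > 0")
    duration = n_frames / fps
    out = []
    t = window_s
    win_frames = int(round(window_s * fps))
    while t <= duration + 1e-9:
        end = int(round(t * fps))
        start = end - win_frames
        if start >= 0 and end <= n_frames:
            out.append((start, end, float(t)))
        t += hop_s
    return out


def reference_hr(
    reference: ReferenceTrace,
    t_start: float,
    t_end: float,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> float:
    """Ground-truth HR for the window (t_start, t_end].

    Mean of the reference instantaneous-HR samples inside the window; if the
    trace carries no HR channel, falls back to the same spectral-peak
    estimator applied to the reference waveform.
    """
    sel = (reference.time_s > t_start) & (reference.time_s <= t_end)
    if not sel.any():
        raise ValueError(f"reference trace does not overlap window ({t_start}, {t_end}]")
    hr = np.asarray(reference.hr_bpm, dtype=float)
    if hr.size and np.all(np.isfinite(hr[sel])):
        return float(hr[sel].mean())
    ppg = np.asarray(reference.ppg, dtype=float)[sel]
    conditioned = bandpass_filter(ppg - ppg.mean(), reference.sample_rate, band_hz)
    return estimate_hr(conditioned, reference.sample_rate, band_hz).hr_bpm
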