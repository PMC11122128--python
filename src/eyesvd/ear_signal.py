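"""Eye-aspect-ratio (EAR) baseline signal.

EAR = (||p2 - p6|| + ||p3 - p5||) / (2 ||p1 - p4||): eye height over eye
width from the 6-point eye contour (p1/p4 the horizontal corners, p2/p3 the
upper lid, p6/p5 the lower lid).  The ratio is scale-invariant and dips to
~0 during blinks, but is blind to pupil position — the limitation that
motivates the SVD-based signal.

Per-session processing: missing values (failed landmark detection) are
linearly interpolated; the series is then robustly standardized with the
median and median absolute deviation (MAD) of the first 20 s of the session,
under the assumption that participants are attentive at session start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .svd_signal import TemporalSignal, preprocess_signal

__all__ = [
    "EARSeries",
    "compute_ear",
    "ear_series_from_landmarks",
    "interpolate_missing",
    "robust_scale",
    "ear_temporal_signal",
    "CALIBRATION_SECONDS",
]

CALIBRATION_SECONDS = 20.0


@dataclass
class EARSeries:
    """Per-frame EAR values (NaN = missing) at a known frame rate."""

    values: np.ndarray
    fps: float = 30.0
    baseline_stats: tuple[float, float] | None = None  # (median, MAD)

    def __len__(self) -> int:
        return len(self.values)


def compute_ear(p1, p2, p3, p4, p5, p6) -> float:
    """Eye aspect ratio from the six contour points (each an (x, y) pair)."""
    p1, p2, p3, p4, p5, p6 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4, p5, p6))
    width = np.linalg.norm(p1 - p4)
    if width == 0:
        raise ValueError("zero eye width")
    return float((np.linalg.norm(p2 - p6) + np.linalg.norm(p3 - p5)) / (2.0 * width))


def ear_series_from_landmarks(landmarks: np.ndarray, fps: float = 30.0) -> EARSeries:
    """EAR per frame from a (k, 6, 2) landmark track (NaN rows = missing)."""
    landmarks = np.asarray(landmarks, dtype=float)
    k = landmarks.shape[0]
    vals = np.full(k, np.nan)
    for i in range(k):
        pts = landmarks[i]
        if np.any(~np.isfinite(pts)):
            continue
        vals[i] = compute_ear(*pts)
    return EARSeries(values=vals, fps=fps)


def interpolate_missing(series: EARSeries) -> EARSeries:
    """Linear interpolation of interior gaps; edge gaps take the nearest
    observed value (linear interpolation is undefined there)."""
    vals = np.asarray(series.values, dtype=float)
    if np.all(np.isnan(vals)):
        raise ValueError("all values missing")
    s = pd.Series(vals).interpolate(method="linear", limit_area="inside")
    s = s.ffill().bfill()
    return EARSeries(values=s.to_numpy(), fps=series.fps, baseline_stats=series.baseline_stats)


def robust_scale(series: EARSeries, calibration_seconds: float = CALIBRATION_SECONDS) -> EARSeries:
    """Robust z-score against the session's calibration window.

    value -> (value - median_cal) / MAD_cal, where median/MAD come from the
    first ``calibration_seconds`` of the (gap-free) series.  MAD is the raw
    median absolute deviation (no normal-consistency factor).  Degenerate
    fallbacks: a zero calibration MAD falls back to the full-session MAD;
    if that is also zero the series is centered only.
    """
    vals = np.asarray(series.values, dtype=float)
    if np.any(np.isnan(vals)):
        raise ValueError("interpolate before scaling")
    n_cal = min(len(vals), int(round(calibration_seconds * series.fps)))
    if n_cal < 1:
        raise ValueError("empty calibration window")
    cal = vals[:n_cal]
    med = float(np.median(cal))
    mad = float(np.median(np.abs(cal - med)))
    if mad == 0:
        mad = float(np.median(np.abs(vals - np.median(vals))))
    scaled = (vals - med) / mad if mad > 0 else vals - med
    return EARSeries(values=scaled, fps=series.fps, baseline_stats=(med, mad))


def ear_temporal_signal(
    landmarks: np.ndarray, fps: float = 30.0, scale: bool = True
) -> TemporalSignal:
    """Full EAR baseline pipeline ending in a [0, 1] TemporalSignal.

    Raw EAR -> gap interpolation -> (optional) robust per-session scaling ->
    min–max scaling to [0, 1] (no smoothing; the moving average belongs to
    the SVD pipeline).  Feature extraction consumes the result.
    """
    series = ear_series_from_landmarks(landmarks, fps=fps)
    series = interpolate_missing(series)
    if scale:
        series = robust_scale(series)
    sig = preprocess_signal(series.values, window=1, fps=fps, source="ear")
    return sig
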