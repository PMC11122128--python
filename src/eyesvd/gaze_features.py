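"""Gaze baseline: horizontal fixation/saccade metrics from an iris track.

Each frame after the first is classified against its predecessor's
horizontal iris position: a displacement of at least the threshold (default
1 pixel) marks a saccade; exactly zero displacement marks a fixation;
sub-threshold non-zero drift (possible with sub-pixel tracking) is left
unlabeled.  The three sequence-level features are the fixation and saccade
percentages (over the k-1 decidable frames) and the mean saccade velocity
(total pixel movement over saccade frames divided by their count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IrisTrack",
    "GazeFeatureVector",
    "classify_frames",
    "gaze_summary",
    "FIXATION",
    "SACCADE",
    "UNLABELED",
]

FIXATION = "fixation"
SACCADE = "saccade"
UNLABELED = "unlabeled"

DEFAULT_THRESHOLD = 1.0


@dataclass
class IrisTrack:
    """Per-frame horizontal iris coordinate in pixels (NaN = missing)."""

    x: np.ndarray
    fps: float = 30.0

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class GazeFeatureVector:
    fixation_pct: float
    saccade_pct: float
    saccade_velocity: float  # pixels/frame

    def as_dict(self) -> dict[str, float]:
        return {
            "horizontal fixation percentage": self.fixation_pct,
            "horizontal saccade percentage": self.saccade_pct,
            "horizontal saccade velocity": self.saccade_velocity,
        }


def _clean_track(track: IrisTrack | np.ndarray) -> np.ndarray:
    x = track.x if isinstance(track, IrisTrack) else track
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 frames")
    if np.all(np.isnan(x)):
        raise ValueError("all iris positions missing")
    if np.any(np.isnan(x)):
        s = pd.Series(x).interpolate(method="linear", limit_area="inside").ffill().bfill()
        x = s.to_numpy()
    return x


def classify_frames(track: IrisTrack | np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> list[str]:
    """Per-frame labels; frame 1 has no predecessor and stays unlabeled."""
    x = _clean_track(track)
    labels = [UNLABELED]
    for dx in np.abs(np.diff(x)):
        if dx >= threshold:
            labels.append(SACCADE)
        elif dx == 0:
            labels.append(FIXATION)
        else:
            labels.append(UNLABELED)
    return labels


def gaze_summary(
    track: IrisTrack | np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    velocity_mode: str = "pooled",
) -> GazeFeatureVector:
    """Sequence-level gaze features.

    Percentages use the k-1 decidable frames as denominator, so that a
    constant track yields fixation_pct = 1.  Velocity by default pools all
    saccade frames — sum of absolute displacements over the number of
    saccade frames (0 when there are none); ``velocity_mode="per_episode"``
    instead averages the mean velocity of each run of consecutive saccade
    frames.
    """
    x = _clean_track(track)
    dx = np.abs(np.diff(x))
    n = len(dx)  # k - 1 decidable frames
    sacc = dx >= threshold
    fix = dx == 0
    n_sacc = int(sacc.sum())
    if n_sacc == 0:
        velocity = 0.0
    elif velocity_mode == "pooled":
        velocity = float(dx[sacc].sum() / n_sacc)
    elif velocity_mode == "per_episode":
        bounded = np.concatenate(([False], sacc, [False]))
        starts = np.flatnonzero(bounded[1:] & ~bounded[:-1])
        ends = np.flatnonzero(~bounded[1:] & bounded[:-1])
        velocity = float(np.mean([dx[s:e].mean() for s, e in zip(starts, ends)]))
    else:
        raise ValueError(f"unknown velocity_mode {velocity_mode!r}")
    return GazeFeatureVector(
        fixation_pct=float(fix.sum() / n),
        saccade_pct=float(n_sacc / n),
        saccade_velocity=velocity,
    )
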