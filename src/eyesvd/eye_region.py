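"""Eye-region cropping from per-frame facial landmarks.

In the 98-point facial-landmark layout, the left-eye contour occupies
points 60–67 and the right-eye contour points 68–75.  A standardized eye
crop is obtained by taking the axis-aligned bounding box of the eye
landmarks, expanding it by a margin (default 25% of the box's own width and
height on each side), clamping to the image, and resizing to a fixed output
size (default 96 x 128) with bilinear interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

logger = logging.getLogger(__name__)

__all__ = [
    "LEFT_EYE_INDICES",
    "RIGHT_EYE_INDICES",
    "LandmarkFrame",
    "EyeCropSequence",
    "crop_eye",
    "crop_sequence",
    "to_grayscale",
]

LEFT_EYE_INDICES = tuple(range(60, 68))
RIGHT_EYE_INDICES = tuple(range(68, 76))

# Rec. 601 luma weights for color -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

DEFAULT_OUT_SIZE = (96, 128)  # (height, width)
DEFAULT_MARGIN = 0.25


@dataclass
class LandmarkFrame:
    """Eye landmarks for one frame: an (n, 2) array of (x, y) points."""

    points: np.ndarray
    frame_index: int = 0
    eye_side: str = "left"


@dataclass
class EyeCropSequence:
    """A stack of k same-size grayscale eye crops at a known frame rate."""

    frames: np.ndarray  # (k, H, W)
    fps: float = 30.0
    source_eye: str = "left"
    fill_flags: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __len__(self) -> int:
        return len(self.frames)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Standard luma conversion for color input; identity for grayscale."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        return frame @ _LUMA
    return frame


def expanded_box(
    points: np.ndarray, margin: float, frame_shape: tuple[int, int]
) -> tuple[float, float, float, float]:
    """Landmark bounding box expanded by ``margin`` x box-dimension per side
    and clamped to the frame.  Returns (x0, x1, y0, y1)."""
    pts = np.asarray(points, dtype=float)
    x0, y0 = pts[:, 0].min(), pts[:, 1].min()
    x1, y1 = pts[:, 0].max(), pts[:, 1].max()
    bw, bh = x1 - x0, y1 - y0
    if bw <= 0 or bh <= 0:
        raise ValueError("degenerate landmark bounding box")
    h, w = frame_shape
    if x0 < 0 or y0 < 0 or x1 > w - 1 or y1 > h - 1:
        logger.warning("eye landmarks outside frame; crop clamped to borders")
    x0e = max(0.0, x0 - margin * bw)
    x1e = min(float(w), x1 + margin * bw)
    y0e = max(0.0, y0 - margin * bh)
    y1e = min(float(h), y1 + margin * bh)
    return x0e, x1e, y0e, y1e


def crop_eye(
    frame: np.ndarray,
    eye_landmarks: LandmarkFrame | np.ndarray,
    margin: float = DEFAULT_MARGIN,
    out_size: tuple[int, int] = DEFAULT_OUT_SIZE,
) -> np.ndarray:
    """Crop the margin-expanded landmark box and resize to ``out_size``.

    Sub-pixel box edges are rounded outward to whole pixels before the
    resize, so a margin of 0 reproduces the tight integer bounding box.
    """
    pts = eye_landmarks.points if isinstance(eye_landmarks, LandmarkFrame) else eye_landmarks
    gray = to_grayscale(frame)
    x0, x1, y0, y1 = expanded_box(pts, margin, gray.shape)
    xi0, xi1 = int(np.floor(x0)), int(np.ceil(x1)) + 1
    yi0, yi1 = int(np.floor(y0)), int(np.ceil(y1)) + 1
    xi1 = min(xi1, gray.shape[1])
    yi1 = min(yi1, gray.shape[0])
    patch = gray[yi0:yi1, xi0:xi1]
    out = resize(
        patch, out_size, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )
    return out.astype(float)


def crop_sequence(
    frames,
    landmark_track,
    eye_side: str = "left",
    margin: float = DEFAULT_MARGIN,
    out_size: tuple[int, int] = DEFAULT_OUT_SIZE,
    fps: float = 30.0,
) -> EyeCropSequence:
    """Per-frame crops with missing-landmark handling.

    ``landmark_track`` is a sequence (one entry per frame) of landmark
    arrays/LandmarkFrames, with ``None`` marking frames where detection
    failed.  Missing frames repeat the previous crop and are flagged; a
    missing head of the sequence is back-filled from the first detected
    frame.  All frames missing is an error.
    """
    n = len(frames)
    if n == 0 or len(landmark_track) != n:
        raise ValueError("need one landmark entry per frame")
    if all(lm is None for lm in landmark_track):
        raise ValueError("all frames missing landmarks")

    crops: list[np.ndarray | None] = [None] * n
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        if landmark_track[i] is not None:
            crops[i] = crop_eye(frames[i], landmark_track[i], margin, out_size)
        else:
            flags[i] = True
    # forward-fill, then back-fill the leading gap
    last = None
    for i in range(n):
        if crops[i] is None:
            crops[i] = last
        else:
            last = crops[i]
    first = next(c for c in crops if c is not None)
    for i in range(n):
        if crops[i] is None:
            crops[i] = first
    return EyeCropSequence(
        frames=np.stack(crops), fps=fps, source_eye=eye_side, fill_flags=flags
    )
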