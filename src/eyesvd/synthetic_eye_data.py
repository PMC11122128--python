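"""Synthetic eye-image sequence generator.

Renders parameterized 20-s, 30-FPS grayscale eye-crop sequences (96x128 by
default) with ground-truth blink, pupil-saccade and head-motion events, so
that signal extraction, feature engineering and classification can all be
exercised and validated without access to restricted webcam recordings.

The eye is modeled as a light sclera ellipse (the palpebral fissure) on a
darker skin background, with a dark pupil disc that is clipped by the eyelid
opening.  Three behavioral regimes mirror the attentional states seen in
webcam studies of online learners:

* ``Focus`` — the eye boundary is stationary apart from blinks while the
  pupil makes frequent horizontal saccades separated by short fixations.
* ``nonFocus_fixation`` — mind-wandering with a long fixation: the pupil is
  inactive outside blinks.
* ``nonFocus_headmotion`` — mind-wandering with head movement: slow
  sinusoidal whole-frame translation and rotation on top of an inactive
  pupil.

The regimes deliberately share the same blink statistics: blink rate is not
the discriminating behavior here, pupil and head activity are, which is
exactly the contrast the SVD-based signal is designed to capture and the
eye-aspect-ratio baseline cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "EyeSceneParams",
    "BehaviorRegime",
    "GroundTruthLog",
    "FOCUS",
    "NONFOCUS_FIXATION",
    "NONFOCUS_HEADMOTION",
    "DEFAULT_REGIMES",
    "render_eye_frame",
    "generate_sequence",
    "generate_dataset",
    "landmarks_from_log",
]


@dataclass(frozen=True)
class EyeSceneParams:
    """Scene geometry, photometry and noise for one rendered eye crop.

    Intensities are on the 8-bit [0, 255] scale; geometry is in pixels.
    ``landmark_noise_sigma`` models the sub-pixel jitter of an upstream
    landmark detector and only affects emitted landmark tracks, never the
    rendered images.
    """

    image_height: int = 96
    image_width: int = 128
    fps: float = 30.0
    duration: float = 20.0
    eyelid_aperture_open: float = 40.0
    pupil_radius: float = 12.0
    iris_x_range: tuple[float, float] = (40.0, 88.0)
    background_intensity: float = 110.0
    sclera_intensity: float = 230.0
    pupil_intensity: float = 30.0
    noise_sigma: float = 2.0
    landmark_noise_sigma: float = 0.0
    seed: int = 0

    # Horizontal semi-axis of the eyelid ellipse (eye half-width).
    @property
    def eye_half_width(self) -> float:
        return 0.4 * self.image_width

    @property
    def center(self) -> tuple[float, float]:
        # Pixel-center coordinates; (W-1)/2 keeps mirror symmetry exact.
        return ((self.image_width - 1) / 2.0, (self.image_height - 1) / 2.0)

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not self.pupil_radius < self.image_height / 2:
            raise ValueError("pupil_radius must be < image_height/2")
        if self.noise_sigma < 0 or self.landmark_noise_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.eyelid_aperture_open < 0:
            raise ValueError("eyelid_aperture_open must be non-negative")


@dataclass(frozen=True)
class BehaviorRegime:
    """Event rates and amplitudes defining one attentional-state regime.

    Rates are events/minute; amplitudes in pixels (translation, saccade) or
    degrees (rotation); durations/dwells in frames.
    """

    label: str  # {"Focus", "nonFocus_fixation", "nonFocus_headmotion"}
    blink_rate: float = 12.0
    blink_duration: int = 9
    saccade_rate: float = 0.0
    saccade_amplitude: float = 8.0
    fixation_dwell: int = 8
    head_translation_amplitude: float = 0.0
    head_rotation_amplitude: float = 0.0

    @property
    def binary_label(self) -> int:
        return 1 if self.label == "Focus" else 0

    def validate(self) -> None:
        for name in (
            "blink_rate",
            "saccade_rate",
            "saccade_amplitude",
            "head_translation_amplitude",
            "head_rotation_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.blink_duration < 1 or self.fixation_dwell < 1:
            raise ValueError("durations must be >= 1 frame")


FOCUS = BehaviorRegime(label="Focus", saccade_rate=60.0, saccade_amplitude=8.0)
NONFOCUS_FIXATION = BehaviorRegime(label="nonFocus_fixation", saccade_rate=0.0)
NONFOCUS_HEADMOTION = BehaviorRegime(
    label="nonFocus_headmotion",
    saccade_rate=0.0,
    head_translation_amplitude=6.0,
    head_rotation_amplitude=5.0,
)
DEFAULT_REGIMES = (FOCUS, NONFOCUS_FIXATION, NONFOCUS_HEADMOTION)


@dataclass
class GroundTruthLog:
    """Per-sequence ground truth emitted alongside the rendered frames."""

    blink_frames: list[int] = field(default_factory=list)  # blink apices
    saccade_frames: list[int] = field(default_factory=list)  # jump frames
    aperture_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    iris_x_series: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_eye_frame(
    aperture: float, iris_x: float, params: EyeSceneParams, rng=None
) -> np.ndarray:
    """Render one grayscale eye crop as a float array in [0, 255].

    The sclera is an axis-aligned ellipse with vertical semi-axis
    ``aperture/2``; the pupil is a disc of ``pupil_radius`` centered at
    ``iris_x`` and drawn only where it falls inside the eyelid opening.
    Pixel membership is evaluated at integer pixel centers.  Additive
    Gaussian noise of ``noise_sigma`` is applied (from ``rng`` when given),
    then values are clipped to [0, 255].
    """
    params.validate()
    if not 0 <= aperture <= params.eyelid_aperture_open:
        raise ValueError("aperture out of [0, eyelid_aperture_open]")
    if not 0 <= iris_x <= params.image_width - 1:
        raise ValueError("iris_x outside image width")

    h, w = params.image_height, params.image_width
    cx, cy = params.center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    img = np.full((h, w), params.background_intensity, dtype=float)
    a = params.eye_half_width
    b = aperture / 2.0
    if b > 0:
        inside_lid = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        img[inside_lid] = params.sclera_intensity
        pupil = (xx - iris_x) ** 2 + (yy - cy) ** 2 <= params.pupil_radius**2
        img[pupil & inside_lid] = params.pupil_intensity

    if params.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 255.0)


# ---------------------------------------------------------------------------
# Event scheduling
# ---------------------------------------------------------------------------

def _schedule_events(n_events: int, k: int, half_span: int, rng) -> np.ndarray:
    """Place ``n_events`` apex frames roughly evenly over ``k`` frames with
    jitter, keeping events at least ``2*half_span+1`` frames apart and clear
    of the sequence boundaries."""
    if n_events <= 0:
        return np.empty(0, dtype=int)
    slot = k / n_events
    jitter = max(0.0, slot / 2.0 - half_span - 1)
    apices = []
    for i in range(n_events):
        center = (i + 0.5) * slot
        apex = int(round(center + rng.uniform(-jitter, jitter)))
        apex = int(np.clip(apex, half_span, k - 1 - half_span))
        if apices and apex - apices[-1] < 2 * half_span + 1:
            apex = apices[-1] + 2 * half_span + 1
            if apex > k - 1 - half_span:
                break
        apices.append(apex)
    return np.asarray(apices, dtype=int)


def _aperture_series(regime: BehaviorRegime, params: EyeSceneParams, rng):
    """Per-frame eyelid aperture with symmetric linear close–open blinks."""
    k = params.n_frames
    n_blinks = int(round(regime.blink_rate * params.duration / 60.0))
    half = regime.blink_duration // 2
    apices = _schedule_events(n_blinks, k, half, rng)
    ap = np.full(k, params.eyelid_aperture_open, dtype=float)
    open_ap = params.eyelid_aperture_open
    for apex in apices:
        for off in range(-half, half + 1):
            t = apex + off
            if 0 <= t < k:
                frac = abs(off) / max(half, 1)  # 0 at apex -> closed
                ap[t] = min(ap[t], open_ap * frac)
        ap[apex] = 0.0
    return ap, apices.tolist()


def _iris_series(regime: BehaviorRegime, params: EyeSceneParams, rng):
    """Per-frame horizontal iris position: piecewise-constant fixations
    separated by instantaneous saccade jumps."""
    k = params.n_frames
    lo, hi = params.iris_x_range
    x0 = (lo + hi) / 2.0
    n_sacc = int(round(regime.saccade_rate * params.duration / 60.0))
    if n_sacc <= 0:
        return np.full(k, x0, dtype=float), []
    jump_frames = _schedule_events(n_sacc, k, regime.fixation_dwell // 2, rng)
    xs = np.empty(k, dtype=float)
    x = x0
    jumps = set(jump_frames.tolist())
    for t in range(k):
        if t in jumps:
            amp = regime.saccade_amplitude
            # choose the direction that stays in range; random when both fit
            candidates = [x + amp, x - amp]
            feasible = [c for c in candidates if lo <= c <= hi]
            if feasible:
                x = feasible[int(rng.integers(len(feasible)))]
            else:
                x = float(np.clip(x + amp * rng.choice([-1.0, 1.0]), lo, hi))
        xs[t] = x
    return xs, sorted(jumps)


def _head_motion(regime: BehaviorRegime, params: EyeSceneParams, rng):
    """Slowly varying whole-frame translation (px) and rotation (deg)."""
    k = params.n_frames
    t = np.arange(k) / params.fps
    if regime.head_translation_amplitude == 0 and regime.head_rotation_amplitude == 0:
        z = np.zeros(k)
        return z, z, z
    f_tr = rng.uniform(0.2, 0.6)  # Hz, slow drift
    f_rot = rng.uniform(0.2, 0.6)
    ph = rng.uniform(0, 2 * np.pi, size=3)
    dx = regime.head_translation_amplitude * np.sin(2 * np.pi * f_tr * t + ph[0])
    dy = 0.5 * regime.head_translation_amplitude * np.sin(2 * np.pi * f_tr * t + ph[1])
    rot = regime.head_rotation_amplitude * np.sin(2 * np.pi * f_rot * t + ph[2])
    return dx, dy, rot


# ---------------------------------------------------------------------------
# Sequence and dataset generation
# ---------------------------------------------------------------------------

def generate_sequence(
    regime: BehaviorRegime, params: EyeSceneParams
) -> tuple[np.ndarray, GroundTruthLog, int]:
    """Render a full labeled sequence for one regime.

    Returns ``(frames, log, label)`` where ``frames`` is a ``(k, H, W)``
    uint8 array, ``log`` carries the ground-truth event series,
    and ``label`` is 1 for Focus, 0 otherwise.  The same
    ``(regime, params)`` pair (including ``params.seed``) reproduces
    bit-identical output.
    """
    regime.validate()
    params.validate()
    rng = np.random.default_rng(params.seed)
    ap, blink_frames = _aperture_series(regime, params, rng)
    xs, saccade_frames = _iris_series(regime, params, rng)
    dx, dy, rot = _head_motion(regime, params, rng)

    k = params.n_frames
    frames = np.empty((k, params.image_height, params.image_width), dtype=np.uint8)
    has_head_motion = (
        regime.head_translation_amplitude > 0 or regime.head_rotation_amplitude > 0
    )
    for i in range(k):
        img = render_eye_frame(ap[i], xs[i], params, rng=rng)
        if has_head_motion:
            if rot[i] != 0.0:
                img = ndimage.rotate(
                    img,
                    rot[i],
                    reshape=False,
                    order=1,
                    mode="constant",
                    cval=params.background_intensity,
                )
            if dx[i] != 0.0 or dy[i] != 0.0:
                img = ndimage.shift(
                    img,
                    (dy[i], dx[i]),
                    order=1,
                    mode="constant",
                    cval=params.background_intensity,
                )
            img = np.clip(img, 0.0, 255.0)
        frames[i] = np.round(img).astype(np.uint8)

    log = GroundTruthLog(
        blink_frames=blink_frames,
        saccade_frames=saccade_frames,
        aperture_series=ap,
        iris_x_series=xs,
    )
    return frames, log, regime.binary_label


def landmarks_from_log(
    log: GroundTruthLog, params: EyeSceneParams, rng=None
) -> np.ndarray:
    """Emit per-frame 6-point eye-contour landmarks (p1..p6) consistent with
    the rendered eyelid ellipse.

    Returns a ``(k, 6, 2)`` array of (x, y) points: p1/p4 are the horizontal
    eye corners, p2/p3 the upper-lid points and p6/p5 the lower-lid points at
    ±a/2 from center.  Gaussian jitter of ``params.landmark_noise_sigma`` is
    added when non-zero, emulating an imperfect landmark detector.
    """
    k = len(log.aperture_series)
    cx, cy = params.center
    a = params.eye_half_width
    pts = np.empty((k, 6, 2), dtype=float)
    for i, ap in enumerate(log.aperture_series):
        b = ap / 2.0
        h = b * np.sqrt(3.0) / 2.0 * 2.0  # ellipse height at x = ±a/2
        half_h = h / 2.0
        pts[i] = [
            (cx - a, cy),            # p1: outer corner
            (cx - a / 2, cy - half_h),  # p2: upper lid
            (cx + a / 2, cy - half_h),  # p3: upper lid
            (cx + a, cy),            # p4: inner corner
            (cx + a / 2, cy + half_h),  # p5: lower lid
            (cx - a / 2, cy + half_h),  # p6: lower lid
        ]
    if params.landmark_noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed + 1)
        pts = pts + rng.normal(0.0, params.landmark_noise_sigma, size=pts.shape)
    return pts


def dataset_plan(
    n_sequences: int,
    focus_fraction: float = 5.0 / 6.0,
    regimes: tuple[BehaviorRegime, ...] = DEFAULT_REGIMES,
    seed: int = 0,
) -> list[tuple[BehaviorRegime, int]]:
    """Deterministic (regime, per-sequence seed) plan for a dataset.

    ``round(n_sequences * focus_fraction)`` sequences come from the Focus
    regime(s); the remainder cycle through the non-Focus regimes.
    Per-sequence seeds are drawn deterministically from the master ``seed``.
    """
    if n_sequences < 2:
        raise ValueError("n_sequences must be >= 2")
    if not 0 < focus_fraction < 1:
        raise ValueError("focus_fraction must be in (0, 1)")
    focus_regimes = [r for r in regimes if r.binary_label == 1]
    nonfocus_regimes = [r for r in regimes if r.binary_label == 0]
    if not focus_regimes or not nonfocus_regimes:
        raise ValueError("regimes must include both classes")
    n_focus = int(round(n_sequences * focus_fraction))
    n_focus = min(max(n_focus, 1), n_sequences - 1)
    rng = np.random.default_rng(seed)
    seq_seeds = rng.integers(0, 2**31 - 1, size=n_sequences)
    plan = []
    for i in range(n_sequences):
        if i < n_focus:
            regime = focus_regimes[i % len(focus_regimes)]
        else:
            regime = nonfocus_regimes[(i - n_focus) % len(nonfocus_regimes)]
        plan.append((regime, int(seq_seeds[i])))
    return plan


def generate_dataset(
    n_sequences: int,
    focus_fraction: float = 5.0 / 6.0,
    params: EyeSceneParams | None = None,
    regimes: tuple[BehaviorRegime, ...] = DEFAULT_REGIMES,
    seed: int = 0,
):
    """Generate a labeled collection of sequences at a given class balance.

    Returns a list of ``(frames, log, label, regime_label)`` tuples.  For
    large datasets prefer iterating over :func:`dataset_plan` and calling
    :func:`generate_sequence` per entry to keep one sequence in memory at
    a time.
    """
    if params is None:
        params = EyeSceneParams()
    out = []
    for regime, seq_seed in dataset_plan(n_sequences, focus_fraction, regimes, seed):
        frames, log, label = generate_sequence(regime, replace(params, seed=seq_seed))
        out.append((frames, log, label, regime.label))
    return out
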