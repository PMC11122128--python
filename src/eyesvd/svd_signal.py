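"""SVD-based 1D temporal eye-signal extraction.

The central idea: a cropped eye-image sequence of k frames is summarized by
a k x d block-energy matrix E, whose rows hold the per-frame sum of squared
pixel intensities in each of d spatial blocks.  A thin singular value
decomposition E = U S V^T separates this spatiotemporal matrix into temporal
(U) and spatial (V) bases.  The first left singular vector u1 carries the
low-rank, quasi-static content of the sequence; the higher-rank vectors
u2, u3, ... carry sparse/high-frequency temporal change — blinks, pupil
saccades, head-motion transients.  The vector whose spectrum has the largest
single-bin magnitude inside a predefined frequency band is selected as the
1D temporal eye-change signal, then min–max scaled to [0, 1] and smoothed
with a short moving average.

Unlike the eye-aspect-ratio baseline, which sees only the eye boundary, this
signal responds to *any* temporal change in the eye region, including pupil
movement with a stationary boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlockGrid",
    "EnergyMatrix",
    "SVDResult",
    "TemporalSignal",
    "compute_energy_matrix",
    "decompose_energy",
    "select_signal_vector",
    "preprocess_signal",
    "extract_svd_signal",
    "DEFAULT_BAND",
    "DEFAULT_WINDOW",
    "DEFAULT_MAX_RANK",
    "RANK_TOL",
]

# Defaults: 6x8 grid gives 16x16-pixel blocks on a 96x128 crop (d = 48,
# well below k = 600 so the thin SVD is well-posed).  The selection band
# [2, 15] Hz at 30 FPS targets the transient (high-frequency) range where
# blink and saccade events concentrate, below Nyquist and above the slow
# gaze-level/illumination drift that otherwise dominates low bins.  The
# 5-frame moving average is ~167 ms at 30 FPS.
DEFAULT_GRID_SHAPE = (6, 8)
DEFAULT_BAND = (2.0, 15.0)
DEFAULT_WINDOW = 5
DEFAULT_MAX_RANK = 10
DEFAULT_SELECTION = "band_power"  # or "max_bin"
# Relative singular-value threshold below which a left singular vector is an
# arbitrary orthonormal-complement direction (numerically null space) and is
# treated as information-free.
RANK_TOL = 1e-10
# Candidate energy floor: min-max scaling makes the frequency score blind to
# a vector's share of the matrix energy, so sensor-noise directions (broad,
# flat spectra) would otherwise compete on shape alone.  Vectors below
# ENERGY_FLOOR * sigma_1 are excluded from selection; if none qualify the
# pool falls back to all of u_2..u_max_rank.
ENERGY_FLOOR = 0.01


@dataclass(frozen=True)
class BlockGrid:
    rows: int = DEFAULT_GRID_SHAPE[0]
    cols: int = DEFAULT_GRID_SHAPE[1]

    @property
    def d(self) -> int:
        return self.rows * self.cols

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1 or self.d < 2:
            raise ValueError("grid must have at least 2 blocks")


@dataclass
class EnergyMatrix:
    """k x d matrix of per-frame, per-block pixel energies."""

    E: np.ndarray
    grid: BlockGrid

    @property
    def k(self) -> int:
        return self.E.shape[0]

    @property
    def d(self) -> int:
        return self.E.shape[1]


@dataclass
class SVDResult:
    """Thin SVD of an energy matrix: U (k x p), S (p,), V (d x p)."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray

    @property
    def p(self) -> int:
        return len(self.S)


@dataclass
class TemporalSignal:
    """A length-k series in [0, 1] at a known frame rate."""

    values: np.ndarray
    fps: float
    source: str  # {"svd", "ear"}
    selected_rank: int | None = None

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Energy matrix
# ---------------------------------------------------------------------------

def _to_unit_intensity(frame: np.ndarray) -> np.ndarray:
    """8-bit integer frames are mapped to [0, 1]; float frames are assumed
    to already be on the intended scale and are used as-is."""
    frame = np.asarray(frame)
    if np.issubdtype(frame.dtype, np.integer):
        return frame.astype(float) / 255.0
    return frame.astype(float)


def compute_energy_matrix(frames, grid: BlockGrid | None = None) -> EnergyMatrix:
    """Sum-of-squared-intensity block energies for every frame.

    ``frames`` is a ``(k, H, W)`` stack or an object with a ``.frames``
    attribute.  Frames whose height/width is not divisible by the grid are
    cropped at the bottom/right edge to the largest tiling size.
    """
    if grid is None:
        grid = BlockGrid()
    stack = getattr(frames, "frames", frames)
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("expected a non-empty (k, H, W) frame stack")
    k, h, w = stack.shape
    bh, bw = h // grid.rows, w // grid.cols
    if bh < 1 or bw < 1:
        raise ValueError("grid finer than the image")
    hh, ww = bh * grid.rows, bw * grid.cols
    x = _to_unit_intensity(stack[:, :hh, :ww])
    sq = x * x
    # (k, rows, bh, cols, bw) -> sum over within-block axes
    blocks = sq.reshape(k, grid.rows, bh, grid.cols, bw)
    E = blocks.sum(axis=(2, 4)).reshape(k, grid.d)
    return EnergyMatrix(E=E, grid=grid)


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

def decompose_energy(energy: EnergyMatrix | np.ndarray) -> SVDResult:
    """Thin SVD of E with singular values in descending order."""
    E = energy.E if isinstance(energy, EnergyMatrix) else np.asarray(energy, float)
    if E.ndim != 2 or E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("E must be k x d with k, d >= 2")
    if not np.all(np.isfinite(E)):
        raise ValueError("E contains non-finite entries")
    U, S, Vt = np.linalg.svd(E, full_matrices=False)
    return SVDResult(U=U, S=S, V=Vt.T)


# ---------------------------------------------------------------------------
# Preprocessing and selection
# ---------------------------------------------------------------------------

def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation: boundary samples
    average over the part of the window that fits inside the series."""
    k = len(v)
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate(([0.0], np.cumsum(v)))
    lo = np.clip(np.arange(k) - left, 0, k)
    hi = np.clip(np.arange(k) + right + 1, 0, k)
    return (csum[hi] - csum[lo]) / (hi - lo)


def preprocess_signal(
    v: np.ndarray, window: int = DEFAULT_WINDOW, fps: float = 30.0, source: str = "svd"
) -> TemporalSignal:
    """Min–max scale a raw vector to [0, 1], then smooth.

    A constant vector carries no temporal information and maps to the
    midpoint 0.5 everywhere.  The moving average is centered with edge
    truncation, so the output length equals the input length.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("signal contains non-finite values")
    if window < 1 or len(v) < window:
        raise ValueError("need length >= window >= 1")
    vmin, vmax = v.min(), v.max()
    if vmax - vmin == 0:
        scaled = np.full_like(v, 0.5)
    else:
        scaled = (v - vmin) / (vmax - vmin)
    out = _moving_average(scaled, window) if window > 1 else scaled
    return TemporalSignal(values=out, fps=fps, source=source)


def _band_score(values: np.ndarray, fps: float, band, mode: str) -> float:
    """In-band frequency score of the mean-removed series: total in-band
    power (``band_power``, default) or the maximum single-bin magnitude
    (``max_bin``).  Band edges are inclusive."""
    x = values - values.mean()
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fps)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError("band contains no FFT bins")
    if mode == "max_bin":
        return float(mag[in_band].max())
    if mode == "band_power":
        return float((mag[in_band] ** 2).sum() / len(x))
    raise ValueError(f"unknown selection mode {mode!r}")


def select_signal_vector(
    svd: SVDResult,
    fps: float = 30.0,
    band: tuple[float, float] = DEFAULT_BAND,
    max_rank: int = DEFAULT_MAX_RANK,
    window: int = DEFAULT_WINDOW,
    mode: str = DEFAULT_SELECTION,
) -> tuple[int, np.ndarray]:
    """Pick the higher-rank left singular vector with the strongest
    in-band frequency content.

    Candidates are u_2 .. u_min(max_rank, p) (u_1 holds the low-rank,
    quasi-static component).  Each candidate is preprocessed exactly as the
    final signal will be, FFT-transformed, and scored by its in-band
    spectral content (total band power by default, single-bin peak as the
    alternative ``mode``); ties break toward the lowest rank.  Candidates
    whose singular value is numerically zero relative to sigma_1 are scored
    0 (their direction is arbitrary).  Returns ``(rank, raw_vector)`` with
    rank being the 1-based column index j* >= 2.
    """
    if max_rank < 2:
        raise ValueError("max_rank must be >= 2")
    if not (0 < band[0] < band[1] <= fps / 2):
        raise ValueError("band must lie within (0, fps/2]")
    p = svd.p
    if p < 2:
        raise ValueError("no candidate singular vectors beyond u_1")
    hi = min(max_rank, p)
    sigma1 = svd.S[0]
    ranks = list(range(2, hi + 1))
    strong = [j for j in ranks if svd.S[j - 1] >= ENERGY_FLOOR * sigma1]
    pool = strong or ranks
    best_rank, best_score = pool[0], -np.inf
    for j in pool:
        if sigma1 == 0 or svd.S[j - 1] <= RANK_TOL * sigma1:
            score = 0.0
        else:
            sig = preprocess_signal(svd.U[:, j - 1], window=window, fps=fps)
            score = _band_score(sig.values, fps, band, mode)
        if score > best_score:  # strict: ties keep the lowest rank
            best_rank, best_score = j, score
    return best_rank, svd.U[:, best_rank - 1].copy()


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def extract_svd_signal(
    frames,
    grid: BlockGrid | None = None,
    fps: float = 30.0,
    band: tuple[float, float] = DEFAULT_BAND,
    window: int = DEFAULT_WINDOW,
    max_rank: int = DEFAULT_MAX_RANK,
    mode: str = DEFAULT_SELECTION,
) -> TemporalSignal:
    """Full pipeline: block energies -> thin SVD -> vector selection ->
    scaling and smoothing.  Records the selected rank on the signal."""
    energy = compute_energy_matrix(frames, grid)
    svd = decompose_energy(energy)
    rank, vec = select_signal_vector(
        svd, fps=fps, band=band, max_rank=max_rank, window=window, mode=mode
    )
    if svd.S[0] == 0 or svd.S[rank - 1] <= RANK_TOL * svd.S[0]:
        vec = np.zeros_like(vec)  # information-free -> flat 0.5 signal
    sig = preprocess_signal(vec, window=window, fps=fps, source="svd")
    sig.selected_rank = rank
    return sig
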