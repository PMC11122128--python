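"""Statistical and spectral features of 1D temporal eye signals.

Fifteen statistical and seventeen spectral feature families (wavelet
features expand per scale) summarize each per-sequence signal.  Definitions
are pinned here so the feature table is bit-stable:

* FFT-based features use the one-sided spectrum of the raw (unwindowed)
  signal: ``mag = |rfft(s)|``, ``psd = mag**2 / n``.
* Signal entropy is Shannon entropy (bits) of a 10-equal-width-bin
  histogram, normalized by log2(10); a constant signal has entropy 0.
* Spectral moments (centroid, spread, skewness, kurtosis) treat the
  magnitude spectrum, normalized to sum 1, as a distribution over frequency.
* Maximum/median frequency are the 95% / 50% quantiles of the cumulative
  magnitude spectrum.
* Power bandwidth is the frequency span of the bins whose power is at least
  half the spectral maximum (-3 dB width; 0 for a single-bin spectrum).
* Spectral distance is the summed difference between the cumulative
  magnitude and the straight line from 0 to its total.
* Wavelet features come from the continuous wavelet transform with the
  Mexican-hat (Ricker) wavelet at scales 1..9 (scales 5 and 8 always
  present), computed as the classic discrete scheme: convolution with the
  sampled Ricker kernel of length min(10*scale, n), 'same' alignment.
  Per scale: RMS energy and variance of the coefficients, plus the Shannon
  entropy (nats) of the per-scale relative energies.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .svd_signal import TemporalSignal

__all__ = [
    "statistical_features",
    "spectral_features",
    "extract_features",
    "band_power",
    "STATISTICAL_NAMES",
    "SPECTRAL_NAMES",
    "WAVELET_SCALES",
    "ENTROPY_BINS",
]

ENTROPY_BINS = 10
WAVELET_SCALES = tuple(range(1, 10))  # scales 5 and 8 guaranteed present


def _values_fps(s, fps=None):
    if isinstance(s, TemporalSignal):
        return np.asarray(s.values, dtype=float), s.fps
    if fps is None:
        raise ValueError("fps required for plain arrays")
    return np.asarray(s, dtype=float), fps


# ---------------------------------------------------------------------------
# Statistical domain
# ---------------------------------------------------------------------------

def _histogram_entropy(x: np.ndarray) -> float:
    if x.max() == x.min():
        return 0.0
    counts, _ = np.histogram(x, bins=ENTROPY_BINS)
    p = counts[counts > 0] / len(x)
    return float(-(p * np.log2(p)).sum() / np.log2(ENTROPY_BINS))


def statistical_features(s, fps: float | None = None) -> dict[str, float]:
    """The 15 statistical features; requires length >= 4 so that skewness
    and kurtosis are defined."""
    x, _ = _values_fps(s, fps)
    if len(x) < 4:
        raise ValueError("signal too short (need >= 4 samples)")
    mean = float(x.mean())
    med = float(np.median(x))
    return {
        "abs_energy": float((x * x).sum()),
        "entropy": _histogram_entropy(x),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "max": float(x.max()),
        "min": float(x.min()),
        "mean": mean,
        "mean_abs_dev": float(np.abs(x - mean).mean()),
        "median": med,
        "median_abs_dev": float(np.median(np.abs(x - med))),
        "std": float(x.std()),
        "var": float(x.var()),
        "pk_pk": float(x.max() - x.min()),
        "rms": float(np.sqrt((x * x).mean())),
        # a constant signal has no shape: define both moments as 0 there
        "kurtosis": float(sp_stats.kurtosis(x)) if np.ptp(x) > 0 else 0.0,
        "skewness": float(sp_stats.skew(x)) if np.ptp(x) > 0 else 0.0,
    }


STATISTICAL_NAMES = tuple(statistical_features(np.array([0.0, 1.0, 0.0, 1.0]), fps=1.0))


# ---------------------------------------------------------------------------
# Spectral domain
# ---------------------------------------------------------------------------

def ricker_kernel(n_points: int, a: float) -> np.ndarray:
    """Sampled Ricker (Mexican-hat) wavelet: A (1 - (t/a)^2) exp(-t^2/2a^2)
    with A = 2 / (sqrt(3 a) pi^{1/4}), t centered on the kernel."""
    A = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25)
    t = np.arange(n_points) - (n_points - 1) / 2.0
    return A * (1.0 - (t / a) ** 2) * np.exp(-(t**2) / (2.0 * a**2))


def _ricker_cwt_row(x: np.ndarray, a: float) -> np.ndarray:
    kernel = ricker_kernel(min(int(10 * a), len(x)), a)
    return np.convolve(x, kernel, mode="same")


def _spectrum(x: np.ndarray, fps: float):
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fps)
    psd = mag * mag / len(x)
    return freqs, mag, psd


def _cumulative_quantile_freq(freqs, mag, q: float) -> float:
    total = mag.sum()
    if total == 0:
        return 0.0
    cum = np.cumsum(mag)
    idx = int(np.searchsorted(cum, q * total))
    return float(freqs[min(idx, len(freqs) - 1)])


def band_power(s, band: tuple[float, float], fps: float | None = None) -> float:
    """Total one-sided spectral power of the mean-removed signal inside
    ``band`` (edges inclusive)."""
    x, fs = _values_fps(s, fps)
    freqs, _, psd = _spectrum(x - x.mean(), fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(psd[sel].sum())


def spectral_features(
    s, fps: float | None = None, scales=WAVELET_SCALES
) -> dict[str, float]:
    """The 17 spectral feature families (wavelet rows expanded per scale)."""
    x, fs = _values_fps(s, fps)
    if len(x) < 8:
        raise ValueError("signal too short (need >= 8 samples)")
    freqs, mag, psd = _spectrum(x, fs)
    total_mag = mag.sum()

    # magnitude spectrum as a distribution over frequency
    if total_mag > 0:
        p = mag / total_mag
        centroid = float((freqs * p).sum())
        spread = float(np.sqrt((((freqs - centroid) ** 2) * p).sum()))
        if spread > 0:
            skewn = float((((freqs - centroid) ** 3) * p).sum() / spread**3)
            kurt = float((((freqs - centroid) ** 4) * p).sum() / spread**4)
        else:
            skewn, kurt = 0.0, 0.0
    else:
        centroid = spread = skewn = kurt = 0.0

    # -3 dB power bandwidth
    half = psd.max() / 2.0
    above = np.flatnonzero(psd >= half)
    bandwidth = float(freqs[above[-1]] - freqs[above[0]]) if len(above) else 0.0

    # lowest spectral peak above DC
    peaks, _ = sp_signal.find_peaks(mag)
    peaks = peaks[peaks > 0]
    fundamental = float(freqs[peaks[0]]) if len(peaks) else 0.0

    # decrease, distance, slope, entropy, variation
    idx = np.arange(1, len(mag))
    denom = mag[1:].sum()
    decrease = float(((mag[1:] - mag[0]) / idx).sum() / denom) if denom > 0 else 0.0

    cum = np.cumsum(mag)
    line = np.linspace(0.0, cum[-1], len(cum))
    distance = float((cum - line).sum())

    psd_sum = psd.sum()
    if psd_sum > 0:
        q = psd[psd > 0] / psd_sum
        sentropy = float(-(q * np.log(q)).sum() / np.log(len(psd))) if len(psd) > 1 else 0.0
    else:
        sentropy = 0.0

    fmean = freqs.mean()
    fvar = ((freqs - fmean) ** 2).sum()
    slope = float(((freqs - fmean) * (mag - mag.mean())).sum() / fvar) if fvar > 0 else 0.0

    a, b = mag[:-1], mag[1:]
    na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
    variation = float(1.0 - (a * b).sum() / (na * nb)) if na > 0 and nb > 0 else 0.0

    feats = {
        "max_power_spectrum": float(psd.max()),
        "maximum_frequency": _cumulative_quantile_freq(freqs, mag, 0.95),
        "median_frequency": _cumulative_quantile_freq(freqs, mag, 0.50),
        "power_bandwidth": bandwidth,
        "fundamental_frequency": fundamental,
        "spectral_centroid": centroid,
        "spectral_decrease": decrease,
        "spectral_distance": distance,
        "spectral_entropy": sentropy,
        "spectral_kurtosis": kurt,
        "spectral_skewness": skewn,
        "spectral_slope": slope,
        "spectral_spread": spread,
        "spectral_variation": variation,
    }

    coef = np.stack([_ricker_cwt_row(x, a) for a in scales])
    energies = np.sqrt((coef * coef).mean(axis=1))
    for sc, e, v in zip(scales, energies, coef.var(axis=1)):
        feats[f"wavelet_energy_s{sc}"] = float(e)
        feats[f"wavelet_variance_s{sc}"] = float(v)
    e2 = (coef * coef).sum(axis=1)
    tot = e2.sum()
    if tot > 0:
        pe = e2[e2 > 0] / tot
        feats["wavelet_entropy"] = float(-(pe * np.log(pe)).sum())
    else:
        feats["wavelet_entropy"] = 0.0
    return feats


SPECTRAL_NAMES = tuple(
    spectral_features(np.sin(np.linspace(0, 20 * np.pi, 64)), fps=30.0)
)


def extract_features(s, domain: str = "both", fps: float | None = None) -> dict[str, float]:
    """Feature vector for one signal; ``domain`` in {statistical, spectral, both}."""
    if domain == "statistical":
        return statistical_features(s, fps)
    if domain == "spectral":
        return spectral_features(s, fps)
    if domain == "both":
        out = statistical_features(s, fps)
        out.update(spectral_features(s, fps))
        return out
    raise ValueError(f"unknown domain {domain!r}")
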