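"""Independent oracle implementations used by the tests.

Everything here is deliberately naive (explicit loops, direct textbook
formulas, O(n^2) DFTs) and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Rendering / energy oracles
# ---------------------------------------------------------------------------

def rasterized_disc_count(cx: float, cy: float, r: float, h: int, w: int) -> int:
    """Per-pixel membership count of a disc, evaluated at pixel centers."""
    n = 0
    for y in range(h):
        for x in range(w):
            if (x - cx) ** 2 + (y - cy) ** 2 <= r * r:
                n += 1
    return n


def naive_energy_matrix(frames: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Nested-loop block energies with 8-bit inputs scaled to [0, 1]."""
    k, h, w = frames.shape
    bh, bw = h // rows, w // cols
    E = np.zeros((k, rows * cols))
    for i in range(k):
        frame = frames[i].astype(float)
        if np.issubdtype(frames.dtype, np.integer):
            frame = frame / 255.0
        for br in range(rows):
            for bc in range(cols):
                acc = 0.0
                for y in range(br * bh, (br + 1) * bh):
                    for x in range(bc * bw, (bc + 1) * bw):
                        acc += frame[y, x] ** 2
                E[i, br * cols + bc] = acc
    return E


# ---------------------------------------------------------------------------
# Signal-processing oracles
# ---------------------------------------------------------------------------

def naive_moving_average(v, window: int):
    """Centered moving average with edge truncation, by direct loops."""
    k = len(v)
    left = (window - 1) // 2
    right = window // 2
    out = []
    for i in range(k):
        lo, hi = max(0, i - left), min(k, i + right + 1)
        out.append(sum(v[lo:hi]) / (hi - lo))
    return np.array(out)


def naive_minmax_scale(v):
    v = np.asarray(v, dtype=float)
    if v.max() == v.min():
        return np.full_like(v, 0.5)
    return (v - v.min()) / (v.max() - v.min())


def naive_dft_mag(x):
    """O(n^2) one-sided DFT magnitudes."""
    n = len(x)
    half = n // 2 + 1
    mags = []
    for kk in range(half):
        re = sum(x[t] * math.cos(-2 * math.pi * kk * t / n) for t in range(n))
        im = sum(x[t] * math.sin(-2 * math.pi * kk * t / n) for t in range(n))
        mags.append(math.hypot(re, im))
    return np.array(mags)


def naive_svd_pipeline(E, fps=30.0, band=(2.0, 15.0), window=5, max_rank=10,
                       mode="band_power", energy_floor=0.01):
    """Full-SVD, loop-based reimplementation of the signal pipeline:
    decomposition -> candidate scoring -> selection -> preprocessing."""
    E = np.asarray(E, dtype=float)
    k, d = E.shape
    U, S, Vt = np.linalg.svd(E, full_matrices=True)
    p = min(k, d)
    ranks = list(range(2, min(max_rank, p) + 1))
    strong = [j for j in ranks if S[j - 1] >= energy_floor * S[0]]
    pool = strong if strong else ranks
    best_rank, best_score = pool[0], -np.inf
    for j in pool:
        if S[0] == 0 or S[j - 1] <= 1e-10 * S[0]:
            score = 0.0
        else:
            s = naive_moving_average(naive_minmax_scale(U[:, j - 1]), window)
            x = s - s.mean()
            mags = naive_dft_mag(x)
            freqs = [fps * kk / len(x) for kk in range(len(mags))]
            in_band = [m for f, m in zip(freqs, mags) if band[0] <= f <= band[1]]
            if mode == "max_bin":
                score = max(in_band)
            else:
                score = sum(m * m for m in in_band) / len(x)
        if score > best_score:
            best_rank, best_score = j, score
    vec = U[:, best_rank - 1]
    if S[0] == 0 or S[best_rank - 1] <= 1e-10 * S[0]:
        vec = np.zeros_like(vec)
    sig = naive_moving_average(naive_minmax_scale(vec), window)
    return best_rank, sig


# ---------------------------------------------------------------------------
# Statistical feature oracles (direct textbook formulas, loop-based)
# ---------------------------------------------------------------------------

def _naive_percentile(sorted_x, q):
    """Linear-interpolation percentile on pre-sorted data."""
    n = len(sorted_x)
    pos = q / 100.0 * (n - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return sorted_x[lo] * (1 - frac) + sorted_x[hi] * frac


def naive_statistical_features(x, n_bins=10):
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sx = sorted(x)
    median = (sx[n // 2] if n % 2 else (sx[n // 2 - 1] + sx[n // 2]) / 2.0)
    var = sum((v - mean) ** 2 for v in x) / n
    std = math.sqrt(var)
    m2 = var
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    # histogram entropy, 10 equal-width bins, bits, normalized by log2(10)
    mn, mx = min(x), max(x)
    if mx == mn:
        entropy = 0.0
    else:
        counts = [0] * n_bins
        width = (mx - mn) / n_bins
        for v in x:
            b = min(int((v - mn) / width), n_bins - 1)
            counts[b] += 1
        entropy = -sum(
            (c / n) * math.log2(c / n) for c in counts if c
        ) / math.log2(n_bins)
    return {
        "abs_energy": sum(v * v for v in x),
        "entropy": entropy,
        "iqr": _naive_percentile(sx, 75) - _naive_percentile(sx, 25),
        "max": mx,
        "min": mn,
        "mean": mean,
        "mean_abs_dev": sum(abs(v - mean) for v in x) / n,
        "median": median,
        "median_abs_dev": (
            sorted(abs(v - median) for v in x)[n // 2]
            if n % 2
            else sum(sorted(abs(v - median) for v in x)[n // 2 - 1 : n // 2 + 1]) / 2.0
        ),
        "std": std,
        "var": var,
        "pk_pk": mx - mn,
        "rms": math.sqrt(sum(v * v for v in x) / n),
        "kurtosis": m4 / (m2 * m2) - 3.0 if m2 > 0 else 0.0,
        "skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# Spectral feature oracles
# ---------------------------------------------------------------------------

def naive_ricker_kernel(n_points, a):
    A = 2.0 / (math.sqrt(3.0 * a) * math.pi**0.25)
    return [
        A * (1.0 - ((t - (n_points - 1) / 2.0) / a) ** 2)
        * math.exp(-((t - (n_points - 1) / 2.0) ** 2) / (2.0 * a * a))
        for t in range(n_points)
    ]


def naive_same_convolution(x, kern):
    """'same'-mode convolution by direct summation (numpy alignment)."""
    n, m = len(x), len(kern)
    full = [0.0] * (n + m - 1)
    for i in range(n):
        for j in range(m):
            full[i + j] += x[i] * kern[j]
    start = (m - 1) // 2
    return np.array(full[start : start + n])


def naive_spectral_features(x, fps, scales=tuple(range(1, 10))):
    x = [float(v) for v in x]
    n = len(x)
    mags = naive_dft_mag(x)
    freqs = np.array([fps * kk / n for kk in range(len(mags))])
    psd = mags**2 / n
    total = mags.sum()

    def quantile_freq(q):
        if total == 0:
            return 0.0
        acc = 0.0
        for f, m in zip(freqs, mags):
            acc += m
            if acc >= q * total:
                return float(f)
        return float(freqs[-1])

    p = mags / total if total > 0 else np.zeros_like(mags)
    centroid = float(sum(f * w for f, w in zip(freqs, p)))
    spread = math.sqrt(sum((f - centroid) ** 2 * w for f, w in zip(freqs, p)))
    skewn = (
        sum((f - centroid) ** 3 * w for f, w in zip(freqs, p)) / spread**3
        if spread > 0
        else 0.0
    )
    kurt = (
        sum((f - centroid) ** 4 * w for f, w in zip(freqs, p)) / spread**4
        if spread > 0
        else 0.0
    )

    half = psd.max() / 2.0
    above = [i for i, v in enumerate(psd) if v >= half]
    bandwidth = float(freqs[above[-1]] - freqs[above[0]]) if above else 0.0

    fundamental = 0.0
    for i in range(1, len(mags) - 1):
        if mags[i] > mags[i - 1] and mags[i] > mags[i + 1]:
            fundamental = float(freqs[i])
            break

    denom = mags[1:].sum()
    decrease = (
        float(sum((mags[i] - mags[0]) / i for i in range(1, len(mags))) / denom)
        if denom > 0
        else 0.0
    )

    cum = np.cumsum(mags)
    line = [cum[-1] * i / (len(cum) - 1) for i in range(len(cum))]
    distance = float(sum(c - l for c, l in zip(cum, line)))

    psd_sum = psd.sum()
    if psd_sum > 0 and len(psd) > 1:
        qs = [v / psd_sum for v in psd if v > 0]
        sentropy = -sum(q * math.log(q) for q in qs) / math.log(len(psd))
    else:
        sentropy = 0.0

    fmean = freqs.mean()
    fvar = sum((f - fmean) ** 2 for f in freqs)
    mmean = mags.mean()
    slope = (
        float(sum((f - fmean) * (m - mmean) for f, m in zip(freqs, mags)) / fvar)
        if fvar > 0
        else 0.0
    )

    a_, b_ = mags[:-1], mags[1:]
    na, nb = math.sqrt(sum(v * v for v in a_)), math.sqrt(sum(v * v for v in b_))
    variation = (
        1.0 - sum(u * v for u, v in zip(a_, b_)) / (na * nb) if na > 0 and nb > 0 else 0.0
    )

    feats = {
        "max_power_spectrum": float(psd.max()),
        "maximum_frequency": quantile_freq(0.95),
        "median_frequency": quantile_freq(0.50),
        "power_bandwidth": bandwidth,
        "fundamental_frequency": fundamental,
        "spectral_centroid": centroid,
        "spectral_decrease": decrease,
        "spectral_distance": distance,
        "spectral_entropy": float(sentropy),
        "spectral_kurtosis": float(kurt),
        "spectral_skewness": float(skewn),
        "spectral_slope": slope,
        "spectral_spread": float(spread),
        "spectral_variation": float(variation),
    }
    rows = []
    for a in scales:
        kern = naive_ricker_kernel(min(int(10 * a), n), a)
        rows.append(naive_same_convolution(x, kern))
    coef = np.stack(rows)
    for a, row in zip(scales, coef):
        feats[f"wavelet_energy_s{a}"] = float(math.sqrt((row**2).mean()))
        feats[f"wavelet_variance_s{a}"] = float(row.var())
    e2 = (coef**2).sum(axis=1)
    tot = e2.sum()
    feats["wavelet_entropy"] = (
        float(-sum((v / tot) * math.log(v / tot) for v in e2 if v > 0)) if tot > 0 else 0.0
    )
    return feats
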