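"""Hand-engineered quality features for 20-s ECG segments.

Forty-three time- and frequency-domain features, computed from the raw
segment, from five nonoverlapping 4-s subsegments, and from the negated
signal (peak detectors return peaks, not troughs, and monitor leads flip
polarity; the ``_neg`` variants cover both).  The registry
:data:`FEATURE_NAMES` fixes the names and order; :func:`extract_features`
always returns a vector of exactly that length.

Conventions (fixed here, documented in docs/methods.md):

* ``slopes`` — first difference of consecutive samples of the full segment.
* peak amplitudes are read from the *unfiltered* signal at peaks detected on
  the 0.5-8 Hz bandpassed signal.
* ``autocorr`` — normalised autocorrelation of each subsegment for lags
  1..fs (one second); aggregated over all lags and subsegments.
* ``crosscorr`` — normalised cross-correlation sequence between each pair of
  adjacent 4-s subsegments; aggregated over all pair sequences.
* ``he`` — Hurst exponent per subsegment by rescaled-range (R/S) estimation.
* ``dtw`` — dynamic-time-warping distance between adjacent subsegments
  (decimated 10x before alignment; absolute-difference cost, unconstrained).
* ``maxpower`` — maximum of the one-sided FFT power spectrum per subsegment;
  ``meanpowerdiff``/``meanfreqdiff`` are the successive between-subsegment
  differences of the power and frequency at that maximum.
* STFT — Hanning window of 100 samples, 50% overlap; ``se`` is the Shannon
  entropy of the power-normalised spectrum of each STFT time frame.

Features undefined on degenerate input (constant signal, too few peaks) are
set to the sentinel 0 and flagged invalid, keeping the vector fixed-width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy import signal as sps

from .segment import ECGSegment

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "PeakSet",
    "FeatureVector",
    "bandpass",
    "detect_peaks",
    "subsegments",
    "extract_features",
    "extract_feature_matrix",
    "select_k_best",
    "stft_magnitude",
]

FEATURE_NAMES: Tuple[str, ...] = (
    "mean(slopes)",
    "stddev(slopes)",
    "max(zscore(peakamplitude))",
    "min(zscore(peakamplitude_neg))",
    "max(zscore(peakamplitude_neg))",
    "max(peakamplitude)",
    "max(peakamplitude_neg)",
    "stddev(mean(peakamplitude))",
    "stddev(max(peakamplitude))",
    "stddev(min(peakminamplitude))",
    "mean(autocorr)",
    "stddev(autocorr)",
    "mean(autocorr_neg)",
    "stddev(autocorr_neg)",
    "mean(crosscorr)",
    "stddev(crosscorr)",
    "mean(crosscorr_neg)",
    "stddev(crosscorr_neg)",
    "mean(skew)",
    "mean(skew_neg)",
    "stddev(skew)",
    "stddev(skew_neg)",
    "mean(kurtosis)",
    "mean(kurtosis_neg)",
    "stddev(kurtosis)",
    "stddev(kurtosis_neg)",
    "mean(he)",
    "stddev(he)",
    "mean(he_neg)",
    "stddev(he_neg)",
    "mean(dtw)",
    "stddev(dtw)",
    "mean(dtw_neg)",
    "stddev(dtw_neg)",
    "mean(maxpower)",
    "stddev(maxpower)",
    "mean(maxpower_neg)",
    "stddev(maxpower_neg)",
    "stddev(meanpowerdiff)",
    "stddev(meanfreqdiff)",
    "mean(abs(stft))",
    "std(abs(stft))",
    "stddev(se)",
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 43

#: STFT analysis window (samples) and overlap fraction
STFT_WINDOW = 100
STFT_OVERLAP = 0.5
#: decimation factor applied to subsegments before DTW alignment
DTW_DECIMATION = 10


@dataclass
class PeakSet:
    """Detected peak positions (sample indices) and their mV amplitudes."""

    indices: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.indices) != len(self.amplitudes):
            raise ValueError("indices and amplitudes must have equal length")
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class FeatureVector:
    """The 43 named features for one segment, plus per-feature validity flags."""

    values: np.ndarray
    valid: np.ndarray
    segment_id: Optional[str] = None

    names: Tuple[str, ...] = FEATURE_NAMES

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def is_valid(self, name: str) -> bool:
        return bool(self.valid[self.names.index(name)])


# ---------------------------------------------------------------------------
# signal primitives


def bandpass(seg: ECGSegment, low_hz: float = 0.5, high_hz: float = 8.0) -> ECGSegment:
    """Zero-phase Butterworth bandpass, passband [low_hz, high_hz].

    Removes baseline drift below ``low_hz`` and high-frequency noise above
    ``high_hz`` before peak detection.
    """
    nyq = seg.fs_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"need 0 < low < high < fs/2, got ({low_hz}, {high_hz}) at fs={seg.fs_hz}"
        )
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=seg.fs_hz, output="sos")
    return seg.with_values(sps.sosfiltfilt(sos, seg.values))


def detect_peaks(
    seg: ECGSegment, low_hz: float = 0.5, high_hz: float = 8.0,
    min_distance_s: float = 0.25,
) -> PeakSet:
    """R-peak candidates by adaptive-threshold local-maximum detection.

    Detection runs on the bandpassed signal; the threshold sits halfway
    between the median and the 99th percentile, adapting to the segment's own
    amplitude scale.  Amplitudes in the returned :class:`PeakSet` are read
    from the *original* (unfiltered) signal.  A refractory distance of 0.25 s
    caps the rate at 240 bpm.
    """
    x = seg.values
    if len(x) == 0 or np.ptp(x) == 0:
        return PeakSet(np.empty(0, dtype=int), np.empty(0))
    f = bandpass(seg, low_hz, high_hz).values
    med = np.median(f)
    hi = np.percentile(f, 99)
    if hi <= med:
        return PeakSet(np.empty(0, dtype=int), np.empty(0))
    height = med + 0.5 * (hi - med)
    idx, _ = sps.find_peaks(f, height=height, distance=max(1, int(min_distance_s * seg.fs_hz)))
    return PeakSet(idx, x[idx])


def subsegments(seg: ECGSegment, window_s: float = 4.0) -> List[np.ndarray]:
    """Split into contiguous nonoverlapping windows; *window_s* must divide the duration."""
    n_win = seg.duration_s / window_s
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError(
            f"window of {window_s} s does not divide a {seg.duration_s} s segment"
        )
    size = int(round(window_s * seg.fs_hz))
    return [seg.values[i * size : (i + 1) * size] for i in range(int(round(n_win)))]


def stft_magnitude(
    values: np.ndarray, window: int = STFT_WINDOW, overlap: float = STFT_OVERLAP
) -> np.ndarray:
    """One-sided STFT magnitude matrix, shape (window//2 + 1, n_frames).

    Hanning-windowed frames with the given overlap fraction; no padding, so
    only full frames are used.
    """
    hop = max(1, int(round(window * (1.0 - overlap))))
    n = len(values)
    if n < window:
        raise ValueError(f"signal of {n} samples shorter than STFT window {window}")
    n_frames = 1 + (n - window) // hop
    win = np.hanning(window)
    values = np.ascontiguousarray(values, dtype=float)
    s = values.strides[0]
    frames = np.lib.stride_tricks.as_strided(
        values, shape=(n_frames, window), strides=(s * hop, s), writeable=False
    )
    return np.abs(np.fft.rfft(frames * win, axis=1)).T


# ---------------------------------------------------------------------------
# per-block statistics


def _autocorr_sequence(x: np.ndarray, max_lag: int) -> Optional[np.ndarray]:
    """Normalised autocorrelation r_k for k = 1..max_lag; None if variance is 0."""
    xd = x - x.mean()
    denom = float(np.dot(xd, xd))
    if denom == 0.0:
        return None
    max_lag = min(max_lag, len(x) - 1)
    full = np.correlate(xd, xd, mode="full")[len(x) - 1 :]
    return full[1 : max_lag + 1] / denom


def _crosscorr_sequence(a: np.ndarray, b: np.ndarray) -> Optional[np.ndarray]:
    """Full cross-correlation sequence normalised by the L2 norms.

    The blocks are deliberately *not* demeaned: with demeaning the sequence
    sums to zero identically, making its mean uninformative.  Cosine-style
    normalisation keeps similar periodic blocks near 1 at the aligning lags.
    """
    na, nb = np.sqrt(np.dot(a, a)), np.sqrt(np.dot(b, b))
    if na == 0.0 or nb == 0.0:
        return None
    return np.correlate(a, b, mode="full") / (na * nb)


def _hurst_rs(x: np.ndarray) -> Optional[float]:
    """Hurst exponent by rescaled-range analysis.

    Blocks of geometrically spaced sizes; per block, R = range of the demeaned
    cumulative sum, S = standard deviation; H = slope of log mean(R/S) against
    log block size.
    """
    n = len(x)
    sizes = [s for s in (16, 32, 64, 128, 256, 512) if s <= n // 2]
    if len(sizes) < 2:
        return None
    log_s, log_rs = [], []
    for s in sizes:
        m = n // s
        blocks = x[: m * s].reshape(m, s)
        sd = blocks.std(axis=1)
        ok = sd > 0
        if not ok.any():
            continue
        cum = np.cumsum(blocks - blocks.mean(axis=1, keepdims=True), axis=1)
        rs = np.ptp(cum[ok], axis=1) / sd[ok]
        log_s.append(np.log(s))
        log_rs.append(np.log(rs.mean()))
    if len(log_s) < 2:
        return None
    slope, _ = np.polyfit(log_s, log_rs, 1)
    return float(slope)


@njit(cache=True)
def _dtw_distance(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover - jitted
    n, m = len(a), len(b)
    inf = 1e300
    prev = np.full(m + 1, inf)
    prev[0] = 0.0
    for i in range(n):
        cur = np.full(m + 1, inf)
        for j in range(m):
            c = abs(a[i] - b[j])
            best = prev[j + 1]
            if cur[j] < best:
                best = cur[j]
            if prev[j] < best:
                best = prev[j]
            cur[j + 1] = c + best
        prev = cur
    return prev[m]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Unconstrained DTW distance with absolute-difference local cost."""
    return float(_dtw_distance(np.ascontiguousarray(a, dtype=np.float64),
                               np.ascontiguousarray(b, dtype=np.float64)))


# ---------------------------------------------------------------------------
# the 43-feature extractor


def _agg(values: Sequence[float]) -> Tuple[float, float, bool]:
    """(mean, population std, valid) over a list; sentinel on empty."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return 0.0, 0.0, False
    return float(arr.mean()), float(arr.std()), True


def _per_sign_features(x: np.ndarray, fs: int, out: dict, suffix: str) -> None:
    """Fill the features computed identically for the plain and negated signal."""
    seg = ECGSegment(values=x, fs_hz=fs)
    blocks = subsegments(seg, 4.0) if seg.duration_s % 4.0 < 1e-9 else [x]

    # autocorrelation over lags 1..fs, all subsegments pooled
    ac_pool: List[float] = []
    for b in blocks:
        r = _autocorr_sequence(b, fs)
        if r is not None:
            ac_pool.extend(r.tolist())
    m, s, ok = _agg(ac_pool)
    out[f"mean(autocorr{suffix})"] = (m, ok)
    out[f"stddev(autocorr{suffix})"] = (s, ok)

    # cross-correlation between adjacent subsegment pairs, pooled
    cc_pool: List[float] = []
    for a, b in zip(blocks[:-1], blocks[1:]):
        c = _crosscorr_sequence(a, b)
        if c is not None:
            cc_pool.extend(c.tolist())
    m, s, ok = _agg(cc_pool)
    out[f"mean(crosscorr{suffix})"] = (m, ok)
    out[f"stddev(crosscorr{suffix})"] = (s, ok)

    # skewness / kurtosis per subsegment (biased moments, Fisher kurtosis)
    skews, kurts = [], []
    for b in blocks:
        sd = b.std()
        if sd > 0:
            dev = b - b.mean()
            skews.append(float(np.mean(dev**3) / sd**3))
            kurts.append(float(np.mean(dev**4) / sd**4 - 3.0))
    m, s, ok = _agg(skews)
    out[f"mean(skew{suffix})"] = (m, ok)
    out[f"stddev(skew{suffix})"] = (s, ok)
    m, s, ok = _agg(kurts)
    out[f"mean(kurtosis{suffix})"] = (m, ok)
    out[f"stddev(kurtosis{suffix})"] = (s, ok)

    # Hurst exponent per subsegment
    hes = [h for h in (_hurst_rs(b) for b in blocks) if h is not None]
    m, s, ok = _agg(hes)
    out[f"mean(he{suffix})"] = (m, ok)
    out[f"stddev(he{suffix})"] = (s, ok)

    # DTW between adjacent subsegments, decimated for tractable alignment
    dtws = [
        dtw_distance(a[::DTW_DECIMATION], b[::DTW_DECIMATION])
        for a, b in zip(blocks[:-1], blocks[1:])
    ]
    m, s, ok = _agg(dtws)
    out[f"mean(dtw{suffix})"] = (m, ok)
    out[f"stddev(dtw{suffix})"] = (s, ok)

    # max FFT power per subsegment
    powers = [float(np.max(np.abs(np.fft.rfft(b)) ** 2)) for b in blocks]
    m, s, ok = _agg(powers)
    out[f"mean(maxpower{suffix})"] = (m, ok)
    out[f"stddev(maxpower{suffix})"] = (s, ok)


def extract_features(seg: ECGSegment) -> FeatureVector:
    """Compute the full 43-feature vector for one (preprocessed) segment.

    Deterministic for fixed input.  Degenerate cases — constant signal,
    fewer than two detected peaks, constant subsegments — yield the sentinel
    0 with the validity flag cleared for the affected features.
    """
    x = seg.values.astype(float)
    fs = seg.fs_hz
    out: dict = {}

    # slope features on the full segment
    d = np.diff(x)
    if d.size:
        out["mean(slopes)"] = (float(d.mean()), True)
        out["stddev(slopes)"] = (float(d.std()), True)
    else:
        out["mean(slopes)"] = (0.0, False)
        out["stddev(slopes)"] = (0.0, False)

    # peak-amplitude features, plain and negated signal
    peaks = detect_peaks(seg)
    neg_seg = seg.with_values(-x)
    peaks_neg = detect_peaks(neg_seg)

    def _zstats(amps: np.ndarray) -> Tuple[Tuple[float, bool], Tuple[float, bool]]:
        if len(amps) >= 2 and amps.std() > 0:
            z = (amps - amps.mean()) / amps.std()
            return (float(z.max()), True), (float(z.min()), True)
        return (0.0, False), (0.0, False)

    zmax, _ = _zstats(peaks.amplitudes)
    out["max(zscore(peakamplitude))"] = zmax
    zmax_n, zmin_n = _zstats(-x[peaks_neg.indices] if len(peaks_neg) else np.empty(0))
    out["max(zscore(peakamplitude_neg))"] = zmax_n
    out["min(zscore(peakamplitude_neg))"] = zmin_n

    out["max(peakamplitude)"] = (
        (float(peaks.amplitudes.max()), True) if len(peaks) else (0.0, False)
    )
    out["max(peakamplitude_neg)"] = (
        (float((-x[peaks_neg.indices]).max()), True) if len(peaks_neg) else (0.0, False)
    )

    # subsegment-wise peak statistics: partition the detected peaks by block
    block_size = 4 * fs
    n_blocks = max(1, seg.n_samples // block_size)
    per_block_mean, per_block_max, per_block_min = [], [], []
    for i in range(n_blocks):
        lo, hi = i * block_size, (i + 1) * block_size
        in_blk = (peaks.indices >= lo) & (peaks.indices < hi)
        if in_blk.any():
            amps = peaks.amplitudes[in_blk]
            per_block_mean.append(float(amps.mean()))
            per_block_max.append(float(amps.max()))
        in_blk_n = (peaks_neg.indices >= lo) & (peaks_neg.indices < hi)
        if in_blk_n.any():
            # troughs of the original signal: minima, read on the plain signal
            per_block_min.append(float(x[peaks_neg.indices[in_blk_n]].min()))

    def _std_over_blocks(vals: List[float]) -> Tuple[float, bool]:
        if len(vals) >= 2:
            return float(np.std(vals)), True
        return 0.0, False

    out["stddev(mean(peakamplitude))"] = _std_over_blocks(per_block_mean)
    out["stddev(max(peakamplitude))"] = _std_over_blocks(per_block_max)
    out["stddev(min(peakminamplitude))"] = _std_over_blocks(per_block_min)

    # block statistics on the plain and negated signal
    _per_sign_features(x, fs, out, "")
    _per_sign_features(-x, fs, out, "_neg")

    # between-subsegment drift of the dominant FFT component
    blocks = subsegments(seg, 4.0) if seg.duration_s % 4.0 < 1e-9 else [x]
    freqs_axis = np.fft.rfftfreq(len(blocks[0]), d=1.0 / fs)
    max_p, max_f = [], []
    for b in blocks:
        p = np.abs(np.fft.rfft(b)) ** 2
        k = int(np.argmax(p))
        max_p.append(float(p[k]))
        max_f.append(float(freqs_axis[k]))
    if len(blocks) >= 3:
        out["stddev(meanpowerdiff)"] = (float(np.std(np.diff(max_p))), True)
        out["stddev(meanfreqdiff)"] = (float(np.std(np.diff(max_f))), True)
    else:
        out["stddev(meanpowerdiff)"] = (0.0, False)
        out["stddev(meanfreqdiff)"] = (0.0, False)

    # STFT magnitude statistics and spectral entropy over time frames
    if seg.n_samples >= STFT_WINDOW:
        mag = stft_magnitude(x)
        out["mean(abs(stft))"] = (float(mag.mean()), True)
        out["std(abs(stft))"] = (float(mag.std()), True)
        power = mag**2
        col_sums = power.sum(axis=0)
        nz = col_sums > 0
        if nz.sum() >= 2:
            p = power[:, nz] / col_sums[nz]
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
            ents = -plogp.sum(axis=0)
            out["stddev(se)"] = (float(np.std(ents)), True)
        else:
            out["stddev(se)"] = (0.0, False)
    else:
        out["mean(abs(stft))"] = (0.0, False)
        out["std(abs(stft))"] = (0.0, False)
        out["stddev(se)"] = (0.0, False)

    values = np.array([out[name][0] for name in FEATURE_NAMES], dtype=float)
    valid = np.array([out[name][1] for name in FEATURE_NAMES], dtype=bool)
    values[~np.isfinite(values)] = 0.0
    return FeatureVector(values=values, valid=valid, segment_id=seg.segment_id)


def extract_feature_matrix(segments: Sequence[ECGSegment]) -> np.ndarray:
    """Stack :func:`extract_features` over segments into an (n, 43) matrix."""
    return np.stack([extract_features(s).values for s in segments]) if segments else (
        np.empty((0, N_FEATURES))
    )


def select_k_best(X: np.ndarray, y: Sequence, k: int) -> List[str]:
    """Rank features by the one-way ANOVA F statistic between classes; top *k* names.

    Constant columns (undefined F) rank last.  Column names follow
    :data:`FEATURE_NAMES` when X has 43 columns, else positional names.
    """
    from sklearn.feature_selection import f_classif

    X = np.asarray(X, dtype=float)
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available features")
    if len(set(y)) < 2:
        raise ValueError("need at least two classes for feature selection")
    names = (
        list(FEATURE_NAMES)
        if X.shape[1] == N_FEATURES
        else [f"f{i}" for i in range(X.shape[1])]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(X, np.asarray(y))
    f_stat = np.where(np.isfinite(f_stat), f_stat, -np.inf)
    order = np.argsort(-f_stat, kind="stable")
    return [names[i] for i in order[:k]]
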