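"""Independent brute-force reference implementations of the 43 features.

Deliberately naive code — explicit loops and direct formula evaluation —
sharing nothing with ecgqc.features except the documented definitions, so a
disagreement localises a bug in the optimised implementation.
"""

import math

import numpy as np


def mean_std(vals):
    if len(vals) == 0:
        return 0.0, 0.0
    m = sum(vals) / len(vals)
    var = sum((v - m) ** 2 for v in vals) / len(vals)
    return m, math.sqrt(var)


def slopes(x):
    return [x[i + 1] - x[i] for i in range(len(x) - 1)]


def blocks_of(x, fs, window_s=4.0):
    size = int(window_s * fs)
    n = len(x) // size
    return [x[i * size : (i + 1) * size] for i in range(n)] if n >= 1 else [x]


def autocorr_pool(x, fs, window_s=4.0):
    pool = []
    for b in blocks_of(x, fs, window_s):
        mu = sum(b) / len(b)
        denom = sum((v - mu) ** 2 for v in b)
        if denom == 0:
            continue
        for k in range(1, min(fs, len(b) - 1) + 1):
            num = sum((b[t] - mu) * (b[t + k] - mu) for t in range(len(b) - k))
            pool.append(num / denom)
    return pool


def crosscorr_pool(x, fs, window_s=4.0):
    blocks = blocks_of(x, fs, window_s)
    pool = []
    for a, b in zip(blocks[:-1], blocks[1:]):
        da = list(a)
        db = list(b)
        na = math.sqrt(sum(v * v for v in da))
        nb = math.sqrt(sum(v * v for v in db))
        if na == 0 or nb == 0:
            continue
        n, m = len(a), len(b)
        # full correlation: lag runs over every overlap of the two blocks
        for lag in range(-(m - 1), n):
            s = 0.0
            for j in range(m):
                i = lag + j
                if 0 <= i < n:
                    s += da[i] * db[j]
            pool.append(s / (na * nb))
    return pool


def skew_of(b):
    m = sum(b) / len(b)
    sd = math.sqrt(sum((v - m) ** 2 for v in b) / len(b))
    if sd == 0:
        return None
    return sum((v - m) ** 3 for v in b) / len(b) / sd**3


def kurtosis_of(b):
    m = sum(b) / len(b)
    sd = math.sqrt(sum((v - m) ** 2 for v in b) / len(b))
    if sd == 0:
        return None
    return sum((v - m) ** 4 for v in b) / len(b) / sd**4 - 3.0


def hurst_rs(b):
    n = len(b)
    sizes = [s for s in (16, 32, 64, 128, 256, 512) if s <= n // 2]
    if len(sizes) < 2:
        return None
    pts = []
    for s in sizes:
        rs_list = []
        for start in range(0, (n // s) * s, s):
            blk = b[start : start + s]
            m = sum(blk) / s
            sd = math.sqrt(sum((v - m) ** 2 for v in blk) / s)
            if sd == 0:
                continue
            cum, cmin, cmax, acc = [], None, None, 0.0
            for v in blk:
                acc += v - m
                cum.append(acc)
            rs_list.append((max(cum) - min(cum)) / sd)
        if rs_list:
            pts.append((math.log(s), math.log(sum(rs_list) / len(rs_list))))
    if len(pts) < 2:
        return None
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    return sum((a - mx) * (b_ - my) for a, b_ in zip(xs, ys)) / sum(
        (a - mx) ** 2 for a in xs
    )


def dtw_plain(a, b):
    n, m = len(a), len(b)
    dp = [[math.inf] * (m + 1) for _ in range(n + 1)]
    dp[0][0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(a[i - 1] - b[j - 1])
            dp[i][j] = c + min(dp[i - 1][j], dp[i][j - 1], dp[i - 1][j - 1])
    return dp[n][m]


def dtw_pool(x, fs, window_s=4.0, decim=10):
    blocks = blocks_of(x, fs, window_s)
    return [
        dtw_plain(list(a[::decim]), list(b[::decim]))
        for a, b in zip(blocks[:-1], blocks[1:])
    ]


def maxpower_pool(x, fs, window_s=4.0):
    out = []
    for b in blocks_of(x, fs, window_s):
        p = np.abs(np.fft.rfft(b)) ** 2
        out.append(float(max(p)))
    return out


def maxpower_freqs(x, fs, window_s=4.0):
    powers, freqs = [], []
    for b in blocks_of(x, fs, window_s):
        p = np.abs(np.fft.rfft(b)) ** 2
        f = np.fft.rfftfreq(len(b), d=1.0 / fs)
        k = int(np.argmax(p))
        powers.append(float(p[k]))
        freqs.append(float(f[k]))
    return powers, freqs


def stft_frames(x, window=100, overlap=0.5):
    hop = int(window * (1 - overlap))
    win = np.hanning(window)
    frames = []
    i = 0
    while i + window <= len(x):
        frames.append(np.abs(np.fft.rfft(np.asarray(x[i : i + window]) * win)))
        i += hop
    return frames  # list of one-sided magnitude vectors


def spectral_entropies(x, window=100, overlap=0.5):
    ents = []
    for mag in stft_frames(x, window, overlap):
        p = mag**2
        tot = p.sum()
        if tot == 0:
            continue
        p = p / tot
        ents.append(float(-sum(v * math.log(v) for v in p if v > 0)))
    return ents
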