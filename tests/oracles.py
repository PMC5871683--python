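"""Independent brute-force reference implementations used only by tests.

Everything here is written from the feature definitions with plain loops
and manual FFT arithmetic, deliberately avoiding the code paths (and where
practical the library calls) used by the package itself.
"""

from __future__ import annotations

import numpy as np


def kurtosis_oracle(tc, fs, length=5.0, overlap=1.0):
    """Mean excess kurtosis over epochs via explicit central moments."""
    n = int(round(length * fs))
    hop = int(round((length - overlap) * fs))
    vals = []
    start = 0
    while start + n <= len(tc):
        e = np.asarray(tc[start : start + n], dtype=float)
        e = e - sum(e) / len(e)
        m2 = sum(x**2 for x in e) / len(e)
        m4 = sum(x**4 for x in e) / len(e)
        vals.append(0.0 if m2 == 0 else m4 / m2**2 - 3.0)
        start += hop
    k = sum(vals) / len(vals)
    return max(0.0, k)


def mev_oracle(tc, fs, length=5.0, overlap=1.0):
    """Max/mean epoch variance via the E[x^2] - E[x]^2 form."""
    n = int(round(length * fs))
    hop = int(round((length - overlap) * fs))
    variances = []
    start = 0
    while start + n <= len(tc):
        e = np.asarray(tc[start : start + n], dtype=float)
        variances.append(sum(x**2 for x in e) / len(e) - (sum(e) / len(e)) ** 2)
        start += hop
    mean_v = sum(variances) / len(variances)
    return 0.0 if mean_v == 0 else max(variances) / mean_v


def welch_oracle(tc, fs, window_s=2.0):
    """Hand-rolled Welch PSD: Hann segments, 50% overlap, density scaling."""
    tc = np.asarray(tc, dtype=float)
    nper = min(int(round(window_s * fs)), tc.size)
    step = nper - nper // 2
    # periodic Hann window
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nper) / nper)
    scale = 1.0 / (fs * np.sum(w**2))
    segs = []
    start = 0
    while start + nper <= tc.size:
        x = tc[start : start + nper]
        x = x - x.mean()
        spec = np.fft.rfft(x * w)
        p = scale * np.abs(spec) ** 2
        if nper % 2 == 0:
            p[1:-1] *= 2
        else:
            p[1:] *= 2
        segs.append(p)
        start += step
    f = np.fft.rfftfreq(nper, 1 / fs)
    return f, np.mean(segs, axis=0)


def band_fraction_oracle(tc, fs, window_s=2.0):
    """Mean Welch PSD per canonical band, normalized over the five bands."""
    bands = [(0.3, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 40.0), (40.0, 100.0)]
    f, p = welch_oracle(tc, fs, window_s)
    means = []
    for lo, hi in bands:
        m = (f >= lo) & (f < hi)
        means.append(p[m].mean() if m.any() else 0.0)
    total = sum(means)
    if total <= 0:
        return [0.0] * 5
    return [v / total for v in means]


def mif_oracle(tc, fs, window_s=2.0):
    f, p = welch_oracle(tc, fs, window_s)
    lo = p[(f >= 0.0) & (f <= 20.0)].sum()
    hi = p[(f >= 21.0) & (f <= 100.0)].sum()
    if lo + hi == 0 or lo > hi:
        return 0.0
    return hi / (lo + hi)


def sliding_corr_oracle(tc, template):
    """Dense per-window |Pearson r| with np.corrcoef, one window at a time."""
    n = len(template)
    out = []
    for start in range(len(tc) - n + 1):
        w = np.asarray(tc[start : start + n], dtype=float)
        if w.std() == 0:
            out.append(0.0)
            continue
        out.append(abs(np.corrcoef(w, template)[0, 1]))
    return np.array(out)


def template_corr_oracle(tc, template, threshold=0.65):
    r = sliding_corr_oracle(tc, template)
    kept = r[r >= threshold]
    return float(kept.mean()) if kept.size else 0.0


def entropy_feature_oracle(tcs, fs, bins=100, z_thr=1.64, floor=0.2, segment_s=5.0):
    """EF per IC via manual binning (searchsorted) and explicit z-scores."""
    tcs = np.asarray(tcs, dtype=float)
    n = int(round(segment_s * fs))
    n_seg = tcs.shape[1] // n
    h = np.zeros((tcs.shape[0], n_seg))
    for i in range(tcs.shape[0]):
        for j in range(n_seg):
            seg = tcs[i, j * n : (j + 1) * n]
            lo, hi = seg.min(), seg.max()
            if hi == lo:
                h[i, j] = 0.0
                continue
            edges = np.linspace(lo, hi, bins + 1)
            which = np.searchsorted(edges, seg, side="right") - 1
            which[which == bins] = bins - 1  # the max lands in the last bin
            counts = np.zeros(bins)
            for b in which:
                counts[b] += 1
            p = counts[counts > 0] / seg.size
            h[i, j] = -sum(pi * np.log(pi) for pi in p)
    ef = np.zeros(tcs.shape[0])
    for j in range(n_seg):
        col = h[:, j]
        mu, sd = col.mean(), col.std()
        if sd == 0:
            continue
        z = (col - mu) / sd
        ef += (np.abs(z) >= z_thr).astype(float)
    ef = ef / n_seg
    ef[ef <= floor] = 0.0
    return ef


def three_stage_rule_oracle(matrix, sizes, full_index):
    """Literal application of the three selection criteria; first-in-order ties."""
    matrix = np.asarray(matrix, dtype=float)
    full = matrix[full_index]
    stage1 = [
        i
        for i in range(matrix.shape[0])
        if i != full_index and all(matrix[i, j] >= full[j] for j in range(matrix.shape[1]))
    ]
    if not stage1:
        return full_index
    best_sum = max(matrix[i].sum() for i in stage1)
    stage2 = [i for i in stage1 if matrix[i].sum() == best_sum]
    best_size = min(sizes[i] for i in stage2)
    stage3 = [i for i in stage2 if sizes[i] == best_size]
    return stage3[0]
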