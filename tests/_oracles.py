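"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles, deliberately
avoiding the library code paths (and, where practical, even the same FFT
routines), so agreement is evidence of correctness rather than shared bugs.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import welch


# ---------------------------------------------------------------------------
# MFCC: direct DFT -> explicit triangles -> log -> naive DCT-II


def brute_force_mfcc(x: np.ndarray, sample_rate=4000, window_ms=25.0, hop_ms=10.0,
                     n_mels=40, n_kept=13, nfft=128, log_floor=1e-12) -> np.ndarray:
    win = int(round(sample_rate * window_ms / 1000.0))
    hop = int(round(sample_rate * hop_ms / 1000.0))
    n_frames = 1 + (x.size - win) // hop
    n = np.arange(win)
    hann = 0.5 - 0.5 * np.cos(2.0 * np.pi * n / win)

    # explicit DFT matrix on the zero-padded frame
    k = np.arange(nfft // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(k, np.arange(nfft)) / nfft)

    # explicit HTK-mel triangles evaluated per bin
    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    pts = imel(np.linspace(mel(0.0), mel(sample_rate / 2.0), n_mels + 2))
    bin_freqs = k * sample_rate / nfft
    fb = np.zeros((n_mels, k.size))
    for m in range(n_mels):
        for b, f in enumerate(bin_freqs):
            if pts[m] <= f <= pts[m + 1]:
                denom = pts[m + 1] - pts[m]
                fb[m, b] = (f - pts[m]) / denom if denom > 0 else 0.0
            elif pts[m + 1] < f <= pts[m + 2]:
                denom = pts[m + 2] - pts[m + 1]
                fb[m, b] = (pts[m + 2] - f) / denom if denom > 0 else 0.0

    # naive orthonormal DCT-II matrix
    j = np.arange(n_mels)
    dct_mat = np.cos(np.pi * np.outer(np.arange(n_mels), (j + 0.5)) / n_mels)
    dct_mat *= np.sqrt(2.0 / n_mels)
    dct_mat[0] *= np.sqrt(0.5)

    out = np.zeros((n_kept, n_frames))
    for t in range(n_frames):
        frame = np.zeros(nfft)
        frame[:win] = x[t * hop : t * hop + win] * hann
        spec = dft @ frame
        power = np.abs(spec) ** 2
        logmel = np.log(fb @ power + log_floor)
        ceps = dct_mat @ logmel
        out[:, t] = ceps[1 : n_kept + 1]
    return out


# ---------------------------------------------------------------------------
# confusion-matrix metrics: explicit loops


def brute_force_metrics(cm: np.ndarray) -> dict:
    cm = np.asarray(cm)
    k = cm.shape[0]
    total = cm.sum()
    per_class = {}
    for c in range(k):
        tp = cm[c, c]
        fp = sum(cm[r, c] for r in range(k)) - tp
        fn = sum(cm[c, r] for r in range(k)) - tp
        tn = total - tp - fp - fn
        acc = (tp + tn) / total
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = dict(
            accuracy=acc, precision=prec, recall=rec, specificity=spec, f1=f1
        )
    macro = {
        m: sum(per_class[c][m] for c in range(k)) / k
        for m in ("accuracy", "precision", "recall", "specificity", "f1")
    }
    return {"per_class": per_class, "macro": macro}


# ---------------------------------------------------------------------------
# acoustic heuristics: transient counting and tonal prominence


def transient_count(x: np.ndarray, fs: int, ratio: float = 8.0) -> int:
    """Short-burst count: 15 ms window maxima of the locally normalised
    amplitude envelope, thresholded at median + ratio * MAD."""
    e = np.abs(x)
    local = median_filter(e, size=int(0.2 * fs), mode="nearest") + 1e-9
    c = e / local
    w = int(0.015 * fs)
    n = c.size // w
    seg = c[: n * w].reshape(n, w).max(axis=1)
    med = np.median(seg)
    mad = np.median(np.abs(seg - med)) + 1e-9
    return int(np.sum(seg > med + ratio * mad))


def tonal_prominence_db(x: np.ndarray, fs: int, band=(150.0, 900.0)) -> float:
    """Welch-spectrum peak over the band median, in dB."""
    f, p = welch(x, fs, nperseg=1024)
    sel = (f >= band[0]) & (f <= band[1])
    return float(10.0 * np.log10(p[sel].max() / (np.median(p[sel]) + 1e-30)))


def spectral_peak_hz(x: np.ndarray, fs: int, band=(50.0, 1500.0)) -> float:
    f, p = welch(x, fs, nperseg=2048)
    sel = (f >= band[0]) & (f <= band[1])
    return float(f[sel][np.argmax(p[sel])])


def heuristic_label(x: np.ndarray, fs: int) -> str:
    """Energy/peak rule-based classifier over the three classes."""
    if tonal_prominence_db(x, fs) > 10.0:
        return "wheeze"
    if transient_count(x, fs) >= 7:
        return "fine_crackle"
    return "normal"
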