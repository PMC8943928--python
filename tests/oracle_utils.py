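"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (per-sample
scans, per-window fits) so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def peaks_bruteforce(a) -> tuple[list[int], list[float]]:
    """All strict local maxima (plateau → first sample) and prominences.

    Prominence by the topographic definition: walk out from the peak on
    each side until a strictly higher sample or the series edge, take
    the minimum seen on each side, and subtract the higher of the two
    minima from the peak height.
    """
    a = [float(v) for v in a]
    n = len(a)
    idx: list[int] = []
    for i in range(1, n - 1):
        if a[i] > a[i - 1]:
            j = i
            while j + 1 < n and a[j + 1] == a[i]:
                j += 1
            if j + 1 < n and a[j + 1] < a[i]:
                idx.append(i)
    proms: list[float] = []
    for i in idx:
        m = a[i]
        lm = m
        j = i - 1
        while j >= 0 and a[j] <= m:
            if a[j] < lm:
                lm = a[j]
            j -= 1
        rm = m
        j = i + 1
        while j < n and a[j] <= m:
            if a[j] < rm:
                rm = a[j]
            j += 1
        proms.append(m - (lm if lm > rm else rm))
    return idx, proms


def loess_bruteforce(y, sample_rate, window, degree) -> np.ndarray:
    """Per-sample weighted polynomial fit: the definitional loess path."""
    y = np.asarray(y, dtype=float)
    n = y.size
    span = int(round(window * sample_rate))
    if span % 2 == 0:
        span += 1
    h = (span - 1) // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        x = np.arange(lo, hi, dtype=float) - i
        w = (1.0 - np.abs(x / (h + 1)) ** 3) ** 3
        deg = min(degree, hi - lo - 1)
        coef = np.polyfit(x, y[lo:hi], deg, w=np.sqrt(w))
        out[i] = np.polyval(coef, 0.0)
    return out


def all_series(length: int, alphabet=(0.0, 1.0, 2.0)) -> np.ndarray:
    """Every series of a given length over a small alphabet, one per row."""
    k = len(alphabet)
    m = k**length
    digits = (np.arange(m)[:, None] // k ** np.arange(length)[None, :]) % k
    return np.asarray(alphabet, dtype=float)[digits]
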