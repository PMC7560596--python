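"""Independent brute-force reference implementations used only by tests.

Deliberately naive: explicit double loops and per-window polyfits, sharing
no code with the package, so agreement with the vectorized implementation
is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def naive_dfa(series, n_scales=19, order=2, min_window=4, max_fraction=0.25):
    """Plain-loop DFA: returns (alpha, scales, fluctuations)."""
    x = np.asarray(series, dtype=float)
    total = len(x)
    mean = sum(x) / total
    prof = []
    acc = 0.0
    for v in x:
        acc += v - mean
        prof.append(acc)
    prof = np.array(prof)

    max_window = int(np.floor(total * max_fraction))
    raw = [
        min_window * (max_window / min_window) ** (i / (n_scales - 1))
        for i in range(n_scales)
    ]
    scales = sorted({int(round(s)) for s in raw})

    flucts = []
    for n in scales:
        k = len(prof) // n
        sq_sum = 0.0
        for w in range(k):
            seg = prof[w * n : (w + 1) * n]
            t = np.arange(n, dtype=float)
            coeffs = np.polyfit(t, seg, order)
            resid = seg - np.polyval(coeffs, t)
            sq_sum += float(np.mean(resid**2))
        flucts.append(np.sqrt(sq_sum / k))

    log_n = [np.log2(s) for s in scales]
    log_f = [np.log2(f) for f in flucts]
    slope = np.polyfit(log_n, log_f, 1)[0]
    return float(slope), scales, flucts


def naive_fluctuation(prof, n, order=2):
    """Single-scale fluctuation with explicit window loop."""
    prof = np.asarray(prof, dtype=float)
    k = len(prof) // n
    sq = 0.0
    for w in range(k):
        seg = prof[w * n : (w + 1) * n]
        t = np.arange(n, dtype=float)
        c = np.polyfit(t, seg, order)
        sq += float(np.mean((seg - np.polyval(c, t)) ** 2))
    return float(np.sqrt(sq / k))


def naive_precision_per_axis(x_deg, y_deg):
    """RMS successive angular displacement per axis, averaged across axes."""
    dx = [x_deg[i + 1] - x_deg[i] for i in range(len(x_deg) - 1)]
    dy = [y_deg[i + 1] - y_deg[i] for i in range(len(y_deg) - 1)]
    rms_x = (sum(d * d for d in dx) / len(dx)) ** 0.5
    rms_y = (sum(d * d for d in dy) / len(dy)) ** 0.5
    return 0.5 * (rms_x + rms_y)


def naive_corr_squared(a, b):
    """Pearson correlation squared via explicit sums."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((a[i] - ma) * (b[i] - mb) for i in range(n))
    va = sum((a[i] - ma) ** 2 for i in range(n))
    vb = sum((b[i] - mb) ** 2 for i in range(n))
    return (cov / (va * vb) ** 0.5) ** 2
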