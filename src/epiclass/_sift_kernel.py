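"""Compiled inner loop for envelope sifting.

Semantics mirror the public ``emd`` functions exactly: strict extrema with
plateau midpoints, natural cubic splines through extrema mirrored across
both record ends, zero crossings counted as sign changes of the nonzero
samples.  ``emd.sift`` delegates here; the pure NumPy/SciPy construction
remains available as ``emd.compute_envelopes`` and is tested against this
kernel for agreement.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _extrema(x):
    """Strict maxima/minima indices, plateau midpoints, endpoints excluded."""
    n = x.size
    maxima = np.empty(n, dtype=np.int64)
    minima = np.empty(n, dtype=np.int64)
    n_max = 0
    n_min = 0
    run_start = 0
    prev = x[0]
    last_dir = 0
    for i in range(1, n):
        if x[i] != prev:
            direction = 1 if x[i] > prev else -1
            if last_dir == 1 and direction == -1:
                maxima[n_max] = (run_start + i - 1) // 2
                n_max += 1
            elif last_dir == -1 and direction == 1:
                minima[n_min] = (run_start + i - 1) // 2
                n_min += 1
            last_dir = direction
            run_start = i
            prev = x[i]
    return maxima[:n_max], minima[:n_min]


@njit(cache=True)
def _zero_crossings(x):
    count = 0
    prev = 0.0
    for i in range(x.size):
        v = x[i]
        if v != 0.0:
            if prev != 0.0 and (v > 0.0) != (prev > 0.0):
                count += 1
            prev = v
    return count


@njit(cache=True)
def _natural_spline_envelope(t, v, n):
    """Evaluate the natural cubic spline through (t, v) at 0 .. n-1."""
    m = t.size
    # second derivatives via the Thomas algorithm (natural BC: M0 = Mm-1 = 0)
    M = np.zeros(m)
    if m > 2:
        a = np.empty(m - 2)
        b = np.empty(m - 2)
        c = np.empty(m - 2)
        d = np.empty(m - 2)
        for i in range(1, m - 1):
            h0 = t[i] - t[i - 1]
            h1 = t[i + 1] - t[i]
            a[i - 1] = h0
            b[i - 1] = 2.0 * (h0 + h1)
            c[i - 1] = h1
            d[i - 1] = 6.0 * ((v[i + 1] - v[i]) / h1 - (v[i] - v[i - 1]) / h0)
        for i in range(1, m - 2):
            w = a[i] / b[i - 1]
            b[i] -= w * c[i - 1]
            d[i] -= w * d[i - 1]
        M[m - 2] = d[m - 3] / b[m - 3]
        for i in range(m - 4, -1, -1):
            M[i + 1] = (d[i] - c[i] * M[i + 2]) / b[i]
    out = np.empty(n)
    seg = 0
    # per-segment cubic coefficients hoisted out of the sample loop
    h = t[1] - t[0]
    c3u = M[0] / (6.0 * h)
    c3w = M[1] / (6.0 * h)
    c1u = v[0] / h - M[0] * h / 6.0
    c1w = v[1] / h - M[1] * h / 6.0
    t_lo, t_hi = t[0], t[1]
    for j in range(n):
        xj = float(j)
        if xj > t_hi and seg < m - 2:
            while seg < m - 2 and t[seg + 1] < xj:
                seg += 1
            h = t[seg + 1] - t[seg]
            c3u = M[seg] / (6.0 * h)
            c3w = M[seg + 1] / (6.0 * h)
            c1u = v[seg] / h - M[seg] * h / 6.0
            c1w = v[seg + 1] / h - M[seg + 1] * h / 6.0
            t_lo, t_hi = t[seg], t[seg + 1]
        u = t_hi - xj
        w = xj - t_lo
        out[j] = (c3u * u * u + c1u) * u + (c3w * w * w + c1w) * w
    return out


@njit(cache=True)
def _mirrored(idx, val, n):
    """Reflect the two extrema nearest each end across the boundaries."""
    m = idx.size
    t = np.empty(m + 4)
    v = np.empty(m + 4)
    t[0] = -float(idx[1])
    t[1] = -float(idx[0])
    v[0] = val[1]
    v[1] = val[0]
    for i in range(m):
        t[i + 2] = float(idx[i])
        v[i + 2] = val[i]
    last = float(n - 1)
    t[m + 2] = 2.0 * last - float(idx[m - 1])
    t[m + 3] = 2.0 * last - float(idx[m - 2])
    v[m + 2] = val[m - 1]
    v[m + 3] = val[m - 2]
    return t, v


@njit(cache=True)
def mean_envelope(x):
    """(mean envelope, ok flag); ok is False when extrema are too few."""
    mx, mn = _extrema(x)
    if mx.size < 2 or mn.size < 2:
        return np.zeros(1), False
    tu, vu = _mirrored(mx, x[mx], x.size)
    tl, vl = _mirrored(mn, x[mn], x.size)
    upper = _natural_spline_envelope(tu, vu, x.size)
    lower = _natural_spline_envelope(tl, vl, x.size)
    return 0.5 * (upper + lower), True


@njit(cache=True)
def sift_kernel(signal, sd_threshold, max_iter):
    """Sift until SD < threshold with the mode condition satisfied.

    Returns (imf, iterations).  SD is the Cauchy ratio
    sum((h_prev - h)^2) / sum(h_prev^2); the mode condition is
    |#extrema - #zero-crossings| <= 1.
    """
    h = signal.copy()
    iterations = 0
    sd_ok = False  # SD verdict from the previous subtraction
    while iterations < max_iter:
        mx, mn = _extrema(h)
        if mx.size < 2 or mn.size < 2:
            break
        # the loop-top extrema scan doubles as the mode-condition check
        if sd_ok and abs(mx.size + mn.size - _zero_crossings(h)) <= 1:
            break
        tu, vu = _mirrored(mx, h[mx], h.size)
        tl, vl = _mirrored(mn, h[mn], h.size)
        upper = _natural_spline_envelope(tu, vu, h.size)
        lower = _natural_spline_envelope(tl, vl, h.size)
        denom = 0.0
        num = 0.0
        for i in range(h.size):
            env_i = 0.5 * (upper[i] + lower[i])
            denom += h[i] * h[i]
            num += env_i * env_i
            h[i] = h[i] - env_i
        iterations += 1
        sd = num / denom if denom > 0.0 else 0.0
        sd_ok = sd < sd_threshold
    return h, iterations
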