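"""Independent reference EMD used only as a cross-check oracle in tests.

Synthetic stand-in for an external reference implementation: it follows
the same documented algorithm as the package (strict extrema, envelopes
through the two extrema nearest each end reflected across the record
boundaries, natural cubic splines, Cauchy-SD stop with the mode
condition) but shares no code with it — extrema come from
``scipy.signal.argrelextrema``, the natural spline is solved as a dense
linear system and evaluated from its piecewise-polynomial form, and the
sifting loop has its own bookkeeping.  Agreement is a meaningful check
because a defect in either route's spline solve, mirroring or stopping
logic would decorrelate the IMFs.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import argrelextrema


def _natural_spline(knot_t: np.ndarray, knot_v: np.ndarray,
                    x: np.ndarray) -> np.ndarray:
    """Natural cubic spline by dense solve of the second-derivative system."""
    t, v = knot_t.astype(float), knot_v.astype(float)
    m = len(t)
    h = np.diff(t)
    A = np.zeros((m, m))
    rhs = np.zeros(m)
    A[0, 0] = A[-1, -1] = 1.0
    for i in range(1, m - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2.0 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 6.0 * ((v[i + 1] - v[i]) / h[i] - (v[i] - v[i - 1]) / h[i - 1])
    M = np.linalg.solve(A, rhs)
    seg = np.clip(np.searchsorted(t, x, side="right") - 1, 0, m - 2)
    hs, u, w = h[seg], t[seg + 1] - x, x - t[seg]
    return (M[seg] * u ** 3 + M[seg + 1] * w ** 3) / (6.0 * hs) \
        + (v[seg] / hs - M[seg] * hs / 6.0) * u \
        + (v[seg + 1] / hs - M[seg + 1] * hs / 6.0) * w


def _mirrored(idx: np.ndarray, vals: np.ndarray, n: int):
    t = np.concatenate(([-idx[1], -idx[0]], idx,
                        [2 * (n - 1) - idx[-1], 2 * (n - 1) - idx[-2]]))
    v = np.concatenate(([vals[1], vals[0]], vals, [vals[-1], vals[-2]]))
    return t, v


def _mode_condition(x: np.ndarray) -> bool:
    n_ext = len(argrelextrema(x, np.greater)[0]) + len(argrelextrema(x, np.less)[0])
    signs = np.sign(x[x != 0])
    zc = int(np.sum(signs[1:] != signs[:-1]))
    return abs(n_ext - zc) <= 1


def reference_emd(signal: np.ndarray, max_imfs: int = 3,
                  sd_threshold: float = 0.2,
                  max_iter: int = 300) -> list[np.ndarray]:
    residual = np.asarray(signal, dtype=float).copy()
    grid = np.arange(len(residual), dtype=float)
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima = argrelextrema(residual, np.greater)[0]
        minima = argrelextrema(residual, np.less)[0]
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = residual.copy()
        for _ in range(max_iter):
            maxima = argrelextrema(h, np.greater)[0]
            minima = argrelextrema(h, np.less)[0]
            if len(maxima) < 2 or len(minima) < 2:
                break
            upper = _natural_spline(*_mirrored(maxima, h[maxima], len(h)), grid)
            lower = _natural_spline(*_mirrored(minima, h[minima], len(h)), grid)
            prev = h
            h = h - 0.5 * (upper + lower)
            sd = float(np.sum((prev - h) ** 2) / np.sum(prev ** 2))
            if sd < sd_threshold and _mode_condition(h):
                break
        imfs.append(h)
        residual = residual - h
    return imfs
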