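"""Empirical mode decomposition by envelope sifting.

A signal is decomposed into intrinsic mode functions (IMFs): oscillatory
components whose extrema and zero-crossing counts differ by at most one.
Each IMF is obtained by repeatedly subtracting the mean of the upper and
lower cubic-spline envelopes (Huang's sifting), stopping when the Cauchy
standard-deviation ratio SD = sum((h_prev - h)^2) / sum(h_prev^2) falls
below a threshold and the mode condition holds.  Spline end swings are
mitigated by reflecting the two extrema nearest each end across the
record boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DegenerateInputError, MonotoneResidualError


@dataclass
class SiftCriteria:
    """Stopping rule for sifting.

    A candidate is accepted when the Cauchy ratio
    SD = sum((h_prev - h)^2) / sum(h_prev^2) drops below ``sd_threshold``
    (Huang's classical 0.2) AND the mode condition holds.  On broadband
    signals the joint stop can need well over a hundred passes, hence the
    generous iteration cap.
    """

    sd_threshold: float = 0.2
    max_sift_iter: int = 300
    max_imfs: int = 3

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise DegenerateInputError("sd_threshold must be > 0")
        if self.max_imfs < 1:
            raise DegenerateInputError("max_imfs must be >= 1")


@dataclass
class IMFSet:
    """Ordered IMFs plus the residual for one channel; sums to the input."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    n_sift_iterations: list[int] = field(default_factory=list)
    source_channel: str = ""

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out = out + imf
        return out


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    Flat plateaus count once, at their midpoint sample.  Endpoints are
    never extrema.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise DegenerateInputError("need a 1-D signal of length >= 3")
    # run-length encode equal-value plateaus
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [x.size - 1]))
    vals = x[starts]
    if vals.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(np.diff(vals))
    mids = (starts + ends) // 2
    interior = np.arange(1, vals.size - 1)
    is_max = (s[interior - 1] > 0) & (s[interior] < 0)
    is_min = (s[interior - 1] < 0) & (s[interior] > 0)
    return mids[interior[is_max]], mids[interior[is_min]]


def count_zero_crossings(signal: np.ndarray) -> int:
    """Sign changes, with exact zeros attached to the preceding sign."""
    x = np.asarray(signal, dtype=np.float64)
    s = np.sign(x)
    nz = s[s != 0]
    if nz.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(nz)))


def is_imf(signal: np.ndarray) -> bool:
    """Mode condition: |#extrema - #zero-crossings| <= 1."""
    mx, mn = find_extrema(signal)
    return abs((len(mx) + len(mn)) - count_zero_crossings(signal)) <= 1


def _mirrored_knots(idx: np.ndarray, values: np.ndarray,
                    n: int) -> tuple[np.ndarray, np.ndarray]:
    """Reflect the two extrema nearest each end across the boundaries."""
    left_t = (-idx[1], -idx[0]) if idx[0] > 0 else (-idx[2], -idx[1])
    left_v = (values[1], values[0]) if idx[0] > 0 else (values[2], values[1])
    last = n - 1
    if idx[-1] < last:
        right_t = (2 * last - idx[-1], 2 * last - idx[-2])
        right_v = (values[-1], values[-2])
    else:
        right_t = (2 * last - idx[-2], 2 * last - idx[-3])
        right_v = (values[-2], values[-3])
    t = np.concatenate((left_t, idx, right_t)).astype(float)
    v = np.concatenate((left_v, values, right_v))
    order = np.argsort(t)
    t, v = t[order], v[order]
    keep = np.concatenate(([True], np.diff(t) > 0))
    return t[keep], v[keep]


def compute_envelopes(signal: np.ndarray, maxima: np.ndarray,
                      minima: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic-spline envelopes through mirrored extrema."""
    x = np.asarray(signal, dtype=np.float64)
    if len(maxima) < 2 or len(minima) < 2:
        raise MonotoneResidualError(
            f"need >= 2 maxima and >= 2 minima, got {len(maxima)}/{len(minima)}")
    t = np.arange(x.size)
    tu, vu = _mirrored_knots(np.asarray(maxima), x[maxima], x.size)
    tl, vl = _mirrored_knots(np.asarray(minima), x[minima], x.size)
    upper = CubicSpline(tu, vu, bc_type="natural")(t)
    lower = CubicSpline(tl, vl, bc_type="natural")(t)
    return upper, lower


def _mean_envelope(x: np.ndarray) -> np.ndarray:
    mx, mn = find_extrema(x)
    upper, lower = compute_envelopes(x, mx, mn)
    return 0.5 * (upper + lower)


def sift(signal: np.ndarray, criteria: SiftCriteria | None = None
         ) -> tuple[np.ndarray, int]:
    """Extract one IMF candidate; returns (imf, number of sift iterations).

    Iterates h <- h - mean_envelope(h) until SD < sd_threshold with the
    mode condition satisfied, or max_sift_iter is reached.  If the working
    signal runs out of extrema mid-sift, the current candidate is returned.
    The loop runs in a compiled kernel whose envelope construction matches
    ``compute_envelopes`` sample for sample.
    """
    from ._sift_kernel import sift_kernel

    criteria = criteria or SiftCriteria()
    h = np.ascontiguousarray(signal, dtype=np.float64)
    imf, iterations = sift_kernel(h, criteria.sd_threshold,
                                  criteria.max_sift_iter)
    return imf, iterations


def decompose(signal: np.ndarray, criteria: SiftCriteria | None = None,
              source_channel: str = "") -> IMFSet:
    """Sequentially sift out up to ``max_imfs`` IMFs; the leftover is the
    residual, so IMFs + residual reconstruct the input exactly (floating
    point aside)."""
    criteria = criteria or SiftCriteria()
    residual = np.asarray(signal, dtype=np.float64).copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    for _ in range(criteria.max_imfs):
        mx, mn = find_extrema(residual) if residual.size >= 3 else ((), ())
        if len(mx) < 2 or len(mn) < 2:
            break  # monotone (or near-monotone) residual: stop
        imf, n_iter = sift(residual, criteria)
        imfs.append(imf)
        counts.append(n_iter)
        residual = residual - imf
    return IMFSet(imfs=imfs, residual=residual, n_sift_iterations=counts,
                  source_channel=source_channel)
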