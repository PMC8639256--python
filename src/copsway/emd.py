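"""Empirical mode decomposition (EMD) by envelope-mean sifting.

EMD decomposes a 1-D series into intrinsic mode functions (IMFs): the
sifting loop repeatedly subtracts the mean of the cubic-spline envelopes
through the local maxima and minima until the remainder is locally
zero-mean and satisfies the IMF property (the number of extrema and the
number of zero crossings differ by at most one).  The first IMF carries
the highest-frequency content; successive IMFs are extracted from the
running residual until it is monotonic or a level cap is reached.
Six levels suffice for 100 Hz COP sway records, whose informative
content lies below ~25 Hz.

Numerical choices
-----------------
* Sifting stops on the classic Cauchy-type criterion
  ``SD = sum((d_prev - d_new)**2) / sum(d_prev**2) < sd_threshold``
  (default 0.2) combined with the IMF extrema/zero-crossing property,
  with a hard cap of ``max_sift`` iterations (default 200 — noisy
  series commonly need 40-100 before the IMF property stabilises).
* Envelopes are natural cubic splines through the extrema, with the two
  extrema nearest each end mirrored about the end point to suppress
  boundary swings; with exactly two extrema of a kind the envelope is
  the straight line through them.
* Flat plateaus count as a single extremum at their midpoint sample.

The whole module is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "DegenerateSignalError",
    "NotSiftableError",
    "ImfDecomposition",
    "find_extrema",
    "envelope_mean",
    "sift_one_imf",
    "decompose",
    "count_zero_crossings",
    "is_imf",
]


#: sifting iteration cap; noise-dominated series often need 50-100
#: iterations before the extrema/zero-crossing property stabilises
MAX_SIFT_DEFAULT = 200


class DegenerateSignalError(ValueError):
    """Input too short or too featureless for the requested operation."""


class NotSiftableError(ValueError):
    """Fewer than two maxima or two minima: no envelope can be built."""


@dataclass(frozen=True)
class ImfDecomposition:
    """Ordered IMFs (index 1..K) plus the final residual.

    ``sift_counts[k-1]`` is the number of sifting iterations used for
    IMF ``k``; a negative entry flags an IMF returned at the iteration
    cap without meeting the stop criterion.
    """

    imfs: tuple
    residual: np.ndarray
    sift_counts: tuple

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    @property
    def source_length(self) -> int:
        return len(self.residual)

    def imf(self, level: int):
        """Return IMF ``level`` (1-based) or None if not extracted."""
        if not 1 <= level:
            raise ValueError("IMF levels are 1-based")
        if level > len(self.imfs):
            return None
        return self.imfs[level - 1]

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out

    def to_frame(self, source=None):
        """Diagnostic table: columns input, imf1..imfK, residual."""
        import pandas as pd

        data = {}
        if source is not None:
            data["input"] = np.asarray(source, float)
        for k, imf in enumerate(self.imfs, start=1):
            data[f"imf{k}"] = imf
        data["residual"] = self.residual
        return pd.DataFrame(data)


def find_extrema(series):
    """Locate strict interior extrema; plateaus contribute their midpoint.

    Returns ``(max_idx, max_val, min_idx, min_val)`` as arrays.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise DegenerateSignalError("need a 1-D series of length >= 3")

    # compress runs of equal values so a plateau behaves as one sample
    keep = np.empty(len(x), dtype=bool)
    keep[0] = True
    keep[1:] = x[1:] != x[:-1]
    starts = np.flatnonzero(keep)                      # run start indices
    ends = np.append(starts[1:], len(x)) - 1           # run end indices
    mids = (starts + ends) // 2
    y = x[starts]

    if len(y) < 3:
        empty = np.array([], dtype=int)
        return empty, np.array([]), empty.copy(), np.array([])

    d = np.sign(np.diff(y))
    interior = np.arange(1, len(y) - 1)
    turn = d[:-1] * d[1:]                              # <0 at a strict turn
    max_pos = interior[(turn < 0) & (d[:-1] > 0)]
    min_pos = interior[(turn < 0) & (d[:-1] < 0)]
    max_idx = mids[max_pos]
    min_idx = mids[min_pos]
    return max_idx, x[max_idx], min_idx, x[min_idx]


def count_zero_crossings(series) -> int:
    """Sign changes of the series, ignoring exact zeros between them."""
    x = np.asarray(series, dtype=float)
    s = np.sign(x)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(s[:-1] != s[1:]))


def is_imf(series) -> bool:
    """IMF defining property: |#extrema - #zero crossings| <= 1."""
    try:
        mx, _, mn, _ = find_extrema(series)
    except DegenerateSignalError:
        return False
    n_ext = len(mx) + len(mn)
    return abs(n_ext - count_zero_crossings(series)) <= 1


def _envelope(n: int, idx: np.ndarray, val: np.ndarray) -> np.ndarray:
    """Evaluate one envelope over samples 0..n-1 with mirrored ends."""
    if len(idx) < 2:
        raise NotSiftableError("need at least 2 extrema for an envelope")
    if len(idx) == 2:
        # straight line through the two extrema, extended to both ends
        slope = (val[1] - val[0]) / (idx[1] - idx[0])
        return val[0] + slope * (np.arange(n) - idx[0])

    # mirror the two extrema nearest each end about the end samples
    left_i = 2 * 0 - idx[:2][::-1]
    left_v = val[:2][::-1]
    right_i = 2 * (n - 1) - idx[-2:][::-1]
    right_v = val[-2:][::-1]
    xi = np.concatenate([left_i, idx, right_i]).astype(float)
    yi = np.concatenate([left_v, val, right_v])
    # mirrored points can collide with originals when an extremum sits
    # exactly at an end sample; keep strictly increasing knots
    keep = np.empty(len(xi), dtype=bool)
    keep[0] = True
    keep[1:] = np.diff(xi) > 0
    spline = CubicSpline(xi[keep], yi[keep], bc_type="natural")
    return spline(np.arange(n))


def envelope_mean(series, extrema=None) -> np.ndarray:
    """Mean of the upper (maxima) and lower (minima) cubic envelopes."""
    x = np.asarray(series, dtype=float)
    if extrema is None:
        extrema = find_extrema(x)
    max_idx, max_val, min_idx, min_val = extrema
    if len(max_idx) < 2 or len(min_idx) < 2:
        raise NotSiftableError(
            f"need >= 2 maxima and minima, found {len(max_idx)} / {len(min_idx)}"
        )
    upper = _envelope(len(x), np.asarray(max_idx), np.asarray(max_val))
    lower = _envelope(len(x), np.asarray(min_idx), np.asarray(min_val))
    return 0.5 * (upper + lower)


def sift_one_imf(series, sd_threshold: float = 0.2, max_sift: int = MAX_SIFT_DEFAULT):
    """Extract one IMF candidate by repeated envelope-mean subtraction.

    Returns ``(imf, iterations, converged)``.  If the stop criterion is
    not met within ``max_sift`` iterations the current candidate is
    returned with ``converged=False`` and a warning.
    """
    d = np.asarray(series, dtype=float).copy()
    for it in range(1, max_sift + 1):
        try:
            m = envelope_mean(d)
        except (NotSiftableError, DegenerateSignalError):
            if it == 1:
                raise
            return d, it - 1, True  # ran out of extrema: d is as refined as it gets
        d_new = d - m
        denom = float(np.sum(d * d))
        sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
        d = d_new
        if sd < sd_threshold and is_imf(d):
            return d, it, True
    warnings.warn(
        f"sifting did not converge within {max_sift} iterations", RuntimeWarning
    )
    return d, max_sift, False


def decompose(
    series,
    max_imf: int = 6,
    sd_threshold: float = 0.2,
    max_sift: int = MAX_SIFT_DEFAULT,
) -> ImfDecomposition:
    """Decompose a series into up to ``max_imf`` IMFs plus a residual.

    Extraction stops early once the running residual is monotonic or has
    fewer than two maxima or two minima.  The telescoping construction
    guarantees ``sum(imfs) + residual == input`` to rounding error.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise DegenerateSignalError("need a 1-D series of length >= 10")
    if max_imf < 1:
        raise ValueError("max_imf must be >= 1")

    residual = x.copy()
    imfs = []
    counts = []
    for _ in range(max_imf):
        try:
            mx, _, mn, _ = find_extrema(residual)
        except DegenerateSignalError:
            break
        if len(mx) < 2 or len(mn) < 2:
            break
        imf, iters, converged = sift_one_imf(
            residual, sd_threshold=sd_threshold, max_sift=max_sift
        )
        imfs.append(imf)
        counts.append(iters if converged else -iters)
        residual = residual - imf
    return ImfDecomposition(tuple(imfs), residual, tuple(counts))
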