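"""Sway feature statistics on raw COP series and their IMF levels.

Five statistics summarise each series:

====  ==================  ======================================
id    feature             domain
====  ==================  ======================================
1     RMSD                time (root-mean-square sway)
2     median frequency    frequency (half-power frequency, Hz)
3     total power         frequency (integrated spectral power)
4     approximate entropy nonlinear (regularity, ApEn)
5     sample entropy      nonlinear (regularity, SampEn)
====  ==================  ======================================

Features are coded ``axis.level.feature``: axis ``x`` (anterior-
posterior) or ``y`` (mediolateral); level 0 for the raw series and 1-6
for IMF1-IMF6; feature 1-5 as above — e.g. ``x.0.1`` is the RMSD of the
raw COPx series and ``y.2.4`` the ApEn of COPy's second IMF.  The full
grid is 2 x 7 x 5 = 70 codes per trial; a level the decomposition did
not reach yields NaN ("not available"), never a zero-filled series.

Entropies use embedding dimension ``m = 2`` and tolerance
``r = 0.2 * STD`` of the series they are computed on (each IMF uses its
own STD), under the Chebyshev distance.  Spectral features are defined
on a mean-removed one-sided periodogram, which satisfies the discrete
Parseval identity: integrated power equals the centered variance.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from . import emd as _emd
from ._entropy import apen_kernel, entropy_kernel, sampen_counts
from .io import CopTrace

AXES = ("x", "y")
LEVELS = tuple(range(7))
FEATURE_IDS = (1, 2, 3, 4, 5)
FEATURE_NAMES = {
    1: "rmsd",
    2: "median_frequency",
    3: "total_power",
    4: "approx_entropy",
    5: "sample_entropy",
}
#: feature ids by domain: time / frequency / nonlinear
DOMAINS = {"time": (1,), "frequency": (2, 3), "nonlinear": (4, 5)}

META_COLUMNS = ("subject_id", "group", "condition", "trial")


class FeatureUndefinedError(ValueError):
    """The statistic is undefined on this input (reported NaN downstream)."""


def feature_code(axis: str, level: int, feature_id: int) -> str:
    """Build the ``axis.level.feature`` code string, validating each part."""
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    if level not in LEVELS:
        raise ValueError(f"level must be in 0..6, got {level!r}")
    if feature_id not in FEATURE_IDS:
        raise ValueError(f"feature_id must be in 1..5, got {feature_id!r}")
    return f"{axis}.{level}.{feature_id}"


def parse_code(code: str):
    """Inverse of :func:`feature_code` → ``(axis, level, feature_id)``."""
    axis, level, fid = code.split(".")
    level, fid = int(level), int(fid)
    if axis not in AXES or level not in LEVELS or fid not in FEATURE_IDS:
        raise ValueError(f"malformed feature code {code!r}")
    return axis, level, fid


def all_codes() -> list:
    return [feature_code(a, l, f) for a in AXES for l in LEVELS for f in FEATURE_IDS]


def level_codes(level: int) -> list:
    """The 10 codes of one decomposition level ({x,y} x 5 features)."""
    return [feature_code(a, level, f) for a in AXES for f in FEATURE_IDS]


def rmsd(series) -> float:
    """Root-mean-square deviation about the series mean."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D series of length >= 2")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def power_spectrum(series, sampling_rate: float):
    """One-sided periodogram over (0, Nyquist], DC bin excluded.

    The series is mean-centered internally; the returned density
    integrates (sum * df) to the centered variance (Parseval).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("need a 1-D series of length >= 8")
    f, p = periodogram(
        x - x.mean(), fs=sampling_rate, window="boxcar", detrend=False
    )
    return f[1:], p[1:]


def total_power(series, sampling_rate: float) -> float:
    """Integrated one-sided spectral power; equals the centered variance."""
    f, p = power_spectrum(series, sampling_rate)
    df = f[1] - f[0] if len(f) > 1 else f[0]
    return float(p.sum() * df)


def median_frequency(series, sampling_rate: float) -> float:
    """Smallest frequency below which half of the spectral power lies.

    Linearly interpolated between the two bins straddling the half-power
    point; undefined (raises) for a zero-power series.
    """
    f, p = power_spectrum(series, sampling_rate)
    total = p.sum()
    if total <= 0:
        raise FeatureUndefinedError("zero total power: median frequency undefined")
    cum = np.cumsum(p)
    half = total / 2.0
    k = int(np.searchsorted(cum, half))
    if k == 0:
        return float(f[0])
    prev = cum[k - 1]
    frac = (half - prev) / (cum[k] - prev)
    return float(f[k - 1] + frac * (f[k] - f[k - 1]))


def approx_entropy(series, m: int = 2, r_fraction: float = 0.2) -> float:
    """Approximate entropy ApEn(m, r) with r = r_fraction * STD.

    Template self-matches are included.  A constant series returns 0 by
    the continuity convention (every template matches every other).
    """
    x = np.ascontiguousarray(series, dtype=float)
    if x.ndim != 1 or len(x) < m + 2:
        raise ValueError(f"need a 1-D series of length >= {m + 2}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    return float(apen_kernel(x, m, 1, r_fraction * sd))


def sample_entropy(
    series, m: int = 2, r_fraction: float = 0.2, tau: int = 1
) -> float:
    """Sample entropy SampEn(m, r) = -ln(A/B), self-matches excluded.

    ``tau`` is the embedding lag (1 = consecutive samples).  Undefined
    (raises :class:`FeatureUndefinedError`) for a constant series
    (r = 0) or when either pair count is zero — never silently infinite.
    """
    x = np.ascontiguousarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if x.ndim != 1 or len(x) < (m + 1) * tau + 1:
        raise ValueError("series too short for the requested embedding")
    sd = float(np.std(x))
    if sd == 0.0:
        raise FeatureUndefinedError("constant series: r = 0, SampEn undefined")
    a, b = sampen_counts(x, m, tau, r_fraction * sd)
    if a == 0 or b == 0:
        raise FeatureUndefinedError(f"degenerate pair counts A={a}, B={b}")
    return float(-math.log(a / b))


def _series_features(x, sampling_rate, m, r_fraction):
    """All five statistics of one series; NaN where undefined.

    Both entropies share one template-matching pass (same m, same r).
    """
    out = {}
    out[1] = rmsd(x)
    try:
        out[2] = median_frequency(x, sampling_rate)
    except FeatureUndefinedError:
        out[2] = np.nan
    out[3] = total_power(x, sampling_rate)
    xc = np.ascontiguousarray(x, dtype=float)
    sd = float(np.std(xc))
    if sd == 0.0:
        out[4] = 0.0        # ApEn continuity convention
        out[5] = np.nan     # SampEn undefined at r = 0
    else:
        apen, a, b = entropy_kernel(xc, m, 1, r_fraction * sd)
        out[4] = float(apen)
        out[5] = float(-math.log(a / b)) if (a > 0 and b > 0) else np.nan
    return out


def extract_features(
    trace: CopTrace,
    decomposition_x: Optional[_emd.ImfDecomposition] = None,
    decomposition_y: Optional[_emd.ImfDecomposition] = None,
    max_imf: int = 6,
    m: int = 2,
    r_fraction: float = 0.2,
    sd_threshold: float = 0.2,
    max_sift: int = 200,
) -> dict:
    """Compute the 70-code feature vector of one trial.

    Decompositions may be passed in (e.g. from a cache); otherwise each
    axis is decomposed here.  IMF levels the decomposition did not reach
    are reported NaN.  Per-feature failures are recorded as NaN and
    never abort the vector.
    """
    decs = {
        "x": decomposition_x
        or _emd.decompose(trace.cop_x, max_imf=max_imf,
                          sd_threshold=sd_threshold, max_sift=max_sift),
        "y": decomposition_y
        or _emd.decompose(trace.cop_y, max_imf=max_imf,
                          sd_threshold=sd_threshold, max_sift=max_sift),
    }
    values = {}
    for axis in AXES:
        dec = decs[axis]
        for level in LEVELS:
            x = trace.axis(axis) if level == 0 else dec.imf(level)
            if x is None:
                for fid in FEATURE_IDS:
                    values[feature_code(axis, level, fid)] = np.nan
                continue
            stats = _series_features(x, trace.sampling_rate, m, r_fraction)
            for fid, val in stats.items():
                values[feature_code(axis, level, fid)] = val
    return values


def feature_table(
    traces: Iterable[CopTrace],
    max_imf: int = 6,
    m: int = 2,
    r_fraction: float = 0.2,
    sd_threshold: float = 0.2,
    max_sift: int = 200,
) -> pd.DataFrame:
    """Feature table over trials: metadata columns plus the 70 codes."""
    rows = []
    for tr in traces:
        row = {
            "subject_id": tr.subject_id,
            "group": tr.group_label,
            "condition": tr.condition,
            "trial": tr.trial_index,
        }
        row.update(
            extract_features(
                tr, max_imf=max_imf, m=m, r_fraction=r_fraction,
                sd_threshold=sd_threshold, max_sift=max_sift,
            )
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + all_codes())


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
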