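"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: naive pure-Python
loops over explicit template lists, against which the optimised
implementations are compared.
"""

import math

import numpy as np


def apen_bruteforce(series, m=2, r=None):
    """ApEn by exhaustive template counting (self-matches included)."""
    x = [float(v) for v in series]
    n = len(x)

    def phi(k):
        templates = [x[i:i + k] for i in range(n - k + 1)]
        nt = len(templates)
        total = 0.0
        for ti in templates:
            c = 0
            for tj in templates:
                if max(abs(a - b) for a, b in zip(ti, tj)) <= r:
                    c += 1
            total += math.log(c / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def sampen_bruteforce(series, m=2, r=None):
    """SampEn by exhaustive pair counting (self-matches excluded)."""
    x = [float(v) for v in series]
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(p - q) for p, q in zip(x[i:i + m], x[j:j + m])) <= r:
                b += 1
                if max(
                    abs(p - q) for p, q in zip(x[i:i + m + 1], x[j:j + m + 1])
                ) <= r:
                    a += 1
    return -math.log(a / b)


def median_frequency_bruteforce(series, sampling_rate):
    """Half-power frequency from a raw FFT cumulative sum."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    # one-sided convention: double everything except DC and Nyquist
    spec = 2.0 * spec
    if n % 2 == 0:
        spec[-1] /= 2.0
    spec, freqs = spec[1:], freqs[1:]  # drop DC
    cum = np.cumsum(spec)
    half = cum[-1] / 2.0
    k = int(np.searchsorted(cum, half))
    if k == 0:
        return float(freqs[0])
    prev = cum[k - 1]
    frac = (half - prev) / (cum[k] - prev)
    return float(freqs[k - 1] + frac * (freqs[k] - freqs[k - 1]))
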