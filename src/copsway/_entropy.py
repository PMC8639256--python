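"""Numba kernels for template-matching entropy statistics.

Both statistics compare delay-embedded templates under the Chebyshev
(maximum-coordinate) distance:

* ApEn(m, r) = phi_m - phi_{m+1}, with phi_k the mean log self-match
  rate of k-length templates, self-matches included;
* SampEn(m, r) = -ln(A/B), with B (A) the number of unordered template
  pairs of length m (m+1) within r, self-matches excluded, both counted
  over the N - m*tau templates that extend to length m+1.

One O(N^2) pair scan serves both: a pair within r at length m
increments the ApEn match counters of both templates and B, and stays
within r at length m+1 iff its last-coordinate gap is within r.  The
tau - ... few m-length templates with no m+1 extension are swept
separately.  numba compilation makes the scan fast enough to run on
every IMF of every trial of a cohort.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def entropy_kernel(x, m, tau, r):
    """Shared pair scan.

    Returns ``(apen, a, b)``: the approximate entropy and the sample-
    entropy pair counts at template lengths m+1 (a) and m (b).
    """
    n = len(x)
    nt1 = n - (m - 1) * tau          # templates of length m
    nt2 = n - m * tau                # templates of length m+1
    c1 = np.ones(nt1)                # self-match included
    c2 = np.ones(nt2)
    a = 0
    b = 0
    for i in range(nt2):
        for j in range(i + 1, nt2):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k * tau] - x[j + k * tau])
                if t > d:
                    d = t
            if d <= r:
                c1[i] += 1.0
                c1[j] += 1.0
                b += 1
                # length-(m+1) distance is max(d, last-coordinate gap)
                if abs(x[i + m * tau] - x[j + m * tau]) <= r:
                    c2[i] += 1.0
                    c2[j] += 1.0
                    a += 1
    # m-length templates that cannot extend to m+1 (indices nt2..nt1-1)
    for j in range(nt2, nt1):
        for i in range(j):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k * tau] - x[j + k * tau])
                if t > d:
                    d = t
            if d <= r:
                c1[i] += 1.0
                c1[j] += 1.0
    phi1 = 0.0
    for i in range(nt1):
        phi1 += np.log(c1[i] / nt1)
    phi1 /= nt1
    phi2 = 0.0
    for i in range(nt2):
        phi2 += np.log(c2[i] / nt2)
    phi2 /= nt2
    return phi1 - phi2, a, b


def apen_kernel(x, m, tau, r):
    return entropy_kernel(x, m, tau, r)[0]


def sampen_counts(x, m, tau, r):
    _, a, b = entropy_kernel(x, m, tau, r)
    return a, b
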