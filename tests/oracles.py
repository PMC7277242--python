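"""Independent brute-force oracles for the demographic statistics.

Everything here is computed by direct, literal summation — explicit Python
loops, Kronecker deltas evaluated as equality checks, no recurrences,
cumulative tricks or convolutions — so these functions stay independent of
the vectorised implementations they are used to check.
"""

import numpy as np


def oracle_remaining_lifespan(l):
    l = list(l) + [0.0]
    out = np.full(len(l) - 1, np.nan)
    for i in range(len(l) - 1):
        if l[i] <= 0:
            continue
        num = den = 0.0
        for k in range(i, len(l) - 1):
            death = l[k] - l[k + 1]
            num += (k - i) * death
            den += death
        out[i] = num / den
    return out


def oracle_metrics(l, m):
    """(B, E, PrT, PrR) by direct cumulative scan and formula evaluation."""
    e = oracle_remaining_lifespan(l)
    total = sum(m)
    cum = 0.0
    B = E = None
    for i, mi in enumerate(m):
        cum += mi
        if B is None and cum >= 0.05 * total - 1e-12 * total:
            B = i
        if E is None and cum >= 0.95 * total - 1e-12 * total:
            E = i
    PrR = (l[E] * e[E]) / (l[B] * e[B])
    return B, E, e[E], PrR


def oracle_efficacy(l, m):
    """Literal evaluation of the four care-efficacy sums."""
    n = len(l)
    c_m = np.zeros(n)
    c_ltr = np.zeros(n)
    c_lts = np.zeros(n)
    c_gm = np.zeros(n)
    for i in range(n):
        for shift, l_idx in ((2, 1), (1, 0)):
            if 0 <= i - shift < n:
                c_m[i] += m[i - shift] * l[l_idx]
        for j in range(8, i - 1):  # j <= i - 2
            c_lts[i] += m[j] * l[i - j - 1]
            if j <= i - 9:
                c_ltr[i] += m[j] * l[i - j - 1]
        for j in range(8, i):  # j <= i - 1
            for k in range(0, i):  # k <= i - 1
                for delta_arg, l_factor in ((i - j - k - 3, l[1]),
                                            (i - j - k - 2, l[0])):
                    if delta_arg == 0:
                        c_gm[i] += (m[j] / 2.0) * l[k] * m[k] * l_factor
    return c_m, c_ltr, c_lts, c_gm


def random_toy_table(rng, n_stages=102):
    """Random decreasing survivorship plus a random fecundity block."""
    from pprls import LifeTable

    q = rng.uniform(0.3, 1.0, size=n_stages)
    l = np.ones(n_stages)
    l[1:] = np.cumprod(q[:-1])
    m = np.zeros(n_stages)
    hi = rng.integers(12, n_stages)
    m[8:hi] = rng.uniform(0, 0.8, size=hi - 8)
    return LifeTable(l=l, m=m)
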