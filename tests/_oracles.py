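"""Independent brute-force oracles, coded with explicit loops.

These deliberately share no code with the package: the conditional
binomial small-p enumeration goes through scipy.stats.binom, and the TMM
evaluation walks the published algorithm step by step with plain Python
loops.  They exist to pin the implementations down, not to be fast.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import binom


def binomial_smallp_oracle(sum_a: int, sum_b: int, n_a: int, n_b: int) -> float:
    """Two-sided conditional binomial p-value by full enumeration.

    Conditional on the total s, the focal-group sum is Binomial(s, q) with
    q = n_a / (n_a + n_b) under the Poisson null; the p-value sums the
    probabilities of every outcome no more likely than the observed one
    (relative tie tolerance 1e-7, the R convention).
    """
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    q = n_a / (n_a + n_b)
    p_obs = binom.pmf(sum_a, s, q)
    total = 0.0
    for a in range(s + 1):
        p_a = binom.pmf(a, s, q)
        if p_a <= p_obs * (1.0 + 1e-7):
            total += p_a
    return min(1.0, total)


def _quantile_type7(values: list[float], p: float) -> float:
    """Linear-interpolation quantile (R type 7 / numpy default)."""
    xs = sorted(values)
    h = (len(xs) - 1) * p
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def _average_ranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_factors_oracle(
    counts: np.ndarray,
    library_sizes: np.ndarray,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> list[float]:
    """Step-by-step TMM factors, explicit loops throughout.

    (1) reference column = the one whose 75th-percentile count-per-library
    is closest to the mean of those quantiles; (2) per column vs reference,
    over rows positive in both, M = log2 ratio of library-scaled
    proportions and A = their average log2; (3) double trim by average
    rank: drop the top/bottom trim_m fraction by M and trim_a by A;
    (4) factor = 2^(inverse-variance weighted mean of kept M), variance by
    the delta method; (5) rescale all factors to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    n_rows, n_cols = counts.shape
    lib = [float(x) for x in library_sizes]

    f75 = []
    for z in range(n_cols):
        f75.append(_quantile_type7(list(counts[:, z]), 0.75) / lib[z])
    mean_f75 = sum(f75) / n_cols
    ref = min(range(n_cols), key=lambda z: abs(f75[z] - mean_f75))

    raw = []
    for z in range(n_cols):
        if z == ref:
            raw.append(1.0)
            continue
        ms, as_, vs = [], [], []
        for g in range(n_rows):
            o, r = counts[g, z], counts[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[z], r / lib[ref]
                ms.append(math.log2(po / pr))
                as_.append(0.5 * (math.log2(po) + math.log2(pr)))
                vs.append((lib[z] - o) / (lib[z] * o) + (lib[ref] - r) / (lib[ref] * r))
        if not ms:
            raw.append(1.0)
            continue
        if max(abs(m) for m in ms) < 1e-6:
            raw.append(1.0)
            continue
        n = len(ms)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = _average_ranks(ms)
        rank_a = _average_ranks(as_)
        num = den = 0.0
        kept_any = False
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ms[i] / vs[i]
                den += 1.0 / vs[i]
                kept_any = True
        raw.append(2.0 ** (num / den) if kept_any else 1.0)

    log_gm = sum(math.log(f) for f in raw) / n_cols
    return [f / math.exp(log_gm) for f in raw]
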