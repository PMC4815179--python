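"""One-vs-rest negative-binomial conditional exact tests across zones.

Each zone is compared against the pooled remaining zones.  Counts are
first scaled to a common library size (geometric mean of the effective
sizes), after which the group sums are negative-binomial under the null of
equal relative abundance: group A (the focal zone, n_a libraries) has mean
n_a*m and dispersion phi/n_a, group B the complement.  Conditioning on the
total s = sum_a + sum_b gives a discrete conditional distribution over
sum_a (a two-category Dirichlet-multinomial; conditional binomial when
phi = 0), and the two-sided p-value sums the probabilities of all outcomes
no more likely than the observed one (the "small-p" rule).

The study pooled triplicate samples into a single library per zone, so the
dispersion phi cannot be estimated from the design; it enters as an
explicit parameter with a Poisson mode for phi = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm as _norm
from statsmodels.stats.multitest import multipletests

from .io import RunConfig, ZoneCountTable
from .normalization import NormalizationResult

__all__ = [
    "equalize_libraries",
    "nb_exact_pvalue",
    "one_vs_rest_tests",
    "adjust_pvalues",
    "POISSON_EPS",
    "MAX_EXACT_TOTAL",
]

#: dispersions at or below this are treated as Poisson (conditional binomial)
POISSON_EPS = 1e-8
#: totals above this switch from exact enumeration to a normal approximation
MAX_EXACT_TOTAL = 10_000
#: relative tolerance when comparing outcome probabilities to the observed one
_TIE_REL = 1e-7


def equalize_libraries(
    counts: np.ndarray, effective_library_sizes: np.ndarray
) -> tuple[np.ndarray, float]:
    """Scale counts to a common library size (geometric mean of sizes).

    Returns the adjusted integer matrix (rounded half-to-even) and the
    common size.  The conditional exact test assumes equal library sizes,
    which real zones never have; this is the standard pseudo-count step.
    """
    sizes = np.asarray(effective_library_sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("effective library sizes must be positive")
    # prod**(1/n) keeps exact-ratio cases exact (e.g. sizes 4e6 and 1e6)
    common = float(np.prod(sizes) ** (1.0 / sizes.size))
    adjusted = np.rint(np.asarray(counts, dtype=float) * (common / sizes))
    return adjusted.astype(np.int64), common


def _conditional_logpmf(s: int, n_a: int, n_b: int, dispersion: float) -> np.ndarray:
    """log P(sum_a = a | total = s) for a = 0..s under the null."""
    a = np.arange(s + 1, dtype=float)
    if dispersion <= POISSON_EPS:
        q = n_a / (n_a + n_b)
        lp = (
            gammaln(s + 1.0)
            - gammaln(a + 1.0)
            - gammaln(s - a + 1.0)
            + a * np.log(q)
            + (s - a) * np.log1p(-q)
        )
    else:
        r_a = n_a / dispersion
        r_b = n_b / dispersion
        lp = (
            gammaln(a + r_a)
            - gammaln(a + 1.0)
            + gammaln(s - a + r_b)
            - gammaln(s - a + 1.0)
        )
    return lp - logsumexp(lp)


def _smallp_from_logpmf(logpmf: np.ndarray, observed: int) -> float:
    pmf = np.exp(logpmf)
    mask = pmf <= pmf[observed] * (1.0 + _TIE_REL)
    if mask.all():  # observed at the mode: every outcome is as likely or less
        return 1.0
    p = float(pmf[mask].sum())
    return min(1.0, max(p, np.finfo(float).tiny))


def _normal_approx_pvalue(
    s: int, n_a: int, n_b: int, observed: int, dispersion: float
) -> float:
    q = n_a / (n_a + n_b)
    mean = s * q
    if dispersion <= POISSON_EPS:
        var = s * q * (1.0 - q)
    else:
        ab = (n_a + n_b) / dispersion
        var = s * q * (1.0 - q) * (ab + s) / (ab + 1.0)
    dev = abs(observed - mean) - 0.5  # continuity correction
    if dev <= 0 or var <= 0:
        return 1.0
    p = float(min(1.0, 2.0 * _norm.sf(dev / np.sqrt(var))))
    return max(p, np.finfo(float).tiny)


def nb_exact_pvalue(
    sum_a: int,
    sum_b: int,
    n_a: int,
    n_b: int,
    dispersion: float,
    max_exact_total: int = MAX_EXACT_TOTAL,
) -> float:
    """Two-sided conditional exact p-value for group sums on equal libraries.

    Exact small-p enumeration for totals up to ``max_exact_total``; beyond
    that a continuity-corrected normal approximation to the conditional
    distribution is used.  A total of zero carries no information and
    returns p = 1.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("each group needs at least one library")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if sum_a < 0 or sum_b < 0:
        raise ValueError("group sums must be non-negative")
    s = int(sum_a) + int(sum_b)
    if s == 0:
        return 1.0
    if s > max_exact_total:
        return _normal_approx_pvalue(s, n_a, n_b, int(sum_a), dispersion)
    logpmf = _conditional_logpmf(s, n_a, n_b, dispersion)
    return _smallp_from_logpmf(logpmf, int(sum_a))


def adjust_pvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def one_vs_rest_tests(
    table: ZoneCountTable,
    norm: NormalizationResult,
    config: RunConfig,
) -> pd.DataFrame:
    """Exact tests of every zone against the pooled remaining zones.

    Returns one row per (transcript, zone): ``logFC`` (log2 of the zone's
    normalized CPM over the mean CPM of the other zones, both offset by
    ``config.prior_cpm``), raw ``p_value``, BH ``q_value`` adjusted within
    each zone's transcript family, ``score`` = -log10(p), and ``approx``
    marking totals handled by the normal approximation.
    """
    n_zones = table.n_zones
    if n_zones < 2:
        raise ValueError("one-vs-rest testing needs at least 2 zones")
    phi = config.effective_dispersion
    adjusted, _ = equalize_libraries(table.counts, norm.effective_library_sizes)
    cpm = norm.cpm
    prior = config.prior_cpm

    n_g = table.n_transcripts
    pvals = np.ones((n_g, n_zones))
    approx = np.zeros((n_g, n_zones), dtype=bool)
    totals = adjusted.sum(axis=1)
    for g in range(n_g):
        s = int(totals[g])
        if s == 0:
            continue
        if s <= MAX_EXACT_TOTAL:
            # the conditional distribution depends only on the total,
            # shared by all six one-vs-rest splits of this transcript
            logpmf = _conditional_logpmf(s, 1, n_zones - 1, phi)
            for z in range(n_zones):
                pvals[g, z] = _smallp_from_logpmf(logpmf, int(adjusted[g, z]))
        else:
            for z in range(n_zones):
                pvals[g, z] = _normal_approx_pvalue(
                    s, 1, n_zones - 1, int(adjusted[g, z]), phi
                )
                approx[g, z] = True

    rest_mean = (cpm.sum(axis=1, keepdims=True) - cpm) / (n_zones - 1)
    logfc = np.log2((cpm + prior) / (rest_mean + prior))
    qvals = np.column_stack(
        [adjust_pvalues(pvals[:, z]) for z in range(n_zones)]
    )

    records = pd.DataFrame(
        {
            "transcript_id": np.repeat(table.transcript_ids, n_zones),
            "zone": np.tile(table.zone_labels, n_g),
            "logFC": logfc.ravel(),
            "p_value": pvals.ravel(),
            "q_value": qvals.ravel(),
            "score": -np.log10(pvals.ravel()),
            "approx": approx.ravel(),
        }
    )
    return records
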