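"""Between-zone normalization: CPM, low-expression filtering, TMM factors.

Counts per million divide each count by its zone's (effective) library
size, times 1e6.  The trimmed mean of M-values (TMM) estimates a per-zone
scaling factor from variance-weighted, doubly trimmed log2 count ratios
against a reference zone, so that effective library size =
library size * normalization factor and
normalized CPM = 1e6 * counts / effective library size.

Filtering removes a transcript only when its CPM falls below the cutoff in
EVERY zone: requiring expression everywhere would discard exactly the
zone-restricted transcripts the analysis is after.  Filtering uses CPM at
raw library sizes (factors 1); TMM factors are then computed on the kept
transcripts.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _hc_average
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ks_2samp, rankdata

from .io import ZoneCountTable

__all__ = [
    "NormalizationResult",
    "compute_cpm",
    "filter_low_expression",
    "tmm_factors",
    "normalize",
    "quantile_normalize",
    "cutoff_diagnostic",
]


@dataclasses.dataclass
class NormalizationResult:
    """TMM factors, effective library sizes and the normalized CPM matrix.

    Factors have geometric mean 1; effective library size is
    ``library_size * factor``; ``cpm[g, z] = 1e6 * counts[g, z] /
    effective_library_sizes[z]``.
    """

    zone_labels: list[str]
    normalization_factors: np.ndarray
    effective_library_sizes: np.ndarray
    cpm: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.normalization_factors, dtype=float)
        if not np.all(np.isfinite(f)) or (f <= 0).any():
            raise ValueError("normalization factors must be finite and positive")
        log_gm = np.mean(np.log(f))
        if abs(log_gm) > 1e-9:
            raise ValueError(
                f"normalization factors must have geometric mean 1 "
                f"(log geometric mean {log_gm:.3g})"
            )

    def cpm_frame(self, transcript_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(self.cpm, index=transcript_ids, columns=self.zone_labels)


def compute_cpm(
    counts: np.ndarray | ZoneCountTable,
    effective_library_sizes: np.ndarray,
) -> np.ndarray:
    """Normalized CPM: ``1e6 * counts / effective library size``, column-wise."""
    if isinstance(counts, ZoneCountTable):
        counts = counts.counts
    sizes = np.asarray(effective_library_sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("effective library sizes must be positive")
    return 1e6 * np.asarray(counts, dtype=float) / sizes[np.newaxis, :]


def filter_low_expression(cpm: np.ndarray, cutoff: float) -> np.ndarray:
    """Boolean mask of transcripts kept by the low-expression filter.

    A transcript is removed iff its CPM is below ``cutoff`` in every zone,
    i.e. kept iff CPM >= cutoff in at least one zone.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return (np.asarray(cpm) >= cutoff).any(axis=1)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    zone_label: str = "?",
) -> float:
    """Unscaled TMM factor of one zone against the reference zone."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    positive = (obs > 0) & (ref > 0)
    if not positive.any():
        warnings.warn(
            f"zone {zone_label!r} shares no positive transcripts with the "
            "reference; using factor 1",
            stacklevel=3,
        )
        return 1.0
    o, r = obs[positive], ref[positive]
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * (np.log2(p_o) + np.log2(p_r))
    # delta-method approximate variance of M
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    table: ZoneCountTable,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Per-zone TMM normalization factors, geometric mean 1.

    Reference zone: the zone whose 75th-percentile count-per-library-size
    is closest to the across-zone mean of that quantile.  Against the
    reference, each zone's factor is 2 to the inverse-variance-weighted
    mean of log2 ratios M, after discarding the top and bottom ``trim_m``
    fraction by M and ``trim_a`` fraction by average log2 abundance A.
    """
    counts = table.counts
    if table.n_zones < 2:
        raise ValueError("TMM needs at least 2 zones")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("every zone must have at least one positive count")
    lib = table.library_sizes.astype(float)
    f75 = np.array(
        [np.percentile(counts[:, z], 75) / lib[z] for z in range(table.n_zones)]
    )
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            1.0
            if z == ref
            else _tmm_pair(
                counts[:, z],
                counts[:, ref],
                lib[z],
                lib[ref],
                trim_m,
                trim_a,
                table.zone_labels[z],
            )
            for z in range(table.n_zones)
        ]
    )
    # rescale so factors multiply to 1 across zones
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def normalize(
    table: ZoneCountTable,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> NormalizationResult:
    """TMM-normalize a (filtered) count table."""
    factors = tmm_factors(table, trim_m=trim_m, trim_a=trim_a)
    effective = table.library_sizes.astype(float) * factors
    return NormalizationResult(
        zone_labels=list(table.zone_labels),
        normalization_factors=factors,
        effective_library_sizes=effective,
        cpm=compute_cpm(table.counts, effective),
    )


def quantile_normalize(cpm: np.ndarray) -> np.ndarray:
    """Force every column to the same value distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; tied values within a column share the mean of the
    target values their positions span.
    """
    x = np.asarray(cpm, dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile_normalize requires no missing values")
    n, k = x.shape
    target = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(k):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = target
        # ties share the mean of the target values they span
        ranks = rankdata(col, method="dense")
        sums = np.bincount(ranks, weights=assigned)
        cnts = np.bincount(ranks)
        out[:, j] = sums[ranks] / cnts[ranks]
    return out


def cutoff_diagnostic(
    table: ZoneCountTable,
    candidate_cutoffs: list[float],
    log_prior: float = 0.25,
) -> dict:
    """Distribution-agreement report across candidate CPM cutoffs.

    For each cutoff (reported in ascending order) the low-expression filter
    is applied at raw library sizes and the maximum pairwise two-sample
    Kolmogorov-Smirnov statistic between zone log2-CPM distributions is
    computed, together with the per-zone quartiles behind box/density plots
    and the pairwise Euclidean distance matrix between zone log2-CPM
    columns used for hierarchical clustering and MDS.
    """
    if any(c < 0 for c in candidate_cutoffs):
        raise ValueError("cutoffs must be >= 0")
    cpm = compute_cpm(table.counts, table.library_sizes.astype(float))
    rows = []
    details = {}
    for cutoff in sorted(candidate_cutoffs):
        keep = filter_low_expression(cpm, cutoff)
        if not keep.any():
            raise ValueError(f"cutoff {cutoff} removes every transcript")
        kept = cpm[keep]
        logc = np.log2(kept + log_prior)
        n_zones = logc.shape[1]
        max_ks = 0.0
        for i in range(n_zones):
            for j in range(i + 1, n_zones):
                max_ks = max(max_ks, ks_2samp(logc[:, i], logc[:, j]).statistic)
        quartiles = pd.DataFrame(
            np.percentile(logc, [25, 50, 75], axis=0).T,
            index=table.zone_labels,
            columns=["q25", "q50", "q75"],
        )
        dist = squareform(pdist(logc.T))
        rows.append(
            {"cutoff": cutoff, "n_kept": int(keep.sum()), "max_ks": max_ks}
        )
        details[cutoff] = {
            "quartiles": quartiles,
            "distance_matrix": pd.DataFrame(
                dist, index=table.zone_labels, columns=table.zone_labels
            ),
            "linkage": _hc_average(pdist(logc.T)) if n_zones > 2 else None,
        }
    return {"report": pd.DataFrame(rows), "details": details}
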