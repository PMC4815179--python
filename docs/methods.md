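# Methods

## The screening problem

A bulk RNA-seq experiment measures one pooled library per ordered axial
zone (six zones, anterior to posterior, in the motivating design: a
planarian amputated into head-to-tail fragments, triplicate samples mixed
into one library per zone).  There are no biological replicates, so
per-transcript variance cannot be estimated from the data; everything
downstream treats the count matrix as one draw from an assumed noise
model and makes that assumption explicit.

## Filtering

CPM is computed with raw library sizes (all factors 1) and a transcript
is removed only when its CPM is below the cutoff (default 0.5) in **all**
zones.  The other reading — require ≥ cutoff everywhere — would discard
exactly the zone-restricted transcripts the screen is meant to find.  The
cutoff itself stays a manual choice; `cutoff_diagnostic` reports, for a
ladder of candidate cutoffs, the maximum pairwise two-sample
Kolmogorov–Smirnov statistic between zone log2-CPM distributions plus the
per-zone quartiles and zone–zone distance matrix behind the usual
box/density/clustering/MDS QC plots, so the "distributions look
identical after filtering" judgement can be made from numbers.

## TMM normalization

Factors follow the published trimmed-mean-of-M-values algorithm: the
reference zone is the one whose 75th-percentile count-per-library-size is
closest to the across-zone mean of that quantile; against the reference,
M = log2 ratio of library-scaled proportions and A = their mean log2 are
computed over transcripts positive in both zones; the top and bottom 30 %
by M and 5 % by A (average ranks, both trims applied jointly) are
discarded; the factor is 2 to the inverse-variance-weighted mean of the
surviving M values, with delta-method variances
(1−p₁)/(n₁p₁) + (1−p₂)/(n₂p₂); finally all factors are rescaled to
geometric mean 1.  Factors are computed on the **filtered** matrix
(filter first, then normalize).  A zone sharing no positive transcript
with the reference gets factor 1 with a warning; an all-zero zone is
rejected at validation.  The implementation is pinned by an
independently coded explicit-loop evaluation of the same steps
(tests/_oracles.py) to 1e-9 on random matrices, and agreed with a
widely used reference implementation to 12 digits during development.

## The exact test

Each zone is tested one-vs-rest.  Counts are first scaled to a common
library size — the geometric mean of the effective sizes — and rounded
half-to-even, because the conditional test requires equal libraries.
Under the null of equal relative abundance, the focal-zone count A and
the pooled-rest count B are negative binomial with means m and (Z−1)m and
dispersions φ and φ/(Z−1); conditional on s = A + B, A follows a
two-category Dirichlet-multinomial with parameters (1/φ, (Z−1)/φ).  The
two-sided p-value is the small-p sum: the total conditional probability
of all outcomes a with P(a|s) ≤ P(a_obs|s)·(1+1e-7) (the relative tie
tolerance conventional in R's exact tests).  For φ ≤ 1e-8 the
conditional distribution is computed directly as Binomial(s, 1/Z): the
Dirichlet-multinomial limit deviates from the binomial by O(s²φ) in the
pmf, so evaluating the limit form at tiny φ would needlessly lose
precision.  s = 0 carries no information and returns p = 1.

For s > 10,000, enumeration gives way to a continuity-corrected normal
approximation to the conditional distribution (matching mean and
variance), and the record is flagged `approx`.  In the decision region
(p between 1e-3 and 0.2) the approximation is within ~0.02 of the exact
value for the splits used here; far-tail p-values are order-of-magnitude
accurate only, which does not affect significance calls at conventional
α.

The dispersion default is φ = 0.1 (`dispersion_mode="poisson"` forces
φ = 0), a typical magnitude for pooled invertebrate bulk libraries; since
the design cannot estimate it, results should be read as conditional on
this choice, and the null-calibration test exercises the pipeline at the
simulator's φ so that assumed and generated noise match.  One empirical
note: the p-value is *usually* but not always monotone increasing in φ —
at large φ (≈1) the reshaping of the small-p acceptance region can
decrease p for moderate outcomes.  The suite monitors this and warns
rather than asserts.

logFC is log2((CPM_z + c)/(mean of other zones' CPM + c)) with
pseudo-CPM c = 0.5, keeping fold changes finite at zero counts.  BH
adjustment is applied within each zone's transcript family (the
field-standard correction; the underlying study does not name one).

## Membership codes

A transcript is specific to every zone with q ≤ α (default 0.05) and
logFC > 0.  The code lists those zones joined by ".", ordered by
normalized CPM descending — "2.1" is specific to zones 1 and 2 with
higher expression in zone 2 — with ties broken by smaller p-value, then
anterior first (the tie-break is a documented convention, not inferred
from data).  "none" encodes no restriction.  `summarize_categories`
counts transcripts per code; `order_for_heatmap` groups transcripts by
primary zone (anterior→posterior, "none" last), sorts within group by
primary-zone CPM, and row-scales CPM to [0, 1] for plotting.

## Synthetic data

The generator emulates the measured structure of a six-zone experiment:

| parameter | default | meaning |
|---|---|---|
| `n_zones` | 6 | ordered axial zones, one library each |
| `library_size_mean`, `library_size_jitter` | 2e6, 0.2 | per-zone depth, drawn uniformly in mean·(1±jitter) |
| `baseline_log_mean`, `baseline_log_sd` | 0, 1 | log-normal baseline relative abundance |
| `fold_change` | 8 | single-zone enrichment over background |
| `dual_ratio` | 2 | stronger/weaker ratio of the adjacent pair |
| `gradient_step` | 2 | per-zone multiplicative step of the ramps |
| `dispersion` | 0.05 | NB over-dispersion φ (0 = Poisson) |
| `below_filter_cpm` | 0.1 | planted CPM of sub-filter transcripts, all zones |

Counts are NB with mean μ = p·L (p the planted abundance column-normalized
over transcripts, L the zone's library size) and variance μ + φμ² — the
same parameterization the test assumes.  The archetype mixture defaults
to 60 % flat, 12 % single-zone, 8 % adjacent-dual, 4 % each gradient, and
12 % below-filter, which puts the restricted fraction of kept transcripts
near the ~20 % seen in real axial screens.  The moderate `baseline_log_sd`
of 1 represents the expressed transcriptome; the very-low-expression tail
is modelled explicitly by the below-filter archetype rather than by a
heavier log-normal tail.  The expected code of a planted profile is
defined by the same rule the screen targets: zones whose planted
abundance exceeds the mean of the other zones', ordered by abundance.

What the generator does **not** emulate: transcript-length effects,
positional/fragment bias, batch effects, replicate structure, and
correlated transcript programs.  Passing recovery tests therefore shows
the statistical machinery is correct under its own assumptions, not that
any particular real dataset satisfies them.

## Numerical and design choices

- Library sizes default to column sums of the matrix but can be
  overridden (real library sizes come from full alignments, not the
  filtered matrix).
- The common library size for equalization is `prod(sizes)**(1/n)`,
  which keeps exact-ratio cases exact; rounding is half-to-even.
- Quantile normalization (diagnostic only, never used for testing)
  replaces each column's sorted values with the across-column mean of
  sorted values; ties share the mean of the target values they span.
- Factors are validated to geometric mean 1 within 1e-9; CPM is exactly
  reproducible as 1e6·counts/effective size.
- The pipeline is a pure function of (counts file, config, seed): all
  artifacts are written with fixed float formatting and re-running with
  the same inputs reproduces them byte-for-byte.

## Problem sizes

The simulation-based checks run at 2,000–5,500 transcripts × 6 zones
with library sizes near 2e6 — large enough that per-transcript totals
reach the thousands and the exact enumeration path dominates, while a
full suite plus the acceptance script completes in a few minutes on one
CPU.

## Known limitations

- With no replicates, φ is an assumption; calls are conditional on it.
- Doubling one zone's counts in an arbitrary mixture table perturbs the
  equalized pseudo-counts by a factor 2^(1/Z) and can flip a handful of
  borderline codes (≈0.3 % in a 2,000-transcript mixture) through the
  rounding and BH boundaries; CPM-level scale invariance is exact only
  when zone compositions are genuinely identical.
- The per-zone BH families control FDR per zone, not jointly across the
  Z×transcripts matrix of tests.
- The normal-approximation tail (s > 10,000) is flagged but its far-tail
  p-values are approximate; ranking by score across that boundary mixes
  exact and approximate values.
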