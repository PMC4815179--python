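# axiszone

Zone-specificity scoring for anterior–posterior axial RNA-seq.

When an animal is cut into ordered tissue fragments along its
anterior–posterior (A–P) axis and each fragment is sequenced in bulk — the
classic design for mapping axially restricted transcripts such as HOX
genes in the planarian *Schmidtea mediterranea* — the analysis question
is: *which transcripts are enriched in which zone(s)?*  `axiszone` turns a
transcripts × zones raw count matrix into composite **zone-membership
codes**, with every intermediate step exposed and tested:

1. **CPM filter** — a transcript is removed only if its counts per million
   (CPM) fall below a cutoff (default 0.5) in *every* zone.
2. **TMM normalization** — trimmed-mean-of-M-values scaling factors
   (reference by 75th-percentile, double trimming of M and A,
   inverse-variance weights), giving
   `effective library size = library size × factor` and
   `normalized CPM = 1e6 × counts / effective library size`.
3. **One-vs-rest exact tests** — each zone *z* is compared against the
   pooled remaining zones with a negative-binomial conditional exact test
   on library-equalized counts.  Under the null the focal-zone sum,
   conditioned on the transcript's total *s*, follows a two-category
   Dirichlet-multinomial (a conditional Binomial(*s*, 1/Z) when the
   dispersion φ = 0); the two-sided p-value sums all outcomes no more
   probable than the observed one.  Per-zone log2 fold changes use
   normalized CPM with a pseudo-CPM prior, and p-values are BH-adjusted
   within each zone's family.
4. **Membership codes** — zones with q ≤ α and logFC > 0, joined by "."
   in order of expression, highest first: `"2.1"` means *specific to zones
   1 and 2, more strongly expressed in zone 2*; `"1.2"` the same zones
   with higher expression in zone 1; `"none"` means no axial restriction.

A synthetic generator (`axiszone.simulate`) plants flat, single-zone,
adjacent-dual, gradient and below-filter archetypes with negative-binomial
noise, so the whole pipeline is testable without sequencing data, and a
recovery scorer reports per-archetype sensitivity against the planted
truth.

## Worked example

```python
import axiszone as az

sim = az.SimulationConfig(n_transcripts=2000, seed=1, dispersion=0.05)
table, truth = az.simulate_zone_counts(sim)

model = az.ZoneSpecificityModel(table, az.RunConfig(dispersion=0.05))
results = model.fit()
print(results.summary())
```

prints

```
Zone-specificity screen
======================================================
zones (anterior -> posterior): 1, 2, 3, 4, 5, 6
transcripts detected:  2000
kept after CPM filter: 1842 (cutoff 0.5)
axially restricted:    613 (q <= 0.05, logFC > 0)
distinct categories:   16 (10 multi-zone)

TMM normalization factors:
  zone 1: factor 0.8043  effective size 1,471,764
  zone 2: factor 1.0594  effective size 1,786,913
  ...

top categories (code: transcripts):
  none: 1229
  6: 104
  1: 100
  ...
```

2000 transcripts were simulated, 1842 survive the 0.5-CPM filter, and 613
of those are called specific to at least one zone at FDR 0.05, falling
into 16 distinct codes.  The TMM factors compensate the composition bias
introduced by the planted gradients at the two ends of the axis.  Against
the planted truth:

```python
print(results.recovery(truth))
```

```
         archetype    n  sensitivity  false_restriction
              flat 1200       0.9575             0.0425
       single_zone  240       1.0000                NaN
     dual_adjacent  160       0.6688                NaN
...
```

Every planted single-zone transcript (8-fold enrichment) is recovered
with its exact code, and 4.25 % of truly flat transcripts pick up a
spurious code — close to the 5 % FDR target.  `results.plot_qc()` and
`results.plot_heatmap()` draw the box/density/MDS panels and the
row-scaled CPM heatmap; `az.run_pipeline(...)` (or `axiszone run` on the
command line) writes all artifacts — results, factors, categories, QC
report and a JSON manifest — deterministically for a given seed.

The same pipeline runs from the shell:

```sh
axiszone simulate --out counts.tsv --truth truth.tsv --seed 1
axiszone run --counts counts.tsv --out-dir out/
```

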