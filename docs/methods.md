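# Methods

This note documents the models, parameter choices, numerical
conventions and known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Outlier model

Expression outliers are defined per gene, across the cohort, on
log2-transformed FPKM. The transform uses a pseudocount of 1
(`log2(FPKM+1)`), matching the +1 convention of the fold-change
formula; zeros otherwise have no logarithm. An alternative
(`transform="log2_dropzero"`) drops zero-FPKM samples before the
quartiles instead, for users who prefer not to compress the low end.

Quartiles are computed by linear interpolation between order
statistics (numpy's default, the "type 7" convention). The fence
multiplier k defaults to 1.5. All threshold comparisons in the funnel
are strict (`>`, `<`): a sample exactly at a fence, a log2 fold change
of exactly 3, or an FPKM of exactly 10/1 does **not** qualify.

The furthest-selection distances are measured in the same
log2(FPKM+1) space as the fences. A positive outlier is kept when its
distance to the maximum expression value is ≤ its distance to the
highest non-outlier value (mirrored for negative outliers); ties are
inclusive and the extremum always survives, so selection is
deterministic. When every sample on one side is an outlier (no
non-outlier reference exists) all are kept.

The per-gene median used in the fold change includes all samples,
including the outlier itself; excluding it would make the statistic
sample-dependent in a way nothing in the design requires. Cohorts
with fewer than 4 samples are rejected — quartile fences on 3 points
are not meaningful for this purpose. Genetically related samples are
not collapsed before quartile estimation; related models carrying the
same event simply appear as multiple outliers.

Default thresholds: differential 3 (both directions), absolute 10
FPKM (positive) and 1 FPKM (negative). Burdens are per sample:
1000 × (extreme calls) / (genes with FPKM > 10, resp. < 1 in that
sample); a zero denominator yields a missing burden rather than an
infinity.

### Threshold recalibration

Tissue cohorts show damped outlier deviations (bulk signal averages
over cell types), so the differential thresholds can be re-tuned:
`calibrate_thresholds` grid-searches (default grid 0.5–4.0, step
0.25) the differential threshold of each direction so that the
achieved fraction — genes retaining an extreme call over genes with a
Tukey call — best matches a reference fraction, holding the absolute
thresholds fixed. The fraction is a step function of the threshold,
so grid + argmin is robust where a root-finder would not be; ties
break toward the smaller threshold, deterministically.

## Cohort-level gene filters

Before calling, the expression matrix drops (a) chrM genes and chrY
pseudoautosomal-region genes (identified by an annotation flag, not by
coordinates), (b) genes with FPKM < 1 in every sample, (c)
non-protein-coding biotypes; outlier calling additionally excludes
chrX/chrY genes, whose dosage varies with sex rather than disease.
Gene identifiers are matched on versionless Ensembl ids. Missing FPKM
cells are an error: the upstream quantification produces dense
matrices, and silently imputing would corrupt quartiles.

## Reference-free copy number

Gene CN values (gene median depth over sample median depth) remove
per-sample library size. Samples are clustered with PCA (centering
only, no per-gene scaling) and k-means (default k = 3, first 10
components, 25 restarts, fixed seed) to group samples sequenced with
the same capture chemistry; cluster count selection is deliberately
left to the user. The metanormal of a cluster is the per-gene median
CN of its samples. Genes with metanormal CN < 0.1 in *at least one*
cluster are excluded everywhere — such genes are absent from that
kit's probe set, and a ratio against a near-zero reference is
meaningless. Calls use strict thresholds on log2(CN/metanormal): > 2
amplified, < −2 deleted. A matched-normal mode (log2 tumor/normal CN)
serves as validation; agreement is summarised as the per-sample
Pearson correlation between the two log2 CNV profiles over retained
genes, pairwise-complete.

## Promoter methylation association

Promoters are upstream-only windows of 1500 bp per transcript TSS,
strand-aware, TSS position excluded; a gene's promoter is the union
over its TSSs and a CpG may belong to several genes. Interval logic
is 0-based half-open; 1-based TSSs are converted on load.

Genes require ≥ 2 extreme outliers of a direction to be tested. "Other
samples" are all β-matrix samples that are not extreme outliers for
that gene/direction (Tukey-only outliers therefore count as others).
Missing β-values are dropped per CpG; CpGs with < 3 values in either
group are skipped. The Wilcoxon rank-sum test is two-sided, exact
when both groups have ≤ 10 values and no ties, otherwise the normal
approximation with tie correction; a fully tied comparison returns
p = 1. BH correction runs globally across all tested (gene, CpG)
pairs within a direction — a per-gene scope is arguably defensible but
the global scope is the stricter and simpler default.

Significance additionally requires the β-median rule. Its default
direction pairs *under*expression with promoter hypermethylation
(outlier median β > 0.80, others < 0.20) and *over*expression with
hypomethylation (mirrored) — the biologically coherent assignment;
`beta_rule_direction="methods"` swaps the two for users wanting the
alternative written convention. The rule is what guarantees a zero
false-positive rate on null data: at the test counts involved, FDR
< 0.05 alone admits occasional flukes, but a group of four samples
drawn from an unmethylated Beta distribution essentially never
reaches a median of 0.80.

CpG context classes are decided by distance to the nearest (merged)
CpG island: 0 → island, ≤ 2 kb → shore, ≤ 4 kb → shelf, else open
sea. This resolves colliding flanks of nearby islands
island-proximally by construction and partitions every base exactly
once. CIMP enrichment is an upper-tail hypergeometric test
(population = CIMP-labeled samples, successes = CIMP-H ∪ CIMP-L,
draws = the gene's extreme negative outliers), BH across tested genes,
restricted to genes with significant promoter hypermethylation.

## Fusion filtering

Caller-A calls need FFPM > 0.1 (strict) and a clean annotation flag,
plus a caller-B call with the same *ordered* (5′, 3′) symbol pair in
the same sample — matching is at gene level because the two callers
report breakpoints on different conventions. Fusions whose 3′ partner
is amplified in the carrier sample are removed (by-products of
chromosomal instability); fusions in samples or genes lacking CNV data
are kept and flagged, the conservative choice. A fusion is "matched"
when its carrier is an extreme positive outlier for the 3′ gene.

## Synthetic cohorts

The generators produce every input format with serialisable planted
truth; they are pure functions of parameters and seed.

* **Expression** — per-gene baseline log2(FPKM+1) uniform in [2, 8],
  Gaussian sample noise σ = 0.3 in log2 space (normal-in-log noise is
  simple and controls the tail mass near the Tukey fences; no
  empirical noise model is attempted). Overexpression plants add +6
  in log2 (double the differential threshold, so recovery tests are
  not fence-edge flaky); underexpression plants zero out samples of
  genes with baseline median FPKM ≳ 9, making |log2fc| > 3 attainable.
  Default study conditions: 2000 genes × 200 samples, 100 + 100
  planted genes.
* **Calibration cohort** — as above but with effect sizes spread
  continuously (positive log2fc uniform in [1, 5]; negative plants
  leave residual expression), so the extreme/Tukey fraction moves at
  every grid candidate and threshold recovery is well-posed.
* **WES depth** — per-cluster probe-affinity profiles (shared
  log-normal base × cluster-specific log2-Gaussian factor, σ = 0.5)
  times per-sample scale; plants multiply one (gene, sample) depth by
  8 or 1/8; noise is multiplicative, 2^N(0, σ) with σ = 0.05 for the
  noisy condition. Plants go on moderate-affinity genes (between 0.5×
  and 1.5× the cluster median): above/below-median placement with an
  odd gene count leaves the per-sample median depth provably
  unchanged, so noiseless planted log2 CNV is exactly ±3, and the
  spike stays small against the cluster separation so clustering is
  not driven by the plants. Events are dealt round-robin over
  samples — every model carries some CNVs, as real tumor lines do.
  The matched-normal matrix shares affinities and scale, has no
  plants, and carries its own noise draws.
* **Methylation** — β from Beta distributions with mean 0.1 / 0.9 and
  concentration 150 (SD ≈ 0.024, typical of array β-values in fully
  (un)methylated states); planted genes switch their outlier samples'
  promoter CpGs to the opposite state; 5 CpGs per promoter, each
  promoter covered by a generated CpG-island interval.
* **Fusions** — survivors appear in both callers, clean, FFPM > 0.1,
  with the 3′ partner a planted overexpression event; each decoy
  violates exactly one filter (low FFPM, single caller, red-herring
  flag, amplified 3′ partner).

What the generators do **not** emulate: the empirical FPKM
distribution of any real cohort, expression–CN coupling, batch
effects, probe cross-reactivity, or subclonality. Passing recovery
tests therefore demonstrates correctness of the decision rules at the
stated effect sizes, not calibration on real data.

## Problem sizes and numerical notes

Acceptance checks run at 2000 × 200 (expression), 1001 × 30 (depth,
3 clusters, 60 events), 100 CpGs × 100 samples with 50 null
repetitions (methylation), and 500-instance oracle sweeps for the
statistical primitives — sizes at which every property the package
guarantees is measurable while the whole suite stays fast. Quantile
and fence computations are vectorised across genes; the funnel for a
2000 × 200 cohort completes in well under a second. Degenerate inputs
are defined, not special-cased ad hoc: constant genes produce zero
calls (IQR = 0 fences equal the constant, strict comparison), empty
directions propagate as empty tables, and zero denominators yield
missing values.

## Known limitations

* No confounder control (the OUTRIDER family of autoencoder methods
  addresses covariate structure this pipeline ignores by design).
* CNV is gene-level only: no segmentation, allele-specific CN, or
  purity/ploidy correction; cluster count k is user-set.
* Methylation preprocessing (normalisation, probe masking) is out of
  scope — the β-matrix is trusted as given.
* Fusion matching ignores symbol aliasing between callers; inputs are
  expected to share a symbol namespace.
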