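# Methods

## Coordinate and counting conventions

All genomic arithmetic uses BED semantics: 0-based, half-open
`[start, end)`. Interval sets are kept canonical (sorted, disjoint,
non-abutting), so the unique-base count of a region is exactly the sum
of interval lengths. Abutting intervals merge: two intervals covering
a contiguous base run denote the same base set, which is the quantity
every downstream statistic counts. Chromosome names are opaque strings
compared verbatim; `read_bed` offers `strip_chr`/`add_chr`
normalization for mixed inputs, off by default. Strand is ignored:
coverage is strandless.

Pileup-style depth tables are 1-based on disk; the −1 shift happens in
`read_depth_table` and nowhere else. Target bases absent from a
sample's depth file are depth 0 — uncaptured, not missing — so every
fraction's denominator is the full target size. This zero-fill rule is
what lets "proportion of the target not captured" be computed from
depth exports alone.

## Representation of one annotation inside another

Each database maps gene symbols to the union of their transcripts'
coding exons, collapsed to unique bases. The subset database is first
clipped into the superset per gene (`enforce_nesting`); genes absent
from the superset are dropped with a warning. Per-gene representation
is `|subset ∩ superset| / |superset|`. The pooled "ALL" row uses the
union over genes before counting, so exons shared between gene symbols
count once; it is a ratio of unique base totals, not a mean of
per-gene percentages (the two differ whenever gene sizes differ).
Gene symbols match exactly and case-sensitively; no alias resolution.

## Coverage statistics

A kit's track is the arithmetic mean of its samples' per-base depths.
A base is *captured at depth d* when this cross-sample mean is ≥ d;
"below" the optimal depth is strict `<`. The cumulative coverage
curve evaluates this at every integer threshold 1..max_depth (default
200). Defaults of 3X (minimum to observe a heterozygous variant) and
30X (confident genotype call) are configurable and centralized in the
audit config so all modules share one threshold semantics.

Per-gene summaries take the median and quartiles of per-base mean
depth over the gene's regions, zero-filled. Quantiles interpolate
linearly between order statistics (the common default of mainstream
statistical environments — numpy's `linear`, R type 7); the
`quantile_method` argument passes any other numpy convention through.
"IQR above the optimal depth" is read as *the interquartile box lies
at or above it* (q1 ≥ 30), i.e. at least 75% of the gene's bases reach
the optimal depth; the alternative span reading (q3 − q1 ≥ 30) is
available via `iqr_rule="span"`. The box reading is the default
because a span reading would label a gene "well covered" merely for
being *heterogeneous*, which is backwards for a uniformity flag.

Inter-sample variability is the per-base 95% CI half-width
`1.96·SD/√n` with the n−1 sample SD — a plain normal approximation,
adequate at the tens-to-hundreds of exomes a capture arm contains; no
bootstrap. The audit computes it over *captured* subset bases (mean
depth > 0): including never-captured bases would add zero-variance
rows and flatter the profile. The observed mean depth of a kit is
likewise reported over its captured bases.

## GC content and regressions

GC is counted case-insensitively over a gene's subset regions from the
genome FASTA, ambiguity codes excluded from numerator and denominator;
an all-ambiguous gene has undefined GC and is excluded from regression
with a warning, as are genes with no base in the depth-track universe.

`fit_ols` is the closed-form simple regression: slope `Sxy/Sxx`,
`r² = 1 − SSres/SStot`, two-sided p from `t = slope/SE` on n−2 df
(identical to the one-predictor F-test). It is written out explicitly
rather than delegated so that degenerate cases have defined behaviour:
a perfect line returns r² = 1.0 exactly with p = 0; a constant
response returns r² = 0, p = 1; a constant predictor raises.
Predictors enter untransformed (GC as a fraction, size in bases).
The best/worst-covered comparison ranks genes by median coverage and
applies Welch's t-test to the two GC samples; Welch is the default
because nothing guarantees equal GC variance in the two tails, and
the pooled-variance t remains available via `equal_var=True`. If both tails have zero variance
the test degenerates and is reported as p = 1 (equal means) or p → 0
with a warning.

The audit runs the regressions on the kit with the highest observed
mean depth, where uniformity differences are least confounded by
shallow sequencing.

## The synthetic study generator

`synthetic_data.generate` emulates the study design end-to-end:

* **Genome** — `n_chroms` random sequences (default 2 × 60 kb,
  background GC 0.40); within each gene's exons, bases are drawn
  i.i.d. with P(G or C) equal to that gene's target GC level, so
  realized GC concentrates binomially around the target.
* **Annotations** — 50 genes by default, 4 exons of 120–180 bp each
  (~600 bp per gene: a deliberately desk-scale stand-in for real
  clinical genes of a few kb; every statistic scales with base counts,
  not absolute sizes). The superset is the exon set; the subset keeps
  `round(f_g · size)` bases per gene (default f_g ~ U[0.10, 0.97],
  matching the spread seen between consensus and broad annotations),
  selected exon-wise — whole exons in random order, then one partial
  exon — so dropout is exon-shaped, as when a consensus database
  omits alternative exons. Nesting is exact by construction, and the
  realized f_g are recorded as truth.
* **Kits and depths** — default four kits with footprints
  0.92/0.97/0.98/0.99 of the subset, mean depths 30.5/80/48/63X and
  20/94/93/6 samples, mirroring successive capture-kit generations.
  A kit's captured footprint trims `1 − footprint` of the subset
  bases off interval ends in random order (again exon-shaped gaps).
  Per captured base in gene g, sample s draws
  `NB(mean = exp(α_K + β·GC_g + ε_s), dispersion φ)` with
  `ε_s ~ N(0, σ²)`; `α_K` anchors the kit's mean depth at the panel's
  mean GC. Defaults β = −2 (≈1.8× depth ratio across GC 0.35–0.65),
  φ = 30 and σ = 0.05, giving a cross-sample coefficient of variation
  around 0.2 at 80X — a realistic magnitude for capture data. φ = None
  selects the Poisson limit. Sample effects act multiplicatively, so
  inter-sample CI half-widths grow with depth. Uncaptured bases are
  simply absent from the emitted files.

All randomness flows from one seed through `SeedSequence` spawning
(layout, sequence, subset selection, one stream per kit), so any stage
is reproducible independently and same-seed runs are byte-identical.

What the generator does **not** emulate: read-level artifacts
(mappability, duplicates, strand bias), copy-number variation,
per-exon GC structure within a gene (GC and hence expected depth are
gene-constant), or residual gene-to-gene depth heterogeneity beyond
GC. Consequently the synthetic GC–coverage r² is higher than real
capture data would show, and gene size is independent of depth by
construction (its regression r² ≈ 0). Passing tests therefore
demonstrate correctness of the audit's computations and qualitative
reproduction of capture behaviour, not quantitative realism of any
particular cohort.

## Numerical and degenerate-input choices

* Coverage-curve evaluation sorts the per-base means once and reads
  all thresholds by binary search; results are bit-for-bit
  deterministic given the input files because base order is total.
* Empty targets, empty supersets, single-sample variability, < 3
  observations or a constant predictor in OLS, and fewer than 2k genes
  in the extremes test all raise typed errors rather than returning
  NaN.
* TSV outputs serialize floats at 6 significant digits; every table
  has a full-precision JSON mirror. Re-running any stage on identical
  inputs is byte-identical.
* The audit CLI exits 0 on success, 2 on configuration/validation
  errors, 1 on runtime failures, and logs version, config digest and
  seed.

## Problem sizes

The shipped defaults — 50 genes × ~600 bp, 213 samples across four
kits (~30 kb superset, ~15 kb subset, ≈3M depth records) — run the
full simulate-plus-audit cycle in well under a minute on one CPU.
Test fixtures use a 12-gene, 2-kit reduction of the same design;
replicate-based checks (GC-slope sign recovery and type-I
calibration, 100 replicates each) use 50 single-kit genes with 2
exons and 4 samples per replicate.

## Known limitations

* Depth files are trusted as ground truth; upstream pileup filters
  (mapping/base quality) change results and are out of scope.
* BAM ingestion is not built in; any pileup-like exporter producing
  the 3-column text is compatible.
* The annotation layer is gene-level; transcript-level reporting and
  GFF/GTF parsing are out of scope (convert to BED upstream).
* Interval algebra is plain set algebra over canonical sets — no
  interval trees; adequate for panel-scale inputs.
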