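# panelcov

Coverage audit of clinically relevant gene panels on whole-exome
capture data.

Whole-exome sequencing is only as clinically useful as its coverage of
the genes that matter. Capture kits are designed against a
conservative consensus coding annotation (CCDS-style), which holds
only part of each gene's known footprint in broader annotation sets
(Known Gene-style); on top of that, capture efficiency and read depth
vary base-to-base and gene-to-gene, driven in large part by GC
content. `panelcov` quantifies all of this for a gene panel:

1. **Representation** — per gene and pooled, the fraction of the
   broad ("superset") annotation's unique bases retained by the
   conservative ("subset") annotation the kit was designed from:
   `fraction = |subset ∩ superset| / |superset|` on unique genomic
   bases (0-based half-open interval algebra, abutting intervals
   merged).
2. **Capture and depth** — per-base depths from each sample's pileup
   export are averaged across the samples of a capture kit; cumulative
   coverage curves report the fraction of target bases with mean depth
   ≥ d for each d, read at the minimum depth to see a heterozygous
   variant (3X) and the optimal depth for a confident genotype call
   (30X). Target bases absent from a sample's file count as depth 0.
3. **Uniformity** — per-gene median and quartiles of per-base mean
   depth, with flags for median < 30X and for the interquartile box
   lying at or above 30X; inter-sample variability as the per-base 95%
   CI half-width `1.96·SD/√n`.
4. **Drivers** — ordinary least squares of per-gene median coverage on
   GC fraction and on gene size (r², two-sided slope t-test on n−2
   df), plus Welch's t-test comparing GC of the 5 best- vs 5
   worst-covered genes.

A fully parameterised synthetic-study generator (nested annotation
databases, capture-kit footprints, negative-binomial depths with a
log-linear GC penalty) makes the whole pipeline testable end-to-end
with recorded ground truth.

## Worked example

Simulate the default study (four kits with footprints 0.92 / 0.97 /
0.98 / 0.99 of the subset annotation, sequenced at mean depths
30.5X / 80X / 48X / 63X in 20 / 94 / 93 / 6 samples; 50 genes with
GC 0.35–0.65 and a negative GC effect on depth), then audit it:

```bash
panelcov simulate --out study --seed 1
cat > audit.yaml <<EOF
paths:
  superset_bed: study/superset.bed
  subset_bed: study/subset.bed
  fasta: study/genome.fa
  manifest: study/manifest.tsv
out_dir: audit_out
EOF
panelcov report --config audit.yaml
cat audit_out/report.txt
```

which prints:

```
panelcov 1.0.0 coverage audit (config 98151e1fdd6a)

Representation: 14768 of 30014 superset bases in subset (49.2%)

kitV2: n=20, observed depth 30.8X; capture at 3X subset 92.0% / superset 45.3%; 26 genes median < 30X, 21 genes IQR flag
kitV3: n=94, observed depth 79.9X; capture at 3X subset 97.0% / superset 47.7%; 1 genes median < 30X, 47 genes IQR flag
kitV4: n=93, observed depth 48.2X; capture at 3X subset 98.0% / superset 48.2%; 0 genes median < 30X, 49 genes IQR flag
kitV5: n=6, observed depth 62.5X; capture at 3X subset 99.0% / superset 48.7%; 0 genes median < 30X, 49 genes IQR flag

GC regression (kitV3, n=50): slope -163.8, r2 0.673, p 3.06e-13
Size regression: r2 0.000, p 0.974
Top-5 vs bottom GC: 38.6% vs 63.3% (p 4.4e-07)
```

Reading it: the conservative annotation holds only 49% of the genes'
known bases, so even a kit capturing 99% of its own design space
(kitV5) reaches under half of the broader annotation. The shallow
30.5X kit leaves 26 of 50 genes below the optimal 30X median; those
genes are the high-GC ones, and the GC regression makes the driver
explicit (negative slope, r² 0.67). Each reported table also exists
as TSV + JSON in `audit_out/`; `panelcov represent`, `coverage` and
`gc` run the stages individually.

As a library, the same audit is a few calls —
`synthetic_data.generate`, `build_db`/`representation_table`,
`build_matrix`/`mean_track`, `coverage_curve`, `gene_summaries`,
`fit_ols` — see the docstrings and `docs/methods.md`.

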