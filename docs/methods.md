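# Methods

## The measurement model

A DNase-seq hotspot is summarized by its **MaxD**, the maximal per-bp cut
count inside the site. Because libraries differ in depth, MaxD is expressed
per 10 million reads: `norm_maxd = raw_maxd × 10⁷ / total_reads`. All
downstream contrasts (Venn partitioning, differential testing, enhancer
intensity) operate on hotspot *calls* plus these counts; peak calling
itself is upstream of this package and its inputs.

**Replicate concordance (RC).** A site is kept when its interval overlaps
(≥ 1 bp, half-open semantics) a site in the other biological replicate.
Overlapping intervals are merged into their union via connected components,
so chained one-to-many overlaps collapse into a single site. The merged
site's normalized MaxD is the mean of the two per-replicate values; the raw
count pair and depth pair are carried so exact count tests remain possible.
The merge rule (union + mean) is a design choice — any consistent rule
would do; union is conservative about site extent and the mean matches how
a replicate-averaged amplitude is usually reported.

**Differential test.** For one site with peak-bp counts cₐ, c_b from
libraries of dₐ, d_b total reads, equal per-bp accessibility implies that,
conditional on n = cₐ + c_b, cₐ ~ Binomial(n, dₐ/(dₐ+d_b)). The two-sided
exact p-value of that binomial is the site's significance; n = 0 gives
p = 1. The exact conditional form stays valid at the single-digit counts a
per-bp statistic produces, at the price of conservatism (empirical size at
α = 0.05 is ≈ 0.036 in the acceptance run). No multiple-testing correction
is applied on the default path; `bh_adjust` exposes Benjamini–Hochberg for
users who want FDR control across sites. Sites with no overlap on the other
side are "unique"; overlapping sites are "common", split into modified /
unchanged at α.

**Venn partitions.** Each input site is assigned exactly one region by
which other sets it overlaps; per-set region counts therefore always sum to
set sizes, and a common region counts each member set's sites separately
(a merged differential record additionally represents each overlapping
group once). Both the 2-way and 3-way partitions are validated against a
brute-force all-pairs oracle in the test suite.

**Annotation.** One category per site with priority
promoter > exon > intron, where the promoter window is TSS ± 2.5 kb
(half-open, TSS = tx_start on +, tx_end − 1 on −). Intergenic sites are
assigned to the nearest gene by midpoint-to-TSS distance (ties to the
lexicographically smaller gene id) and called distal_upstream when 5′ of
that TSS in the gene's orientation, downstream otherwise; no distance cap
is applied. A site touching features of several genes takes the
highest-priority feature across all genes, then the nearest TSS. TSS
aggregation profiles are strand-oriented (minus-strand windows flipped),
binned, depth-normalized to 10 million reads and averaged over TSSs.

**TOD-DHS.** qPCR signal doubles once per cycle at efficiency E ∈ (1, 2],
so the undigested template fraction at a benchmark site is
E^(Cq₀ − Cq) and `fraction_digested = 1 − E^(Cq₀ − Cq)`, clamped to [0, 1];
a missing Cq (no amplification) maps to 1.0 with a flag. Replicate Cq are
averaged before the transform; the per-point sd is the spread of
per-replicate transformed fractions. A DNase concentration qualifies when
the mean sensitive-site fraction lies in the selection window (default
[0.70, 0.80] — the optimum quoted for this assay) and resistant sites stay
at ≤ 0.10 digested; among qualifying concentrations the smallest wins, to
minimize over-digestion artifacts. Efficiency defaults to 2.0 (ideal
doubling) and is configurable per assay since real efficiencies are rarely
reported.

**Enhancer→gene linkage.** Gained sites (default: unique to the second
condition) are annotated; promoter-category sites are removed; what remains
is operationally an enhancer. Each enhancer links every gene whose TSS is
within 50 kb of the nearest site border, inclusive at exactly 50 kb, with
distance 0 when the TSS falls inside the site. Genes hit by several
enhancers collapse to the signed intensity of the largest-|intensity| link
(a sum option exists); intensity is the signed difference of normalized
MaxD from the comparison. Enrichment of the linked genes is a one-sided
hypergeometric tail per gene set, sets intersected with the background
(default: all annotated genes) before testing, BH-adjusted across sets.
The knowledge-base step of the original analysis ran through a proprietary
pathway product; substituting user-supplied GMT sets plus the
hypergeometric test is the one deliberate methodological replacement in
this package, and any GMT collection can be plugged in.

**Expression.** Replicates are averaged per (condition, time); each mean is
divided by the gene's average over the whole time course (so pre-log ratios
average to 1 per gene) or, optionally, over a reference condition; values
are log2. Genes qualify at `max |log2 ratio| ≥ log2(fold)`; the default
fold threshold is 5 (the stricter of the two thresholds quoted for the
same analysis; it is a required, visible parameter). Clustering is
agglomerative with Euclidean distance and average linkage — the common
default of R heatmap tooling, which the original analysis used without
stating a metric — cut into k = 6 groups by default. Zero intensities are
rejected rather than silently pseudocounted; `pseudocount` opts in.

## The synthetic study

`synthetic.generate_fixture` builds a desk-scale rendition of the study:
2 chromosomes × 2 Mb, 50 non-overlapping genes of 2–20 kb with 2–10 exons,
and three conditions (B34 control; B39d1 spontaneous; OIMd1 induced)
sharing a 200-site backbone with 20/25/25 condition-unique sites — about
1/1000 of a human experiment with the site-to-gene geometry preserved.
Site MaxD is log-normal (median 60, σ_log 0.5); 15% of shared sites gain a
log-normal ×2.5 shift in OIMd1; ten "gained enhancer" sites (median MaxD
150) are planted outside every promoter window within 50 kb of ten target
genes. Tag tracks are Poisson around triangular per-site profiles whose
peak mean equals the depth-scaled MaxD, with uniform background absorbing
the rest of the 2M-read library; replicate peak calls jitter boundaries by
±10 bp and re-measure MaxD from their own Poisson realization. Titrations
default to digested fractions {20 U: 0.50, 40 U: 0.75, 80 U: 0.93} with
Cq noise sd 0.05 — a curve whose middle concentration is the correct pick.
The expression matrix plants a +2 log2 effect on the target genes in the
induced condition over log-normal noise (sd 0.25 log2 units, triplicates).
Gene sets are the planted target set plus 20 size-matched random decoys.
All randomness flows from one seed through spawned generators; a fixed
seed reproduces every file byte for byte.

What the generator does **not** emulate: sequence content and mappability,
copy-number or GC biases, correlated replicate noise, peak-caller false
positives/negatives, overlapping or nested genes, and distance-dependent
enhancer–promoter specificity. Passing tests therefore demonstrate that the
algorithms are correct and calibrated under the stated model, not that the
biological conclusions of any particular dataset are right.

## Numerical and design choices

- Overlap means ≥ 1 shared bp under 0-based half-open coordinates,
  everywhere.
- Unique/common status is decided purely by overlap; significantly
  modified common sites are reported as `common_modified`, so either
  reading of "unique" (strict non-overlap, or non-overlap ∪ modified) can
  be recovered downstream, and the linkage pipeline accepts any status
  subset.
- Differential intensity is condition-b minus condition-a normalized MaxD;
  unique sites use the present side's value (negative when lost).
- The per-site tested statistic is the peak-bp count (summed over the two
  replicates of each side, with summed depths).
- Motif-window export centers 200 bp (even widths only) on the recorded
  peak bp, falling back to the interval midpoint, clipping at chromosome
  ends with a flag.
- Top-changed-site selection ranks TSS-proximal (±1 kb) sites by
  |Δ normalized MaxD|, ties broken by genomic position.
- Enrichment ties are ordered by set name for reproducibility; an exact
  discrete p-value can tie across sets with equal overlap geometry.
- The enrichment-null calibration uses a 40,000-gene background with
  half-background set and query sizes: the exact hypergeometric p-value is
  discrete, and the null geometry must make the p-value lattice much finer
  than a Kolmogorov–Smirnov band at n = 1000 draws for the uniformity
  check to probe calibration rather than discreteness.
- Acceptance problem sizes: 50 Venn instances of ≤ 600 intervals, 10,000
  Poisson pairs for test size, 1,000 null enrichment draws, 100 randomized
  titration designs, and 20 seeded end-to-end runs at the default fixture
  scale.

## Known limitations

- The conditional binomial is conservative at small counts; with very deep
  libraries and broad sites a total-tag statistic (not just the peak bp)
  would be more powerful. The data model carries raw pairs so such a test
  can be added without re-reading inputs.
- RC merging can chain several small sites into one span ("daisy-chain"
  unions); at realistic site spacing this is rare but unbounded in theory.
- The intergenic upstream/downstream split has no distance cap, so a site
  megabases from everything still gets a nearest-gene label.
- Enrichment treats genes exchangeably; gene length or enhancer density
  confounders are not modeled.
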