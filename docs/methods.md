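# Methods

This note records the models, conventions and numerical choices behind
`adaptscan`, and what the synthetic-data tests do and do not establish
about real data.

## Data model and conventions

Expression matrices are features × samples with one metadata row per
sample (pair, population, thermal class, developmental stage, cross,
sex mix). Each pair holds exactly one cold- and one warm-derived
population. Genomic coordinates are 0-based half-open internally; BED is
read/written natively, GFF3 and VCF are converted at the boundary. Strand
is carried through but ignored by every statistic, which are all
strand-agnostic. Tabular interchange is TSV with a header and `.` for
missing.

All randomness derives from one global seed. Each stochastic stage asks
for a child generator keyed by a stage label (`child_rng(seed, label)`,
implemented via a CRC-32 hash of the label fed into a `SeedSequence`), so
streams are independent, reproducible, and insensitive to stage order.
The orchestrator is a pure function of (inputs, config): reruns with the
same seed are byte-identical, which the test suite asserts.

## P_ST

P_ST = V_between / (V_between + 2 V_within) quantifies trait
differentiation between the two populations of a pair. With two groups,
V_between is the sample variance of the two population means, i.e.
(m_cold − m_warm)²/2 — this convention is fixed so an independent
brute-force variance decomposition reproduces the implementation to
1e-12. V_within is the unweighted mean of the two within-population
sample variances.

Choices that matter:

* **Trait scale.** Counts are divided by the sample's total mapped
  reads (proportion of transcriptome); no log transform. P_ST makes no
  distributional assumption, and the proportion scale applies uniformly
  to expression and junction-usage traits. A flag is not needed for the
  statistic itself — any positive affine rescaling leaves P_ST invariant
  (property-tested).
* **Trimming.** Each population drops its single maximum and single
  minimum sample per trait before the variances, leaving n − 2 samples
  (six of eight in the reference design). Ties are broken
  deterministically: the first sample in sample-ID sort order is
  dropped. Degenerate traits (zero total variance) get P_ST = 0 with a
  flag rather than 0/0.
* **Median-ratio normalization.** Before P_ST, the warm population's
  samples are multiplied by the median over genes of
  mean_cold/mean_warm. This counters transcriptome skew: if one
  population strongly up-regulates a few very highly expressed genes,
  every other gene's relative abundance shifts oppositely even with
  unchanged absolute expression. The median is robust to the skewed
  genes themselves; afterwards the per-gene ratio distribution has
  median exactly 1 (asserted by recomputation). It is applied uniformly
  per pair and stage, with a config flag to disable.
* **Feature filter.** A gene enters the analysis only if its summed raw
  counts across every within-population sample of the stage strictly
  exceed 200 (a gene at exactly 200 is dropped).
* **Quantiles and outliers.** The stored quantile is the upper-tail rank
  fraction (small = extreme; ties share the mean rank); outliers are
  quantile ≤ 0.05 by default. The splicing adjustment uses the opposite
  convention (values near 1 extreme); one self-inverse conversion
  function bridges the two and is tested in both directions.

### Junction usage traits

Junction usage frequency is the junction's excision count over its
cluster total per sample; frequencies within a cluster-sample sum to 1.
Filters: clusters need ≥ 2 junctions and ≥ 50 supporting reads; a
junction needs mean excision events ≥ 5 and mean alternative events ≥ 5
across samples, and ≥ 6 samples with nonzero usage in every population.
Samples with a zero cluster total have undefined (NaN) frequency and are
dropped per-trait before trimming. When several junctions of one gene
pass the outlier cutoff, only the highest-P_ST junction keeps its flag
(junctions of one gene are not independent). Gene-level splicing
significance is q′_gene = 1 − (1 − q_gene)·n_sum (floored at 0), with
n_sum = Σ(nᵢ − 1) over the gene's clusters: within a cluster the
frequencies are compositional, so one junction per cluster is redundant.

## Parallelism permutations

All tests draw B same-size random gene sets from the tested universe as
the null (default B = 10,000). Because a uniform random subset
intersected with any fixed gene class is hypergeometric, the null draws
are realised by (possibly two-stage) hypergeometric sampling — exactly
equivalent to permuting gene identities, and orders of magnitude
cheaper. Two-tailed p-values are 2 × min(inclusive tail proportions),
capped at 1; "at least as extreme" is inclusive. No pseudo-count is
added by default (a +1 option exists), so a sufficiently extreme
observation can report p = 0, read as p < 1/B. Null 95% bands are the
2.5/97.5 percentiles of the null draws.

The analytic expectation for co-directional sharing between two
independent outlier sets of sizes n₁, n₂ over n tested genes with
direction-agreement rate c is n₁n₂c/n; for two 5% sets and random
directions this is 0.125% of tested genes, and the Monte Carlo null mean
matches it within 3 standard errors (asserted).

The stage-dependence of X-linked outlier enrichment is tested with OLS
on the X-fraction table, f ~ stage × type + pair against the
no-interaction model, via LRT = n·ln(RSS_reduced/RSS_full) on a χ² with
df = parameter difference; the same machinery fits f ~ type + pair for
the pooled F_ST-enrichment analysis. Rank-deficient designs are an error
naming the design columns. If the reduced model already fits perfectly
(RSS below 1e-14) the LRT is defined as 0.

Co-regulation among outliers correlates each gene pair's expression over
the eight outbred samples of one population; the per-pair null permutes
one gene's samples, requiring ≥ 5 of 8 positions to move (rejection
sampling from uniform permutations; acceptance ≈ 0.98). One-tailed p is
the proportion of null correlations ≥ observed. Each pair gets an
independent null; constant genes are skipped.

## cis/trans resampling classifier

Orientation is always the cold side: p_F1 is the cold-allele proportion
in the F1, r_F0 = E_c/(E_c + E_w) the cold-parent share of summed
parental expression (library-size normalised), D = r_F0 − p_F1. The cis
effect is p_F1 − 0.5, the trans effect is D; both effects "favour the
cold allele" when positive, so co-/anti-directionality is a sign
comparison.

* **SNPs.** Only fixed differences between the parental strains, with
  F1 depth ≥ 10, qualify. The feature-level p_F1 summarises per-SNP
  cold fractions by the median (switchable to mean); the same summary is
  used inside the bootstrap for consistency.
* **Cis uncertainty.** B = 1000 multinomial resamples of the flattened
  SNP × allele count vector with the total fixed (equivalent to
  resampling reads with replacement), percentile 2.5/97.5 interval of
  the resampled summaries; cis is significant iff the interval excludes
  0.5. A monoallelic feature yields a degenerate interval at 0 or 1 and
  is flagged significant with a warning.
* **Trans uncertainty.** Each replicate redraws both parents' gene
  counts as Binomial(n = library total, p = gene reads / library total),
  recomputes r_F0′, and pairs it with the b-th cis bootstrap draw to
  form D′ = r_F0′ − p_F1′; trans is significant iff the 95% interval of
  D′ excludes 0. Replicates where both redrawn counts are zero are
  redrawn (logged). Post-filter library totals are used as the binomial n.
* **Representative cross.** Per feature, the between-population cross
  with the greatest absolute parental difference is used, and only if
  that difference strictly exceeds the mean cold−warm difference of the
  outbred crosses; otherwise the feature is excluded.
* **Known artifact.** Because the same F1 data enter both the cis
  estimate and (through D) the trans estimate with opposite signs, pure
  measurement error induces a negative correlation between estimated cis
  and trans effects. The test suite reproduces this (correlation < 0,
  p < 0.01 at depth 100 with zero true effects); biological
  interpretation of anti-directional cis/trans pairs therefore requires
  caution, and the enrichment statistics exclude the both-anti-directional
  category by default.
* **Enrichment chi-squares.** The outlier-vs-nonoutlier 2×2 uses Pearson
  chi-square **with** continuity correction (required to reproduce the
  published worked-example values); cis-affected = cis-only + both
  co-directional, likewise for trans. Fisher's exact test is reported
  additionally when an expected cell is below 1, and is the primary test
  for the small parallel-vs-nonparallel and cis-vs-F_ST tables.
* **Magnitude comparison** of |cis| vs |trans| uses the paired Wilcoxon
  signed-rank test.

The intron-usage variant substitutes junction usage frequencies for
expression levels (p_F1 from diagnostic SNPs in the junction, r_F0 from
parental usage frequencies) under the identical resampling contract.

## F_ST scans

Hudson's estimator is used throughout (no estimator is canonical for
this design; Hudson is robust to unequal sample sizes and is recorded in
output metadata; a Weir–Cockerham site estimator is available behind a
flag). Per site, num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and
den = p₁(1−p₂) + p₂(1−p₁); sites with < 10 sampled alleles in either
population, or monomorphic across both, are undefined and skipped. Note
the finite-sample correction makes the estimate slightly negative at
identical sample frequencies; negative values are reported raw and
clipped to 0 when ranking maxima.

Windows contain exactly 250 non-singleton variable sites (minor allele
count ≥ 2) of a designated reference population, per arm, trailing
partial window dropped; window F_ST is the ratio of summed numerators to
summed denominators over the window's sites with ≥ 5 called haplotypes
per population. A single-site window equals the site estimate
(asserted).

A gene's focal region is its span ± 2 kb, closed at both ends (a SNP
exactly 2 kb beyond the gene boundary is included). F_ST_winmax is the
maximum over windows overlapping the focal region, F_ST_SNPmax the
maximum site value inside it. Significance: blocks of the same window
count slide one window at a time along the arm's high-recombination
interval (defaults X 2.3–21.4 Mb, 2L 0.5–17.5, 2R 5.2–20.8, 3L 0.6–17.7,
3R 6.9–26.6), excluding blocks within 10 windows of the focal region;
the quantile is the inclusive fraction of block maxima ≥ the focal
value, outlier iff ≤ 0.05. SNP blocks (same SNP count, sliding one SNP)
use an exclusion zone of the focal region padded by 10 × the arm's
median window span, since SNP blocks have no window index. Genes whose
focal region leaves the masked interval, or arms with < 50 candidate
blocks, are flagged and receive no call.

## Synthetic data

The generator emulates the study design, not its biology:

* **Expression study** — up to three pairs × two populations × eight
  outbred crosses × three stages. Gene baseline abundances are
  lognormal (σ = 1.5); counts are negative-binomial via gamma–Poisson
  (default dispersion 0.05, typical of bulk RNA-seq across outbred
  biological replicates); library sizes lognormal around 10⁶ reads. A
  chosen fraction of genes is truly differentiated with a 2^lfc
  fold-change in the cold population; a chosen fraction of those share
  one direction across all pairs (parallel), the rest draw directions
  independently. A fraction of genes (default 0.2, near the genomic
  share of the X) is X-linked. An optional skew preset multiplies the
  few most-expressed genes of one cold population to exercise the
  median-ratio normalization.
* **Junction study** — clusters of 2–4 junctions, Dirichlet base usage,
  Poisson cluster totals, multinomial junction counts; differentiated
  clusters shift the first junction's usage in the cold population.
* **ASE experiment** — multiplicative cis (κ) and trans (τ)
  fold-changes. Each F1 read derives from the cold allele with
  probability κ/(κ+1); the warm parent expresses at a small baseline
  rate and the cold parent at κτ × that rate, so the closed forms
  p_F1 → κ/(κ+1) and r_F0 → κτ/(κτ+1) are exact oracles. Optional
  lognormal spread on κ and τ produces effect-size variation.
* **Genotypes** — symmetric Balding–Nichols: ancestral frequencies
  uniform on (0.05, 0.95), each population's frequency a Beta draw with
  the stated baseline F_ST; planted outlier loci receive an extra
  ± δ/2 shift in opposite directions (clipped, logged). Sites are
  independent; positions are uniform over the arm's high-recombination
  interval.

What the generator does **not** emulate: linkage disequilibrium and
selective sweeps' haplotype structure, GC/length biases and mapping
error, batch effects, stage-dependent effect sizes, regulatory-network
dependence among genes (the permutation tests assume independence, as
flagged for the real analysis too), and partially-inbred parental
heterozygosity. Passing tests therefore establish the statistics'
internal correctness and calibration under the stated noise models, not
robustness to those real-data complications.

### Positive-control design

The parallelism positive control plants differentiated genes at the
outlier fraction itself (5% of genes differentiated, all parallel,
|lfc| = 2): the planted set then coincides with the outlier definition,
and the shared co-directional count is expected near the full outlier
count rather than being diluted across excess differentiated genes that
compete for a fixed number of outlier slots. Under this design the
shared-outlier test rejects at the 97.5% null percentile in every
replicate tested. The F_ST positive control plants ten consecutive
strongly differentiated SNPs inside one gene's focal region on an
otherwise low-differentiation arm (baseline F_ST 0.02).

## Problem sizes and runtime

Test-suite and acceptance-script simulation sizes were chosen so that
Monte Carlo error is small relative to each asserted tolerance:
classifier calibration at 500 genes × depth 1000 × B = 1000, power at
200 genes, the artifact check at 1000 genes × depth 100, P_ST null
calibration at 150 genes × 20 (tests) or 10 (script) seeds, F_ST
recovery at 10,000 sites × 60 haplotypes, positive controls at 10 seeds
each. The full suite runs in about a minute on one CPU; the acceptance
script in ~20 s.

## Known limitations

* The two-group V_between convention is a definitional choice; other
  conventions rescale P_ST monotonically and leave outlier ranks
  unchanged.
* Permutation p-values are granular at 1/B and can be exactly 0.
* The coregulation null constrains only the number of displaced
  samples, not the permutation cycle type; with eight samples the
  approximation is inconsequential.
* The cis/trans classifier requires fixed parental differences; the
  polymorphic-site alternative is exercised only qualitatively in the
  validation grid (it needs hundreds of F1 individuals per cross to be
  competitive, which the low-signal grid cells illustrate).
* Windows inherit the reference population's site density; arms with
  sparse reference polymorphism yield few windows and flagged,
  uncallable genes rather than unstable quantiles.
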