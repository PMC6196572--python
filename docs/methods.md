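# Methods

## Scope and data model

The package analyses two-group per-CpG methylation studies. A
`MethylationSiteTable` holds, per CpG and sample, either methylated/total
read counts (RRBS-style, *count mode*) or a percent-methylation value in
[0, 100] (HM450 β-value-style, *fraction mode*). Exactly two groups are
required; the lexicographically first group label is group A, so the
signed difference Δ = m̄_B − m̄_A and the hyper/hypo directions are a
deterministic property of the label names, and exchanging the two labels
exchanges the groups' roles (this antisymmetry is tested).

All coordinates are 0-based half-open, matching BED and refFlat; a CpG
is keyed by the plus-strand position of its cytosine and the two strands
of the dinucleotide are not distinguished (bisulfite pipelines emit one
collapsed record per CpG). Chromosome names are compared verbatim;
chromosomes present in a methylation table but absent from the gene
track are logged, and their sites fall through to *intergenic*. Missing
cells are the `NA` token on disk and NaN in memory.

## Coverage filtering

Read-count tables are trimmed before calling, under one of two policies
that reflect the two study designs the pipeline serves:

* **drop_site** (`min_reads` = 10): a CpG is kept only if *every* sample
  covers it with at least `min_reads` reads — appropriate for small
  homogeneous designs (e.g. 3 vs 3 cell-line replicates), where a single
  undersampled library makes the site's group means unreliable.
* **drop_sample** (`min_reads` = 10, `min_samples_per_group` = 1):
  individual low-coverage samples are masked per site, and the site is
  kept while each group retains at least `min_samples_per_group`
  unmasked samples — appropriate for large heterogeneous cohorts, where
  demanding full coverage across dozens of samples would discard most of
  the genome. The minimum surviving samples per group is configurable;
  the default of 1 is deliberately permissive and can be raised when
  group means from a single sample are unacceptable.

Missing cells count as below-threshold in both policies. Fraction-mode
tables bypass coverage filtering entirely (array β values carry no read
depth); `apply_filter` refuses them rather than silently passing them
through. Both policies are monotone in `min_reads` (tested).

## Differential methylation calling

Group means are unweighted means of per-sample percent values, not
pooled read counts — pooling would let a deeply sequenced sample
dominate its group. The call rule is |Δ| ≥ `threshold_points` (default
30) in percentage points, an absolute — not relative — difference. The
boundary is inclusive by default with a `strict` flag for the
strictly-greater variant, since both phrasings circulate for this style
of threshold; Δ = 0 is never a call. Sites where masking empties a group
are skipped and tallied (`n_excluded`), not errors. Count-mode calling
agrees exactly with converting to percents and calling in fraction mode
(tested). Per-chromosome summaries report both DM counts and
100·(DM on chrom)/(tested on chrom).

No smoothing, beta-binomial modelling or multiple-testing correction is
applied: the method is a deliberate pure effect-size screen, and its
false-positive behaviour is governed by coverage (the synthetic null
test quantifies this: at ~50× coverage and 3 vs 3 samples, a 30-point
threshold on undisturbed sites calls essentially nothing).

## Genomic-context annotation

Promoters are strand-aware: [TSS − 2 kb, TSS) for plus-strand genes and
[tx_end, tx_end + 2 kb) for minus-strand genes, where the TSS of a minus
gene is its tx_end. "Upstream of the TSS" is meaningless without strand,
so strand-silent phrasings are resolved this way. Gene bodies are
[tx_start, tx_end). A site's single reported category uses precedence
promoter > gene body > intergenic; per-gene tallies instead count every
(gene, role) hit, so a CpG in the promoter of one gene and the body of
an overlapping gene contributes to both. Within a body, a site is exonic
iff it falls in any exon block (of any overlapping body-hit gene), else
intronic.

Island context uses the standard 450k nomenclature with configurable
widths: island (inside an interval), shore (within 2 kb of the nearest
island edge), shelf (the next 2 kb), open sea (beyond, or chromosomes
with no islands). Distance to a half-open island [s, e) is 0 inside,
s − p to the left and p − (e−1) to the right; the nearest island
governs, and ties between equidistant islands are broken toward the
lower coordinate (deterministic but immaterial to the class, which
depends only on the distance). Classification is verified against an
exhaustive per-position distance scan.

Gene-level summaries count DM CpGs per (promoter/body × hyper/hypo)
cell and report a cumulative histogram of genes with ≥ t affected CpGs
at t ∈ {1, 2, 5, 8, 10, 20, 50, 100}. For "most affected gene" rankings
two orderings are available from the same summary — raw DM count and DM
count per indexed CpG — since either definition of a per-gene
differential-methylation rate is defensible; neither is privileged.

## Adjacency-clustering permutation test

For each (gene, region) with at least one DM CpG, the tested (post-
filter) CpGs in that region form an index in genomic order; DM CpGs are
flags on that index. The default statistic is the number of adjacent
index pairs (i, i+1) with both flags set; a site-based variant (flagged
sites having a flagged neighbour) is available via `statistic="sites"`.
Adjacency is defined on assay index order, not genomic distance — the
null model re-places the same number of flags uniformly at random
without replacement among the same number of positions, which is only
meaningful on the index.

p = n_ge/trials where n_ge counts trials whose null statistic is ≥ the
observed one; when n_ge = 0 the p-value is floored at 1/trials
(default trials = 100,000, hence a floor of 1×10⁻⁵), the standard
resampling convention that avoids reporting an impossible zero. The
exact null survival function is also available in closed form for the
pair statistic — the number of k-subsets of n indexed positions with
exactly j adjacent pairs is C(k−1, j)·C(n−k+1, k−j) — and the Monte-
Carlo test is validated against both this closed form and brute-force
enumeration for n ≤ 12. Under uniform flag placement the discrete test
is conservative (P(p ≤ α) ≤ α, checked by simulation).

Each region draws from an RNG stream derived from (master seed,
CRC-32 of the region id), so results are independent of the order in
which regions are processed and reproducible region-by-region.

## Expression integration

FPKM = counts·10⁹/(length·total), with totals defaulting to per-sample
column sums and gene lengths taken as exonic lengths. DE calling is
conjunctive: group fold change ≥ 2 in either direction *and* unpaired
two-tailed t-test p < 0.05, with no multiple-testing correction —
mirroring the screen this pipeline reproduces. Student's equal-variance
test is the default (a Welch flag exists); the test is unpaired even
when cohorts are matched, as the plain two-group form is what the
screen defines. Fold changes use a pseudocount ε = 0.1 on both means to
guard zero denominators; the fold boundary is inclusive by default with
a `strict` flag, matching the methylation threshold's convention.

Concordance strata are (promoter/body) × (hyper/hypo); a gene enters a
stratum when it carries ≥ `min_cpg` (default 1) DM CpGs of that
direction in that region and is present in the expression analysis
(unmatched gene identifiers are excluded from denominators). Fractions
down/up/unchanged sum to 1 per non-empty stratum; empty strata report
`None` rather than NaN arithmetic.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with every quantity driven by one seed through named `SeedSequence`
children (stage keys 1–3), so identical configs give byte-identical
files.

* **Gene/island tracks**: non-overlapping stranded genes laid
  left-to-right with intergenic gaps > 2 kb (promoters never collide),
  2–10 exon blocks per gene with exonic transcript edges; CpG islands
  placed inside a configurable fraction (default 0.7) of promoters.
* **Baseline methylation**: a bimodal beta mixture — Beta(2, 20)
  (mode ≈ 5%) and Beta(19, 3) (mode ≈ 90%) at equal weight — matching
  the genome-wide bimodality of bisulfite data rather than a uniform
  baseline.
* **Coverage**: negative binomial (mean 50, size 8), overdispersed
  relative to Poisson so that the two filter policies are exercised by
  realistic coverage dropouts (~25% of sites lose at least one of six
  samples below 10 reads).
* **Planted DM**: 400 sites by default, shifted by ±50 percentage
  points on the probability scale in group B (90% gains), with
  clipping to [0, 1] recorded per site (`clipped`, `delta_achieved`) so
  recovery tests can exclude saturated sites. 60% of DM sites form runs
  of 8 consecutive indexed CpGs within randomly chosen promoters;
  clustered sites have their baseline redrawn from the mixture mode
  that accommodates the shift (gains start low, losses start high),
  modelling coherent promoter runs that gain methylation — without
  this, half of a planted gain-cluster would saturate and the run would
  fragment. Scattered sites keep their mixture baseline.
* **Expression**: per-gene negative-binomial counts (lognormal baseline
  means, size 20) for 22 + 22 samples; among promoter-hyper genes a
  Bernoulli(concordance = 0.52) subset is down-regulated fourfold, plus
  40 independent DE genes in random directions among the remaining
  genes.

Defaults (200 genes, ~20k CpGs, 3 vs 3 methylation samples, 22 vs 22
expression samples) run the full pipeline in a few seconds; all
recovery statistics in the tests use these or smaller sizes.

What the generator does **not** model — and hence what passing tests do
not establish about real data: per-sample biological variability of
methylation within a group (a site's methylation probability is shared
by all samples of a group), bisulfite conversion failure, SNP-driven
artefacts, batch effects, overlapping genes and alternative promoters,
chromosome-scale covariates (the per-chromosome summaries are exercised
structurally, not biologically), and tumor purity/heterogeneity
attenuation of deltas. Recovery rates on this generator characterise
the pipeline's arithmetic and thresholds, not its behaviour under those
confounders.

## Numerical and design notes

* Fixture scale: the clustering acceptance check uses a region of 500
  indexed CpGs with a 10-run (observed adjacency 9), for which the
  exact null tail is ~2×10⁻¹⁸ — the 100,000-trial floor of 1×10⁻⁵ is
  then certain, not probabilistic. With sparser indices (25 CpGs, 8-run)
  the exact tail is ~1.7×10⁻⁵ and a handful of null hits is expected;
  such regions legitimately report p of a few ×10⁻⁵ rather than the
  floor, as the worked example shows.
* Degenerate inputs: empty flag arrays, observed counts exceeding
  n_dm − 1, n_dm > n_total, fraction-mode coverage filtering, groups
  with < 2 expression samples, zero lengths/totals all raise typed
  errors (`ContractError`/`ValidationError`); empty groups at a site
  and empty concordance strata are tallied/marked, not errors.
* t-test p-values of zero-variance identical groups (scipy returns NaN)
  are treated as 1 — identical groups are never DE.
* The pipeline writes only TSV and a JSON manifest (package and library
  versions, seed, all parameters, SHA-256 checksums of file inputs);
  reruns from the manifest's config and seed are byte-identical,
  which the suite asserts.
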