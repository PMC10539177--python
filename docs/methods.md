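# Methods

## Copy-number model and clonality

A sample is a mixture of a deletion-bearing clone (fraction *f*, one
copy at the locus) and normal cells (two copies).  The bulk copy ratio
at a deleted locus is (2 − *f*)/2, so the mean log2 segment ratio is
*r* = log2((2 − *f*)/2) and *f* = 2(1 − 2^*r*), clipped to [0, 1].
When several deletion segments overlap the target region, their log2
ratios are averaged weighted by overlap length before inversion.  A
segment counts as a deletion when its log2 ratio falls below a cutoff
(default −0.1; upstream callers differ in noise floors, so this is
configurable rather than exactly 0).

The estimator assumes a single deletion clone per sample; nested or
independent subclonal deletions of the same region are not
deconvolved.  It also assumes the segment means are allele-specific
noise-free averages — real segment means carry GC/coverage noise that
propagates directly into *f*.

## Deletion-frequency profile and CDRs

Per chromosome, per-sample deletion intervals are merged, and a sweep
over the sorted unique breakpoints yields a stepwise frequency
function: for each elementary interval, the fraction of *deleted*
samples (samples with any deletion on that chromosome — not the whole
cohort) whose merged deletion covers it.  Commonly deleted regions at
threshold *t* are maximal runs of adjacent elementary intervals with
frequency strictly greater than *t* (strict inequality mirrors the
">70% / >80% / >90%" convention); a region's reported frequency is the
minimum over its members, i.e. the fraction deleting the region in
full.  Genes are attached only when fully contained.  Coordinates are
0-based half-open internally; SEG input is converted from 1-based
inclusive at the I/O boundary and BED passes through.

## Clonal hierarchy

CCF adjustment by zygosity and local copy number:

| zygosity      | locus copies (bulk)  | CCF       |
|---------------|----------------------|-----------|
| heterozygous  | 2                    | 2·VAF     |
| hemizygous    | 2 − f                | VAF·(2−f) |
| homozygous    | 2                    | VAF       |

The hemizygous formula assumes the mutation lies on the retained allele
of deletion-bearing cells (mutation clone nested inside the deletion
clone); the alternative topologies cannot be separated from a single
bulk VAF.  CCFs beyond [0, 1] are clipped, with a warning when the
excursion exceeds 0.02 (binomial sampling at modest depth routinely
overshoots slightly).  Heterozygous or homozygous calls *inside* the
deleted region are rejected as inconsistent — with one allele present
only the hemizygous configuration exists there.

Classification uses a 5-percentage-point rule: |f − CCF| < 0.05 is
co-dominant (not arithmetically resolvable), otherwise the larger of
the two is dominant.  A difference of exactly 5 points resolves the
order.  Because 0.05 and most measured fractions are not exactly
representable in binary floating point, the comparison carries a 1e-12
guard so that decimally-exact 5% differences classify as resolved.  The
sample-level verdict compares the deletion against the sample's largest
mutation clone (one founder per sample); a sample without somatic
variants is "deletion_only".

## Haploinsufficiency calling

1. **Low-expression filter.**  A gene is dropped when more than 10% of
   diploid samples express it at or below a floor (default 1.0 in the
   matrix's normalized units; "very low" has no canonical value, so
   the floor is configurable).
2. **Region restriction.**  Only genes whose deletion frequency among
   deleted samples strictly exceeds 70% are assessed — dosage evidence
   is meaningless for genes most deleted samples retain.
3. **Clonality adjustment.**  Per gene, OLS of expression on clonality
   over deleted samples; each deleted sample is extrapolated to full
   clonality, `adjusted = value + slope·(1 − f)`.  Diploid samples are
   untouched.  The fitted slope is applied unconditionally, regardless
   of sign or significance (a `require_negative_slope` flag restricts
   adjustment to negative slopes).  At least 3 deleted samples with
   non-identical clonalities are required; a degenerate design raises.
   By construction the OLS extrapolation leaves the adjusted values
   exactly orthogonal to clonality — the residual slope is numerically
   zero, not merely statistically small.
4. **Tier calling.**  fraction_below = share of deleted samples whose
   adjusted value is strictly below the diploid median (linear
   interpolation for even counts).  The HI tier is the largest of
   80/85/90/95 strictly exceeded; tier 100 requires every deleted
   sample below the median.

The regression may be fitted on linear or log2(x+1) values; the scale
is declared in the matrix and both are supported (the dosage model is
linear in clonality only on the linear scale, so log-scale fits trade
exactness for variance stabilization).

## Signature clustering

Genes are z-scored across samples, samples are clustered
hierarchically and the tree is cut at two clusters; each cluster is
assigned the majority karyotype, and the per-class error rate is the
fraction of that class landing in a cluster mapped to the other class
(if both clusters share a majority, the whole minority class counts as
misclassified).  Default distance/linkage: **euclidean on z-scores with
Ward linkage**.  The class signal of a dosage signature is a shared
downshift across all signature genes; the Pearson-correlation distance
subtracts each sample's mean profile and is therefore blind to exactly
that signal (on the default synthetic cohort it misclassifies every
deleted sample, while Ward/euclidean reproduces the expected few-percent
error).  1 − Pearson with average linkage remains available for
signatures whose signal is a pattern rather than a shift.

The minimal-signature search is greedy forward selection from the
strict-tier HI set, minimizing the summed class error rates, ties
broken alphabetically, stopping when no gene improves the total or a
size cap is reached.  Greedy selection is transparent and
deterministic; it is not guaranteed globally optimal.  Single-gene
signatures are scored with euclidean distance (correlation needs at
least two features).  A published four-gene minimal signature (AGK,
ARPC1A, ZNF277, ZNF398) ships as preset `min4` for scoring user data.

## Moderated differential expression

Two-group comparison on log2 values for genes outside the CDRs (linear
input is log2(x+1)-transformed).  Gene-wise pooled variances s²_g with
d residual degrees of freedom are shrunk toward a prior s²₀ with d₀
prior degrees of freedom estimated by matching the mean and variance of
log s²_g to the scaled-F model s²_g ~ s²₀·F(d, d₀) (digamma/trigamma
moments; trigamma inverted by Newton iteration).  The moderated t uses
the posterior variance (d₀s²₀ + d s²_g)/(d₀ + d) on d + d₀ degrees of
freedom.  `prior_df=0` disables shrinkage (the statistic then equals
the ordinary equal-variance t exactly); `prior_df=inf` pools all genes.
The implementation agrees with the reference empirical-Bayes
implementation in Bioconductor to ~1e-14 on shared inputs (verified in
the test suite via Rscript).

P-values are corrected by the Benjamini–Hochberg step-up
(q(i) = min over j ≥ i of p(j)·m/j, capped at 1).  Significance:
log2FC strictly above 1 (below −1) *and* −log10(q) strictly above 5.
The q-value logarithm is read base-10: a natural-log reading would put
the cut at q < e⁻⁵ ≈ 6.7×10⁻³, implausibly permissive next to a 2-fold
change requirement; the base is configurable.

## Synthetic-lethal filter

An HI gene is a candidate iff it has **no** hemizygous or homozygous
loss-of-function mutation in the cohort (a natural knockout compatible
with survival argues against lethality of inhibition) **and** is
knockout-lethal in mice **or** screen-vulnerable.  The OR combination
is the default: it is the only reading under which the published
evidence lists (16 KO-lethal + 15 screen-vulnerable, 2 shared, minus
the LOF-affected CUX1 and EZH2) reproduce the published total of 27
candidates; the strict conjunction is available as rule `all_three`.
Screen vulnerability: dependency score below −0.5 in at least half of
the assayed cell lines (DepMap-style scores, lower = more essential;
the exact significance procedure behind the published screen calls is
not specified, so both cutoffs are configurable).  Genes absent from a
screen are "not assayed" and never vulnerable.

## Synthetic cohort generator

The generator emulates the study conditions end to end; its defaults
are the conditions all recovery tests run under.

| parameter          | default    | meaning                                   |
|--------------------|------------|-------------------------------------------|
| n_deleted/n_diploid| 49 / 120   | RNA-seq cohort sizes                      |
| clonality_range    | [0.3, 1.0] | deletion clonal fraction, uniform         |
| noise_cv           | 0.2        | CV of multiplicative expression noise     |
| dosage_slope_sd    | 0.15       | per-gene spread of dosage coefficients    |
| depth              | 500        | reads per variant (binomial; inf = exact) |
| core interval      | 96–152 Mb  | span deleted in >90% of deleted samples   |
| n_genes_chr7/other | 120 / 80   | gene panel sizes                          |

Deletions: half the deleted samples lose the whole chromosome, the
rest carry a 7q deletion spanning the core; 5% carry a partial
breakpoint inside the core, producing the nested frequency profile the
CDR mapper must resolve.  Segment log2 ratios encode clonality
exactly.  Expression follows a one-allele dosage model: a covered gene
with dosage coefficient β has mean baseline·(1 − β·f/2); planted HI
genes draw β ~ N(1, 0.15) (β = 1 is full one-allele dosage; the spread
emulates partial compensation), compensated genes have β = 0.
Multiplicative Gaussian noise with the configured CV, truncated at 1%
of the mean to stay positive.  With noise_cv = 0 the dosage law is
exact, which the tests exploit.

Variants are planted in designed CCF strata relative to *f*: sample
maxima at f ± U(0.12, 0.25) (dominant/secondary), exactly f
(co-dominant), plus a variant at exactly f − 0.05 in secondary samples
to probe the cutoff edge (nudged by machine ulps so the represented
difference is not below 0.05).  Observed VAFs are binomial draws at
the configured depth.  Hemizygous LOF mutations are planted in three
core genes and one homozygous LOF gene in diploid carriers, feeding the
candidate filter's veto.  Planted differential genes on another
chromosome draw |log2FC| uniform on [1, 3] — fold changes from 2× up
to 8×, a realistic effect-size range whose lower edge sits at the
significance cut — with 10 genes up and 10 down.  Dependency screens
plant essential genes at score N(−1, 0.15) versus N(0, 0.15), and a
knockout-lethality table flags a mix of essential-HI and non-HI genes.

Everything derives from one `numpy` Generator seeded by the config;
identical configs give byte-identical written cohorts.

What the generator does **not** emulate: read-level data, GC/coverage
noise in segment means, mutation co-occurrence structure, expression
covariance between genes, batch effects, subclonal multi-deletion
architectures, and single-cell modalities.  Recovery results on this
cohort therefore demonstrate correctness of the estimators under the
stated model, not robustness to every artifact of real cohorts.

## Problem sizes and numerical choices

Recovery and calibration suites run at the default cohort size
(49 + 169 samples, 200 genes) over 20 seeds, and the null calibration
of the moderated test at 2000 genes × 20 seeds — sizes chosen so the
full suite completes in well under a minute per criterion while keeping
Monte-Carlo error far from the asserted margins.  Ties and edges:
strict inequalities at every published threshold (>10% low-expression,
>70% deletion frequency, tier fractions, |log2FC| > 1, −log10 q > 5);
the 5% hierarchy cutoff resolves exact differences as non-co-dominant;
medians use linear interpolation; BH is the exact step-up.  Degenerate
inputs (no deletion in target region, constant clonalities, zero
residual df, constant signature genes, empty variant sets) raise
typed errors or documented fallbacks rather than propagating NaNs.

## Known limitations

* Clonality from total copy ratio only; no B-allele-frequency support.
* One deletion clone per sample; the hierarchy is a three-way label,
  not a phylogeny.
* The moderated test assumes log-scale normality and equal group
  variances per gene.
* The greedy minimal signature is locally optimal only.
* KO-mouse lethality and dependency tables are consumed as curated
  inputs; no provenance checking is performed.
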