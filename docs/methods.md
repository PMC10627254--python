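# Methods

## The problem

When a *Drosophila melanogaster* female mates, she receives sperm and
seminal fluid, both of which carry RNA. RNA-seq of her reproductive-tract
organs (parovaria, seminal receptacle, spermatheca) therefore recovers a
mixture of her own transcripts and male-derived ones. When the parents
come from different fully inbred (essentially homozygous) lines, every
exonic site at which the two lines are fixed for different alleles is a
*distinguishing SNP*: any read covering it can be attributed to one
parent. `matecall` implements this attribution end to end, from SNP
discovery to per-gene, per-library origin calls and the downstream
enrichment, sharing, abundance and QC statistics, together with a
synthetic-data generator that lets the whole pipeline run and be scored
against ground truth without any external data.

## Distinguishing-SNP discovery (`genotypes`)

A candidate site must be homozygous in both lines with different alleles;
heterozygous or missing calls in either line disqualify it (a fixed
difference cannot be certified). Multi-allelic and non-SNP records are
skipped with a logged count. A retained site must fall in an exon of
exactly one gene (positions inside overlapping exons of two genes, e.g.
on opposite strands, are dropped), outside any supplied mask regions, and
must be exonic in the gene's *longest* transcript, on which its
transcript coordinate is computed. Sites exonic only in a shorter isoform
are excluded and counted: all downstream span logic is defined on the
longest transcript, so a site invisible there cannot contribute to span.
Ties for longest transcript break to the lexicographically smallest
transcript id.

A gene is **detectable** in a cross when it has at least `min_snps = 5`
distinguishing SNPs whose transcript positions span at least
`min_span = 0.75` of the longest transcript. Span is computed in
transcript coordinates as `(max − min) / L`; the inclusive variant
`(max − min + 1) / L` is available via `Thresholds(span_inclusive=True)`.

Coordinates are 1-based inclusive throughout (VCF/GFF convention); BED
masks are half-open `[start, end)` and converted on load. Inputs must
share one genome coordinate system; no liftover is performed.

## Per-library classification (`allelic`)

At each distinguishing site in a library, allele depths are oriented to
the parental alleles (not ref/alt); depth on an allele matching neither
parent accumulates in `depth_other`. The rules, applied conjunctively and
deterministically:

- a site participates only if its total depth ≥ `min_site_cov = 3`;
- an allele is *present* at a participating site iff it has
  ≥ `min_allele_calls = 3` reads (both alleles can be present; a covered
  site where neither allele reaches 3 supports neither sex);
- a sex's criteria hold for a gene iff it has ≥ `min_snps = 5` present
  sites, total depth summed over those sites ≥ `min_sum_cov = 15`, and
  those sites span ≥ `min_span = 0.75` of the longest transcript.

The summed-coverage rule uses the *total* site depth over the sex's
present sites by default; `Thresholds(sum_allele_specific=True)` switches
to the sex's own allele depth. The two conventions can only diverge when
`min_sum_cov > min_snps × min_allele_calls`; at the defaults
(15 = 5 × 3) they coincide, which is why `Thresholds` only warns, rather
than errors, on inconsistent combinations.

The call is `male`, `female`, `both`, or `undetermined` according to
which sexes' criteria hold. Genes detectable in the cross but failing
both are emitted as `undetermined`, never dropped, so denominators remain
auditable. Classification contains no randomness and no ties.

Note the implied abundance floor: a sex needs on average
`min_span × min_site_cov = 0.75 × 3 = 2.25` reads per SNP across the
transcript to be callable, which is what makes the procedure a
conservative positive assertion of male origin.

## Parent-specific references and the cross-organ update (`diploid_ref`)

For each parent, the reference longest transcript of every gene gets that
parent's alleles substituted at the distinguishing sites (complemented
onto the coding strand for minus-strand genes), so the two personalized
references differ at exactly those positions. Reads placed in transcript
coordinates are assigned to the parent whose alleles they match at every
overlapped site; reads overlapping no site, or matching neither parent
consistently, stay unassigned. This exact-match rule is a desk-scale
stand-in for competitive alignment against both personalized genomes: for
error-free reads the two are equivalent, and ambiguity resolves
conservatively to unassigned. An adapter (`reads_from_sam`) accepts
externally produced transcript-space alignments for real data.

The per-(gene, library, parent) *footprint span* — the fraction of the
transcript between the outermost assigned-read endpoints — feeds the
second-round update: a gene called male (or female) from SNP evidence in
one organ of a cross gains that call in another organ of the same cross
when the parent-specific footprint span there reaches `min_span`. Read
footprints (not just SNP positions) are used because this second round
exists to rescue genes whose SNP coverage is patchy for alignment
reasons. Updated rows are marked `evidence_source=parent_specific_update`;
SNP-derived calls are never overwritten or downgraded — propagation only
adds an origin (`undetermined → male`, `female → both`).

## Downstream statistics (`enrichment`)

**Gene-list enrichment.** With `k` list members among `n` male-derived
genes and `K` list members among `N` detectable genes, the reported
p-value is the exact upper tail *excluding* the observed count,
`p = P(X > k)` for `X ~ Binomial(n, K/N)` — the standard survival
function evaluated at the observed count. Lists are intersected with the
detectable background before counting, lists may overlap, and no
multiple-testing correction is applied. The detection background `N` is
always an explicit input, never hard-coded: which universe of detectable
genes is appropriate depends on the filtering stage the user intends.

**Sharing.** Within-cross sharing is the fraction of genes male-called in
≥ 1 organ of a cross that are male-called in *all* organs of that cross,
pooled over crosses with ≥ 2 organs. Across-cross sharing is, for each
ordered cross pair and each organ present in both, the fraction of genes
male-called in the first cross's organ also male-called in the second's,
averaged over pairs and organs. A statistic undefined for the design
(single organ or single cross) is reported as not-available, never 0.

**Abundance.** Per (gene, library) with a male call, the male-allele
depth summed over male-present SNPs divided by the number of those SNPs
("reads per SNP"); per gene, the mean over such libraries. Genes at or
above the 95th percentile are flagged, ties at the boundary included.
The male-allele depth (not total site depth) is summed because the
quantity estimates the abundance of the male-derived molecules
themselves.

**Expression cross-reference.** Each male-derived gene is checked against
TPM tables from male reference tissues: expressed in accessory gland or
testis (TPM ≥ `tpm_floor = 1` in either), sperm-supported (TPM ≥ floor in
*all* sperm replicates), or an accessory-gland candidate (TPM < floor in
all sperm replicates). Genes absent from the table count as TPM 0 with a
log message. A gene with mixed sperm replicates is neither
sperm-supported nor an AG candidate.

**Coverage QC.** Per tissue, per cross pair, a two-sample
Kolmogorov–Smirnov test on the per-SNP male-allele coverage vectors
(scipy `ks_2samp`); groups with fewer than 2 sites report NaN.

## The synthetic-data generator (`synthetic_data`)

`simulate_genomes` lays out single-exon genes (alternating strand) on one
synthetic chromosome, draws per-base fixed differences at `snp_rate`, and
assigns each gene an origin class from `origin_mix` over
(female_only, male_only, both) and relative abundances. Defaults emulate
one cross of the study design: 300 genes, transcript lengths 500–3000 bp,
`snp_rate = 0.01` (giving a realistic ~5–30 SNPs per gene and roughly
80% detectable genes), `origin_mix = (0.5, 0.25, 0.25)`,
`abundance_scale = 10` mean reads per site at relative abundance 1,
`error_rate = 0`, three libraries (the three organs of one cross).
Relative abundances are LogNormal(0, 0.5) — median 1 with moderate
spread, representing the moderately expressed transcripts the method
targets; extreme low-expression tails are deliberately not modelled,
since genes below the coverage criteria are undetectable by construction.

`simulate_library` draws each parental allele's depth at each site as
Poisson with mean `abundance × abundance_scale × w(pos)`, where the
3′-bias weight is `w(pos) = (pos/L)^degradation_bias` renormalized to
mean 1 over the transcript — the simplest monotone family consistent with
degraded transcripts being 3′-enriched under polyA selection; `bias = 0`
gives uniform coverage. Cross-allele error is symmetric binomial
thinning: a fraction `error_rate` of each allele's reads is reassigned to
the other allele. This stresses the ≥3-calls rule without modelling
base-level sequencing error, PCR duplicates or mapping bias (all
non-goals). `simulate_reads` optionally emits fixed-length fragments
carrying the parental haplotype, for exercising the diploid-reference
path. Each library draws from its own RNG stream keyed on
(seed, library_id), so any library is reproducible in isolation.

What passing recovery tests therefore show: the *rules* are implemented
correctly and are conservative in the stated sense (zero false male
calls without cross-allele error, sensitivity increasing with depth).
What they do not show: robustness to mapping bias, isoform mixtures,
residual heterozygosity, or genotype errors in real lines — the
simulator does not generate those failure modes.

The module also scores recovery: `confusion_matrix` (true origin × called
class over a gene universe, genes without calls counted undetermined) and
`recovery_metrics` (male sensitivity, female-only specificity), where a
gene's called class is the union of its per-library calls.

## Numerical and design notes

- All classification thresholds live in one `Thresholds` dataclass;
  every rule is a ≥ comparison on integers or exact fractions, so there
  are no floating-point tie concerns.
- The cross-with-5×-scale coverage difference observed between crosses in
  real data is treated as an input phenomenon: the simulator exposes
  `abundance_scale` per library/cross but deliberately models no
  mechanism for it.
- Problem sizes in the test suite (300-gene crosses, 3 libraries, seeds
  1–5, scale sweep {2, 5, 10, 20}) were chosen as the smallest design on
  which the recovery properties are stable run-to-run.
- Known limitations: no indels or structural variants; no phasing;
  multi-allelic SNPs are skipped, not decomposed; the exact-match read
  assigner is not a spliced aligner and ignores base qualities; the
  hypergeometric alternative to the binomial enrichment is deliberately
  not the default (the binomial is what reproduces the published table).
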