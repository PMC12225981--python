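# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `te-karyoscan`.

## Data model and coordinates

All genomic intervals are 0-based half-open internally (BED convention);
the readers convert RepeatMasker `.out` rows and GTF records (both
1-based inclusive) at the boundary. Overlap means ≥1 shared bp under the
half-open rule, so abutting intervals do not overlap. Chromosome names
are never normalised: if two inputs share no chromosome name, the overlap
operations raise instead of silently returning zero. Genes must be
stranded because the TSS (interval start on `+`, interval end on `-`)
anchors the upstream regions.

## Subfamily quantification

Per-copy counts are regrouped into per-subfamily counts by summation
through the rosetta copy→subfamily lookup; the operation is purely
additive, so per-sample totals are conserved (a tested invariant). A
built-in exclusion list removes the 24 repeat subfamilies that are not
transposable elements (7SLRNA, 7SK, LSAU, D20S16, REP522, SATR1, SATR2,
ACRO1, ALR/Alpha, BSR/Beta, CER, 6kbHsap, TAR1, SST1, MSR1, SAR, GA-rich,
G-rich, A-rich, HY1, HY3, HY4, HY5, 5S), reducing a 1,270-subfamily
repeat library to 1,246 TE subfamilies. Subfamily names are opaque byte
strings (several contain `/`). Features with zero counts in every sample
are dropped before analysis.

## Normalization

Size factors use the median-of-ratios construction restricted to genes
with positive counts in every sample: each such gene's counts are divided
by the gene's geometric mean across samples (computed in log space for
stability) and a sample's factor is the median of its ratios, with the
midpoint average for even counts taken on the ratio scale. Factors are
estimated from genes only and then applied to genes and TE subfamilies
jointly. Anchoring on genes matters: if TE rows entered the reference, a
genuine genome-wide increase in TE expression would partly be absorbed
into the size factors. Factors are defined up to a common constant;
only ratios between samples are meaningful.

Gene-length offsets (relevant when gene counts are derived from
transcript-level estimates) are out of scope: all inputs are taken as
gene-level counts.

For descriptive statistics and plots only, `remove_batch_effect` fits,
per feature, least squares of `log2(count + 0.5)` on the biological group
(treatment coding) plus batch (sum-to-zero coding) and subtracts the
batch component. Keeping the biological group in the fit prevents
unbalanced batches from absorbing real group differences; sum-to-zero
coding means adjusted values land on the across-batch midpoint. A batch
factor perfectly confounded with the biological group is rejected.
Inferential models never use this adjustment — they carry batch as a
covariate instead.

## Global TE proportion

Per sample: the sum of normalized counts over a chosen set of TE
subfamilies divided by the total normalized counts over genes plus *all*
TE subfamilies. Because the denominator is fixed, subset proportions are
additive and sum to the all-TE proportion. Subsets come from the rosetta
lineage column (LTR, SINE, LINE, SVA, DNA) and from editable name-prefix
rules for the transcriptionally active groups (HERVK including LTR5*,
AluS, AluY, L1, SVA).

Group comparisons use the two-sided Wilcoxon rank-sum test for every
unordered pair of karyotypes — exact enumeration when both groups have ≤8
samples and no ties, the tie-corrected normal approximation otherwise —
and the Kruskal–Wallis test across groups (p = 1 with a log message when
every value is identical). Raw pairwise p-values are reported without
multiplicity correction across the karyotype pairs; callers can apply
`bh_adjust` if they prefer. Directional claims should be read off the
group medians, not one-sided tests. For designs with age structure,
`adjusted_sex_effect_test` fits `value ~ sex + age_group` by least
squares and reports the two-sided t-test on the sex coefficient; with a
constant age group this reduces exactly to the two-sample t-test. Age
groups are decade bins [20–30], ]30–40], …, ]60–70]; the boundary age 30
belongs to the first bin.

`flag_aneuploidy_suspects` implements the marker-gene screen for
cryptic sex-chromosome aneuploidy: a male is flagged when the
X-inactivation marker (XIST) exceeds a configurable fraction (default
0.5) of the female median while the Y marker (USP9Y) is still expressed.
Females are never flagged by this rule.

## Differential expression

Each feature is fit with a negative-binomial GLM on the raw counts:
log link, the log gene-derived size factor as offset, and a design of a
primary factor (karyotype, reference level XX) plus categorical
covariates (batch by default) and optional pairwise interactions.
Choices, in order of consequence:

- **Dispersion** is estimated per feature by maximising the Cox–Reid
  adjusted profile likelihood (the −½ log det(XᵀWX) adjustment removes
  most of the downward bias of the plain MLE at small n), over
  α ∈ [1e−8, 30] on the log scale with a bounded scalar search; the
  floor is 1e−8. No information is shared across features — no empirical
  Bayes shrinkage — which is the main fidelity gap relative to
  shrinkage-based DE tools and the reason their numeric output is not
  reproduced here. Accuracy is instead established by simulation
  calibration and recovery.
- **Wald contrasts** between primary-factor levels are referred to a t
  distribution with residual degrees of freedom (n − p). With a plug-in
  dispersion the usual normal reference is anti-conservative at cohort
  sizes like 6 + 6 (measured type-I ≈ 0.08–0.10 at α = 0.05); the t
  reference restores ≈ 0.05, as verified by the null-calibration test.
  The reported log2FC is the contrast estimate × log2 e.
- **The likelihood-ratio test** compares the full design with the design
  without the primary factor (χ², df = levels − 1), both at the
  full-model dispersion — the omnibus "does karyotype matter at all"
  test used to rank subfamilies.
- **Multiplicity**: BH step-up per test family (one family per contrast,
  one for the LR test); NaN p-values pass through and do not count
  toward m. Features with total count < 10 across samples are excluded
  from testing (a concrete reproducible stand-in for tool-specific
  low-count heuristics). Non-converging features are reported with NaN
  p-values and a logged diagnostic rather than aborting the run.

The per-contrast summary `median_log2fc_test` asks whether TE expression
shifts *overall* between two karyotypes: the two-sided Wilcoxon
signed-rank test of all subfamily log2FCs against zero (zeros dropped,
≥5 finite values required). `rank_top_features` orders by LR adjusted p
with deterministic tie-breaking (raw p, then feature id).

## Y-chromosome enrichment

Expected proportion: length(Y)/length(genome) with the kb defaults
57,200 / 3,088,200 = 1.85% (printed kb values as shipped; replaceable via
`ChromLengths`). Per subfamily with ≥1 annotated copy, the number of
copies on the Y out of the total is tested against that expectation with
the two-sided exact binomial test, minimum-likelihood ("minlike")
two-sided method — the sum of probabilities of all outcomes no more
likely than the observed one — with the tail-doubling alternative behind
a flag. p-values are BH-adjusted across all tested subfamilies, and
subfamilies are classified enriched (padj < α and observed > expected),
depleted (padj < α and observed < expected), or neither; the three
predicate groups (no Y copies, no X copies, neither) are membership
facts independent of the test and may overlap the first three.
`enriched_share_test` then asks whether a selected set of subfamilies
(e.g. the most significantly karyotype-dependent ones) contains more
Y-enriched members than the background share predicts (one-sided exact
binomial).

Copy-weighted genome fractions were deliberately rejected in favour of
length fractions for the expectation, and no mappability correction is
applied.

## Region enrichment

Upstream regions span `span` bp (default 3,000) upstream of the TSS,
clipped at position 0 and, when chromosome lengths are supplied, at the
chromosome end; adjacent genes' regions are *not* merged — each gene
contributes one region. The overlap statistic is count-once: the number
of regions intersecting ≥1 TE copy (strand ignored), computed with
sorted-boundary arrays per chromosome (#starts < region end − #ends ≤
region start), which a brute-force all-pairs oracle verifies in the
tests.

The permutation test draws |selected| regions from the all-genes
universe without replacement per permutation (the selected regions remain
in the universe), recomputes the statistic — implemented as a sum over a
precomputed per-region hit indicator, which is exactly equivalent and
O(1) per permutation — and reports the empirical one-sided p with +1
smoothing, p = (1 + #{null ≥ observed})/(n_perm + 1) (or ≤ for the lower
side). The side is chosen automatically by comparing the observed count
to the null mean. This auto-sidedness is the published behaviour of the
region-permutation framework it mirrors, and it mildly inflates the null
rejection rate (roughly α → 2α worst case); the calibration test bounds
the measured rate in [0.02, 0.09] at α = 0.05 accordingly. Results are
bit-reproducible given the seed, and p ≥ 1/(n_perm + 1) always.

The intragenic test is strand-aware (a gene contains a copy only if the
intervals overlap and strands match; a flag disables this): the share of
selected genes containing ≥1 copy from the selected subfamilies is
compared to the same share over all genes with a two-sided exact binomial
test. When no gene at all contains a copy the test is skipped with an
explicit status rather than returning a degenerate p.

## Synthetic data

The generator emulates a blood-RNA-seq aneuploidy study; its defaults are
the study conditions under which the acceptance checks run.

- **Cohort**: 6 XX, 6 XY, 8 XXY, 4 XYY — the real cohort sizes, so the
  statistical behaviour at those n (e.g. underpowered XYY contrasts) is
  visible.
- **Genome**: one autosome plus X and Y with lengths 2,874,960 /
  156,040 / 57,200 kb (coordinates in bp = kb × 1000), giving the Y its
  real 1.85% length share. TE copies (100 subfamilies × 50 copies,
  length 300 bp) are placed proportionally to length, except that a
  fraction (default 0.1) of subfamilies is Y-enriched and places each
  copy on the Y with probability 0.5. Genes (200, 2 kb) are uniform on
  both strands. Subfamily names cycle through class-consistent prefixes
  (HERVK→LTR, AluS/AluY/MIR→SINE, L1/L2→LINE, SVA, hAT/TcMar→DNA) so the
  lineage- and prefix-based subsets are exercised.
- **Counts**: per-copy and per-gene base means are log-normal around 20
  and 2,000 respectively (log-SD 0.6; the gene mean is set so TE reads
  are a realistic ≈20% of the library rather than dominating the toy
  transcriptome). A copy on the Y contributes 0 in XX, its base mean
  with one Y, ×`y_dosage_effect` (default 2.0, a fully active extra Y)
  per additional Y; X copies scale by `x_dosage_effect` (default 1.1,
  an almost fully inactivated extra X) per additional X. Counts are
  NB-distributed (gamma–Poisson) with shared dispersion 0.05, times a
  log-normal library factor (log-SD 0.2) and, for a random half of
  samples ("batch 2"), a per-feature log-normal batch multiplier
  (log-SD 0.1). Ages are uniform on [20, 70].
- **Determinism**: the whole bundle is a pure function of the design,
  seed included; the fixture writer emits BED/GTF/TSV files that
  round-trip through the package's own readers, plus the ground truth as
  JSON and the design as a YAML manifest.

`simulate_de_matrix` is the reduced two-group generator used for DE
calibration and recovery; planted fold changes alternate sign so the
signal does not bias the size factors, as in real data where DE runs in
both directions.

What the generator does *not* emulate: multi-mapping ambiguity and
mappability structure, per-feature dispersion heterogeneity (available
as an option but off by default), gene length bias, correlated
co-expression, X-inactivation escape genes, and cell-type composition.
Passing tests therefore demonstrate that the statistical machinery
recovers planted signals under the stated noise model at the study's
sample sizes — not that any particular biological result holds in real
data. At the default (realistically sparse) genome density, upstream
regions rarely intersect TE copies; the region-enrichment example uses a
1000× denser toy genome for that reason, and the pipeline reports the
degenerate case honestly (observed 0, p = 1).

## Pipeline

`run_pipeline` validates the config (aggregating all problems into one
error), runs quantify → normalize → global statistics → differential
expression → Y enrichment → region enrichment, writes each stage's TSVs
into its own subdirectory, logs row counts per stage so the conservation
invariants are checkable from logs, and emits one `summary.json`
(sorted keys, floats rounded to 10 decimals) that is byte-identical
across reruns of the same config and seeds. A stage failure writes a
`FAILED` marker naming the stage and re-raises. The region stage derives
its gene and subfamily selections from the DE stage at FDR 0.05 and
skips contrasts with empty selections.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
data at the following scales, chosen to make the Monte-Carlo bounds tight
while keeping a full run around a minute: 2,000 features for the NB Wald
null; 400 features with 60 planted fold-change-2 signals (n = 6/6,
dispersion 0.05) for DE sensitivity/FDR; 400 replicate permutation tests
at n_perm = 500 over an 80-region universe for the permutation null;
100 replicate cohorts at the 6/6/8/4 design for the global-TE ordering
rate; and 3 seeded genomes for Y-enrichment recovery.

## Known limitations

- No dispersion shrinkage or outlier handling: per-feature estimates are
  noisy at very small n, mitigated but not eliminated by the Cox–Reid
  adjustment and the t reference.
- The exact rank-sum branch requires both groups ≤8 without ties;
  beyond that the tie-corrected normal approximation is used, which is
  slightly liberal at tiny n with heavy ties.
- Length-share expectations for Y enrichment ignore assembly gaps and
  mappability; enrichment calls on real annotations inherit those
  biases.
- The permutation universe includes the selected regions (standard
  resampling semantics); excluding them would make the test slightly
  more conservative.
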