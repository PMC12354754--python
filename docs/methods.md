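# Methods

This note documents the statistical models, the synthetic-data generators,
the numerical choices, and the limits of what the test suite demonstrates.

## Unique-read quantification

A read in the read table carries a *candidate feature set*: every feature of
the combined gene+HERV reference it aligns to. The quantifier credits a read
to feature *f* only when its candidate set is exactly `{f}`; any read with
two or more candidates is discarded and counted. Ambiguity is defined at the
feature level: a read spanning two features is discarded even if its genomic
position is unique, because its molecule of origin cannot be attributed.
Within a (barcode, feature) pair, duplicate UMIs collapse to one molecule by
exact string identity — no Hamming-distance correction is attempted, which
keeps the operation auditable; upstream UMI correction, where performed,
should be reflected in the table's UMI column.

Removing HERV loci that overlap protein-coding exons (by ≥1 bp, strand-
agnostic) precedes quantification. The rationale is quantification bias: in
3' single-cell chemistry a read inside an exon-overlapping locus is
indistinguishable from host-gene signal regardless of strand. Overlap with
non-coding transcripts does not trigger removal; only protein-coding exons
are considered.

QC gates are strict inequalities (a cell with exactly 500 detected genes is
removed), mitochondrial percentage is computed on raw counts, and the
rare-feature filter (< 3 cells) runs after the cell filter. The
expressed-HERV filter keeps loci with non-zero counts in strictly more than
20 cells; the threshold is configurable.

## Normalization and pseudobulk

Cell-level normalization is `log1p(count * 1e4 / cell_total)`; pseudobulk
aggregates raw UMIs per (individual, cell type), scales each individual to
1e6 within the cell type, then applies log1p. The two scales (1e4 vs 1e6)
are deliberate and independently configurable. Individuals with zero cells
of a type are absent from that type's matrix rather than zero-filled, since
a zero would be an observation, not a missing one.

Highly variable loci are selected by mean-binned dispersion on the expm1
scale: features fall into 20 equal-frequency mean bins; dispersion
(variance/mean) is centered by the bin median and scaled by the bin MAD,
falling back to the bin mean/SD when the MAD is zero. Defaults: normalized
dispersion > 0.5, mean in (0.1, 4). With very few features per bin the
median/MAD statistic degenerates (a bin of three features scores its own
median as zero); callers working at toy scale should reduce `n_bins`.

HERV–gene co-expression is Spearman's rho (mid-rank ties) computed across
individuals of the per-cell-type pseudobulk, not across single cells, which
matches donor-level sample sizes and avoids sparsity artifacts; pairs with a
constant vector yield NaN and are excluded from summaries.

## Cell-type specificity and chromatin enrichment

Markers are one-vs-rest Wilcoxon rank-sum tests at the cell level
(asymptotic, tie-corrected), Bonferroni-corrected over features × groups —
the conservative reading of "Bonferroni-adjusted". A locus is specific when
adjusted p < 1e-5 and log2FC > 2, where the fold change compares expm1 group
means with ε = 1e-9. Groups with fewer than two cells are skipped and
reported.

Chromatin-state enrichment uses the 15-state ChromHMM vocabulary. A feature
is "in state S" when its interval overlaps any S-labeled interval by ≥1 bp
(a fractional-overlap option exists). The 2×2 table is {specific,
non-specific} × {in S, not}, the background being all features that entered
the differential test; two-sided Fisher p-values are BH-corrected across all
cell types × states tested. Enhancers are the merged union of the
"Enhancers" and "Genic enhancers" states; promoters the union of "Active
TSS" and "Flanking Active TSS".

## cis-eQTL mapping

Phenotypes are pseudobulk loci expressed in strictly more than 10% of
individuals of the cell type. Covariates: sex, age, the top 6 genotype
principal-component scores (SVD of the mean-imputed, centered dosage
matrix) and 2 latent expression factors — principal components of the
top-2000 most variable phenotype columns. The latent factors are a PCA
stand-in for PEER-style factor models; at two factors both capture the same
broad variance components. A caveat demonstrated by the test suite: with
only a handful of phenotypes the first expression PC *is* the strongest
genetic effect, so factor correction at toy scale should be disabled
(`n_factors=0`) — the real design fits factors across thousands of loci,
where no single cis effect dominates.

The nominal scan residualizes phenotype and dosage against the covariates
(QR projection) and tests the residual Pearson correlation with
t = r·√(df/(1−r²)), df = n − 2 − #covariates. By Frisch–Waugh–Lovell this
equals the OLS coefficient t-test with covariates included; the suite checks
agreement with `statsmodels` OLS to six significant digits. Variants
monomorphic in the analysis sample are skipped; missing dosages are
mean-imputed per variant. The cis window is |pos − TSS| ≤ 1 Mb, with the
HERV TSS the strand-aware 5' end of the locus.

The permutation pass permutes phenotype values across individuals, keeping
genotypes and covariates fixed, and re-residualizes the permuted phenotype —
the standard phenotype-permutation scheme of the reference cis-QTL tools.
Because p is monotone in |r| at fixed df, the per-permutation minimum p is
obtained from the maximum |correlation|, making the pass a single matrix
product per phenotype. The empirical p is `(1 + #{perm ≤ obs})/(1 + N)`;
a Beta(a, b) distribution is fitted to the permutation minima by maximum
likelihood (method-of-moments start and fallback, flagged in the output),
and `p_beta` evaluates its CDF at the observed minimum. No
degrees-of-freedom recalibration of the nominal p precedes the fit — a
documented simplification. BH across phenotypes within a cell type gives
q-values (Storey's estimator was deliberately not used: BH is deterministic
and tuning-free).

Conditionally independent signals: the q < 0.05 boundary is propagated to a
global `p_beta` cutoff (midpoint between the largest significant and
smallest non-significant `p_beta`), mapped through each phenotype's Beta CDF
to a per-phenotype nominal threshold. Forward rounds add the best cis
variant while it beats the threshold, conditioning on all accepted dosages;
candidates with dosage r² > 0.95 to an accepted variant are rejected and
logged; the backward pass keeps each accepted variant only if it stays
below threshold conditioned on all the others. Ties in p break by larger
|t|, then smaller position.

## Matched-null eSNP enrichment

For each eSNP, up to 100 variants are sampled uniformly without replacement
from the pool of variants matching on |distance to nearest phenotype TSS|
within 2.5 kb and MAF within 2%, excluding the eSNP itself and any variant
nominally associated (p ≤ 0.05) with any phenotype. "Distance to TSS" is
deliberately the distance to the *nearest* phenotype TSS rather than to a
specific target: the matching is about regulatory context. Pools are reused
across eSNPs; within an eSNP sampling is without replacement. Draws that
fall below 20 matched variants drop the eSNP (threshold configurable).
Enrichment per category is the ratio of hit rates (eSNP vs pooled null) with
a two-sided Fisher test and BH-FDR at 5%.

## SMR, HEIDI, colocalization

SMR uses the exposure's most significant cis variant as the single
instrument (required p < 5e-8; if that variant is absent from the outcome,
the next-best sub-threshold variant is used). At the instrument,
b_xy = β_out/β_exp and T_SMR = z_exp²z_out²/(z_exp² + z_out²) is referred to
χ²(1); se_xy = |b_xy|/√T_SMR. Alleles are harmonized before testing:
outcome effects are flipped where the allele pair is swapped, and
palindromic A/T, C/G variants are dropped (frequency is not trusted to
resolve them).

HEIDI asks whether b_xy is constant across SNPs linked to the instrument —
the signature of one shared causal variant — or heterogeneous, the signature
of linkage between distinct causal variants. Eligible SNPs have exposure
p < 1.57e-3 (χ² > 10) and r² with the instrument in [0.05, 0.9], capped at
the 20 strongest; these eligibility defaults are the method's published
ones, since only the p_HEIDI cutoff itself (0.01) is fixed by the analysis
design. With fewer than 3 eligible SNPs the association is emitted flagged
"untested" rather than silently kept or dropped. The covariance of
d_i = b_xy(i) − b_xy(top) follows from the delta method using the LD
correlations and both z-vectors (exposure and outcome samples independent);
T = Σ(d_i/sd_i)² is a correlated quadratic form whose p-value comes from
Satterthwaite moment matching by default, with the exact Imhof integral
behind a flag for validation. LD is taken from in-sample dosage
correlations; a reference-panel matrix is accepted anywhere an LD matrix is.

Colocalization follows the standard five-hypothesis ABF formulation:
per-variant Wakefield log-ABFs from (β, se) with prior effect s.d. 0.15
(quantitative) or 0.2 (case-control), hypothesis sums in log space with
priors p1 = p2 = 1e-4, p12 = 1e-5, at least 10 shared harmonized variants.
The screening policy Bonferroni-corrects T_SMR p-values within (cell type,
association type); significant means q < 0.05 *and* p_HEIDI > 0.01. The
mediation step is a pure set intersection: (HERV, gene, disease, cell type)
triads whose HERV–gene, HERV–disease and gene–disease associations are each
significant — no re-testing.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (config, seed); child seeds derive from
the global seed by CRC hashing of the operation name, so outputs are
byte-identical across runs and machine-readable truth tables accompany every
planted object.

- **Annotation**: genes on a fixed grid (20 kb bodies, three 1 kb exons),
  HERV loci (400 bp) placed in four strata — exon-overlapping (exact count
  = round(fraction × n)), intronic sense, intronic antisense, intergenic —
  with the non-exonic remainder split evenly, a choice the generator owns.
- **Reads**: per-(cell, feature) molecule counts are Poisson around
  cell-type-structured log-normal rates; each molecule yields one read; a
  configurable fraction acquires a second candidate feature. Default depth
  is 500 UMIs/cell — an arbitrary desk-scale value, as no per-cell depth
  distribution was adopted from any cohort. Reads carry no sequence;
  ambient RNA, doublets and barcode errors are not modeled.
- **Genotypes**: block-equicorrelated latent Gaussians thresholded at
  Hardy–Weinberg quantiles; PSD by construction, zero LD across blocks, no
  population structure beyond the blocks. The latent-to-dosage correlation
  mapping is declared by a seeded Monte-Carlo helper (n = 200,000).
- **Phenotypes**: planted effects are per *standardized* dosage
  (y = β·g_std + covariates + N(0, σ)), applied only in the named cell
  type; the scan reports β per raw allele, so effect-recovery comparisons
  rescale by the sample dosage SD.
- **Summary statistics**: z ~ MVN(Rλ, R) with the non-centrality λ at the
  causal index; β = z·se with se = 1/√(2·maf·(1−maf)·n). Defaults: λ = 9
  for the exposure (a strong cis-eQTL instrument) and λ = 8 for the outcome
  (a genome-wide-significant GWAS locus). GWAS are simulated at summary
  level only — individual-level disease data never exist.
- **Chromatin**: 1 kb bins with a mostly quiescent background (10% active),
  relabeled to enhancer/promoter states over a configurable fraction
  (default 0.8) of each cell type's planted specific loci, in that cell
  type's track only.

Passing tests on these generators demonstrate the *statistical machinery* —
calibration of permutation p-values under Gaussian and heavy-tailed noise,
recovery of planted effects at stated power, HEIDI's shared-vs-linkage
discrimination (measured at the default non-centralities: ~1% vs ~64%
rejection), matched-null calibration — not robustness to real-data
pathologies such as ambient contamination, cell-type misassignment,
population stratification, or fine-scale LD.

## Problem sizes used by the checks

The acceptance suite runs the calibration check at 200 null phenotypes × 50
cis variants × 100 individuals × 1000 permutations; effect recovery over 100
seeds at n = 200; the conditional scan over 50 seeds at n = 300 with
12-phenotype panels and 250 permutations; HEIDI discrimination over 200
seeded draws per scenario; and the end-to-end demo at 3 cell types, 80
individuals, ~550 cells, 1000 permutations. The demo config widens the
matched-null tolerances (100 kb / 10% MAF) because a 2 Mb genome with a few
hundred variants cannot satisfy 2.5 kb / 2% matching; every override is
echoed into the run manifest.

## Known limitations

- PEER is approximated by PCA factors; divergence is possible when latent
  confounders are non-Gaussian or sparse.
- The Beta fit is applied to raw permutation minima without the
  degrees-of-freedom recalibration some reference implementations apply;
  empirical and Beta p-values agree to Spearman ≥ 0.99 in the suite, but
  extreme tails beyond the permutation floor rely on the Beta extrapolation.
- The conditional pass's threshold propagation follows the reference tools'
  midpoint convention; other conventions (e.g. fixed nominal thresholds)
  would change borderline calls.
- UMI collapse is exact-match only.
- `coloc` assumes a single causal variant per trait per region, as the ABF
  formulation requires.
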