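# Methods

`autozyg` implements the downstream homozygosity analysis of a genotyped
case-control cohort: runs-of-homozygosity (ROH) detection, SNP-level
homozygosity association, ROH burden and consensus regions, genomic
inbreeding coefficients, and SNP-based heritability. This note records the
models, the parameter choices, and the design decisions that were genuinely
open.

## ROH detection

ROHs are called with the classical SNP-count sliding-window scheme of
array-era callers. Windows of `window_snp = 50` SNPs slide along each
chromosome; a window is *homozygous* when it contains at most `window_het`
heterozygous and at most `window_missing = 5` missing calls. Each SNP
receives the fraction of overlapping homozygous windows, and SNPs with
fraction > `window_threshold = 0.05` become run cores. We deliberately set
`window_het = 0` (no heterozygote tolerated anywhere), which makes a
heterozygous call a hard segment terminator.

A design choice worth spelling out: the literal per-SNP window-fraction rule
trims the edges of a homozygous tract, because the first and last SNPs of a
run are covered by very few fully-homozygous windows. We instead treat the
eligible-SNP runs as *cores* and extend them outward over consecutive
non-heterozygous calls until a heterozygous call or the chromosome end. With
the defaults (`min_snp = 75 > window_snp = 50`) every zero-heterozygote run
long enough to be reportable contains a core, so the emitted segments
coincide exactly with the maximal zero-heterozygote runs passing the
filters — which is what the brute-force oracle in the test suite checks.

Candidates are split at inter-SNP gaps above `max_gap_kb = 1000`, and kept
when they span at least `min_snp = 75` SNPs and `min_kb = 1000` kb at a
density of at most 50 kb/SNP. Segment length is `end − start + 1` bp
(1-based, inclusive ends). Missing calls never terminate a run; they only
count against `window_missing`.

The minimum run length is calibrated per cohort: `min_roh_snps(h, S, N, α)`
returns the smallest `L` with `(1−h)^L · S · N ≤ α`, i.e. fewer than `α`
expected chance runs of length `L` among `N` individuals typed at `S` SNPs.
At `h = 0.35, S = 536270, N = 1080, α = 0.05` this gives `L = 54` (the value
53 circulating for these arguments does not satisfy the inequality at
exactly h = 0.35; it corresponds to an unrounded heterozygosity slightly
above 0.35 — both behaviours are asserted in tests). Because genotyped SNPs
are not independent, `count_tag_groups` (greedy r² > 0.8 tagging within
250-kb windows) estimates the information reduction and `effective_min_snp`
inflates `L` accordingly; the pipeline default is the pinned 75.

## SNP-level homozygosity association

Per SNP the two homozygote classes are pooled (hom vs het) and the
case/control × hom/het table is tested with a Pearson chi-square, **no**
continuity correction (required to reproduce the published statistics), plus
a one-sided Fisher's exact test in the direction "more homozygous cases".
FDR control is Benjamini-Hochberg step-up; `m_total` may exceed the number
of p-values supplied so that q-values for a reported top list can be
computed against the full array size. The Fisher point estimate is the
sample odds ratio `ad/bc`, not the conditional MLE.

## Burden, F_ROH and consensus regions

Per individual we report ROH count, total and mean length over segments
≥ 1000 kb, and `F_ROH = Σ L_ROH / L_AUTO` with
`L_AUTO = 2,677,608,286 bp` (array-era SNP-mappable autosomal genome,
centromeres excluded; override it for synthetic maps). ROHs are further
split at 1500 kb into short/long classes, so
`F_ROH = F_ROH,short + F_ROH,long` by construction. Burden contrasts use
pooled-variance Student t-tests; categorical odds ratios use pooled-sample
quartile cutoffs (right-closed, ties to the lower class) with the lowest
class as reference and Woolf (log-scale Wald) confidence intervals; zero
cells receive the Haldane-Anscombe 0.5 adjustment and are flagged.

Overlapping segments are pooled per chromosome by single-linkage
(transitive) closure of the interval-overlap relation. A pool's consensus is
the strict intersection (max start, min end); under transitive pooling this
can be empty, in which case the pool is flagged and excluded from the
recurrent list rather than split. Recurrent ROHs are pools with ≥ 6 distinct
carriers ("more than five") and a consensus of ≥ 500 kb. Carrier status is
tested with the uncorrected 2×2 chi-square; the per-SNP homozygote
proportions inside a consensus region are compared between cases and
controls with an *unpaired* one-tailed Student t (SNPs as the unit of
observation; pairing is a defensible alternative but was not chosen).

## Genomic inbreeding

Three per-individual estimators, averaged over non-missing, polymorphic
SNPs with allele frequency p taken from the full sample (cases + controls —
matching the default of standard tooling; a `freq` override exists):

* F1 (variance of additive genotypes): `mean[(x−2p)²/(2pq)] − 1`
* F2 (excess homozygosity): `mean[1 − x(2−x)/(2pq)]`
* F3 (uniting-gamete correlation): `mean[(x² − (1+2p)x + 2p²)/(2pq)]`

Per-SNP ratios are averaged (a `ratio_of_sums` mode is provided). All three
are unbiased for F under HWE-with-inbreeding genotype frequencies; with
sample-estimated frequencies a small O(1/n) finite-sample bias remains.
F3 equals the GRM diagonal minus one by shared formula, and the genome-wide
value equals the SNP-count-weighted mean of per-chromosome values because
the frequencies are shared. Case-control contrasts use Student t-tests per
chromosome and estimator; the covariate-adjusted model is a logistic
regression of case status on F plus sex/PCs/missingness, with Wald
inference.

## GRM, REML and the liability scale

The GRM uses the standard allele-frequency-standardised form with
pairwise-complete normalisation under missingness and the F3-based
diagonal. Note that with sample-frequency centring the mean off-diagonal of
an unrelated cohort is −1/(n−1), not 0. PCA takes the top-k eigenpairs with
a deterministic sign convention.

Variance components are estimated by average-information REML: one EM step
first, then AI steps with an EM fallback whenever an AI step fails or
decreases the restricted likelihood (EM steps are guaranteed ascent, which
the trajectory test asserts); components are floored at `1e-6 · var(y)`;
convergence at `|Δ log L| < 1e-8` or 100 iterations. The SE of h² comes
from the inverse AI matrix by the delta method. A binary phenotype is fitted
on the observed 0-1 scale and transformed to the liability scale as
`h_l² = h_o² · K(1−K)/z²`, `z = φ(Φ⁻¹(1−K))`, with default prevalence
`K = 0.006`. The transform is implemented exactly in this form; an optional
`ascertained_proportion` argument multiplies in the case-control
ascertainment factor `K(1−K)/(P(1−P))` for users who need it.

## Synthetic cohorts

The simulator emulates a filtered GWAS array at desk scale, defaulting to
200 cases + 200 controls × 20,000 SNPs on 4 chromosomes (exponential
inter-SNP gaps, mean 3 kb):

* **Frequencies/LD.** Each LD block (20 SNPs by default) carries a pool of
  20 founder haplotypes with one block-level frequency drawn from
  `maf_range = (0.05, 0.45)` — chosen so mean heterozygosity lands at ~35%,
  typical of a filtered array. The pool's allele count is pinned at
  `round(H·p)` and individuals draw two haplotype indices i.i.d. *with
  replacement*, so single-SNP genotypes are exactly Binomial(2, f) and the
  2pq-heterozygosity and estimator-unbiasedness checks hold without
  finite-pool corrections. Adjacent SNPs share carrier haplotypes with
  probability 0.7, giving blocky within-block r² and zero cross-block LD.
* **Inbreeding.** An individual with coefficient F receives autozygous
  tracts from a stationary alternating-renewal process (exponential
  autozygous sojourns of mean 2,500 kb, non-autozygous of mean
  2,500·(1−F)/F kb), so the probability that any position is autozygous is
  exactly F; inside a tract one haplotype is copied over both. This makes
  both the SNP-wise estimators (per-SNP autozygosity probability F) and
  F_ROH (contiguous ≥ 1 Mb tracts) respond to F.
* **Phenotypes.** Logistic recessive model: only allele-b homozygotes at
  configured risk loci shift the log-odds; individuals are drawn in batches
  from one founder panel until the case/control quotas fill (case-control
  ascertainment). The default baseline prevalence is 0.1 — an ascertainment
  profile that keeps desk-scale cohorts drawable; the liability transform's
  K = 0.006 default is independent of it.
* **Planted ROHs** force zero-heterozygote tracts at fixed coordinates with
  per-phenotype carrier fractions, recording truth intervals.

What the simulator does *not* model: coalescent LD decay, recombination
maps, allele-frequency spectra, genotyping error, population structure
(except through the two-subpopulation constructions used directly in
tests). Passing tests therefore demonstrate correctness of the statistical
machinery under a clean generative model, not robustness to real-data
artefacts.

## Calibration checks and problem sizes

The test suite verifies, at sizes chosen to keep the default run in tens of
seconds: exact agreement of the ROH caller with a brute-force maximal-run
oracle on datasets ≤ 200 SNPs; recovery of F ∈ {0, 0.05, 0.1} by all three
estimators within 3 empirical SEs at n = 500, m = 5,000; GREML recovery of
h² = 0.5 at n = 500, m = 2,000 with the reported-SE 95% interval covering
the truth in ≥ 90% of 50 replicates; the liability multiplier at K = 0.006
against an independent high-precision evaluation (Φ/φ via `mpmath`); and
the homozygosity scan's type-I error within 3 binomial SEs of 0.05 under a
null simulation (independent SNPs, so the binomial SE applies). Degenerate
inputs (zero marginals, zero variances, monomorphic SNPs, empty consensus
intersections, perfect separation) are flagged or raised explicitly rather
than silently dropped.

## Known limitations

* The windowed caller equals the maximal-run oracle only for the
  het-intolerant configuration (`window_het = 0`); with het-tolerant
  windows the eligible runs are reported as-is, without extension.
* REML on a 0-1 phenotype treats the trait as quantitative; no exact
  binary-trait likelihood is provided.
* The greedy tag-group count is seed-anchored (left-to-right) and is a
  proxy, not a full LD-pruning implementation.
* Quartile burden cutoffs are computed on the pooled distribution; heavily
  tied counts can produce unequal groups, which are flagged downstream.
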