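# Methods

`crosscoloc` asks one question of a pair of GWAS summary-statistics tables:
do the two traits share genetic susceptibility, and where? It answers at
three resolutions — genome-wide (an excess of jointly associated SNPs),
regional (clusters of associated SNPs that overlap or sit near each other),
and per-variant (Bayesian colocalization) — and then characterizes the
implicated variants against epigenomic annotations. Everything operates on
per-variant `beta`, `se`, `p`, MAF and imputation info; no individual-level
data is required beyond a genotype reference panel for LD.

## Input handling and harmonization

Variants are QC-filtered with strict thresholds MAF > 0.01 and
info > 0.8 — the conventional post-imputation cuts. Effect alleles of the
second trait are aligned to the first by exact match (keep sign), swap
(negate `beta`), or strand complement of either pattern for non-palindromic
SNPs. Palindromic (A/T, C/G) SNPs whose alleles do not match exactly are
dropped as unresolvable without allele-frequency heuristics, which we
deliberately avoid: the cost is a small loss of variants; the benefit is
that no sign is ever guessed. P-values of exactly zero are clamped to the
smallest positive double because several downstream statistics take logs.
GWAS coordinates are 1-based inclusive; BED tracks are 0-based half-open
and converted at the boundary.

## LD, pruning and D′

r² is the squared Pearson correlation of dosage vectors in the reference
panel. D′ requires haplotype frequencies, which unphased dosages do not
expose directly; a standard two-locus EM (50 iterations or log-likelihood
change < 1e-10) resolves the double-heterozygote ambiguity, after rounding
dosages to genotypes.

Pruning to "approximate linkage equilibrium" uses the familiar windowed
greedy scheme: r² threshold 0.2, 500-kb windows, sliding by 20 retained
variants. Within a window, the first violating pair (position order) loses
its smaller-MAF member; MAF ties drop the variant at the larger position,
making the procedure fully deterministic. Because a stepped window cannot
certify pairs that straddle window boundaries, a final exhaustive sweep
removes any surviving pair within 500 kb at r² ≥ 0.2 — the output therefore
satisfies the advertised guarantee exactly, and the test suite re-verifies
it with an independent pairwise scan.

## Genome-wide shared association

On the pruned SNPs, each p-value cutoff t ∈ {0.0001, 0.0005, 0.001, 0.005,
0.01, 0.05} yields a 2×2 table: below t in both traits (a), in one only
(b, c), in neither (d). Enrichment of the both-low cell is scored by the
one-sided Fisher exact test, P(X ≥ a) for hypergeometric X given the
margins. The survival-function shortcut in scipy loses all relative
accuracy below ~1e-8, so tails under 1e-6 are recomputed by summing the
log-pmf over the remaining support — cheap, because small tails have short
supports. The odds ratio is the plain cross-product a·d/(b·c), reported as
0 when a·d = 0, infinite when only b·c = 0.

The Fisher test assumes independent SNPs even after pruning; the
permutation test drops that assumption. Trait B's p-values are reassigned
across the pruned SNPs — by permutation (default; preserves the marginal
p-value set exactly) or bootstrap (`resample="with"`) — and the empirical p
is the plain proportion of replicates whose both-low count reaches the
observed one (an add-one estimator is available via `add_one=True`). Which
trait is permuted is immaterial under the null; the suite checks the two
choices agree in distribution.

## Associated regions

Two region flavours:

* **shared** — SNPs with p < 1e-3 in *both* traits;
* **distinct** — per-trait SNPs with p < 1e-5 (roughly one false positive
  per GWAS).

Qualifying SNPs on a chromosome are chained by single linkage: the chain
continues while the gap between adjacent qualifying SNPs is under 100 kb,
and a chain must contain at least 10 SNPs. Note the *span* of a region can
greatly exceed 100 kb — the rule constrains adjacent gaps, not total size;
this is the reading consistent with reporting regions several hundred kb
wide. The lead SNP is the minimum-p member (ties: smaller position).

Direction of effect of a shared region is the sign pattern of
sign(beta_a)·sign(beta_b) over its members: `same` if all positive,
`opposite` if all negative, `mixed` otherwise; zero effect estimates are
excluded with a warning.

Distinct regions of the two traits are paired when their lead SNPs lie on
the same chromosome strictly less than 250 kb apart, annotated with D′ and
r² between the leads. Significance of the observed pair count comes from a
positional null: each trait-A region is relocated, size fixed, to a uniform
start within the SNP-covered territory, with the chromosome redrawn
proportionally to territory length (`within_chrom=True` keeps it). The
empirical p is again the plain proportion of replicates reaching the
observed count.

## Bayesian colocalization

Each variant gets a Wakefield approximate Bayes factor per trait: with
shrinkage r = w²/(w² + se²) and z = beta/se,

    log ABF = ½·log(1 − r) + z²·r/2,

under a N(0, w²) effect prior on the log-odds scale, w = 0.2 by default.
Assuming at most one causal variant per trait in a region, the five
hypotheses (no association; trait A only; trait B only; two distinct
variants; one shared variant) accumulate the configuration sums S1 = Σᵢ
ABFᴬᵢ, S2 = Σⱼ ABFᴮⱼ, S12 = Σᵢ ABFᴬᵢ·ABFᴮᵢ, with H3's sum over ordered
distinct pairs equal to S1·S2 − S12. Posteriors weight these by per-SNP
priors p1 = p2 = 1e-4 and p12 = 1e-5 and normalize via log-sum-exp. The
hierarchical alternative — estimating the priors genome-wide by EM — is
out of scope; the fixed-prior enumeration spans the identical hypothesis
space and is the form whose posteriors the test suite can verify against
exhaustive configuration enumeration to 1e-9. Region pairs are colocalized
over the union span of the two regions plus a 50-kb margin. A posterior
above 0.9 is the conventional decision threshold.

## Variant-set enrichment

The associated variant set (AVS) is the cross-associated tag SNPs plus each
tag's LD block (pool variants with r² ≥ 0.8 on the same chromosome).
Matched random variant sets (MRVS) preserve LD structure: every tag is
replaced by a pool variant whose own block size matches, with a ±1, ±2, …
tolerance ladder guaranteeing termination on small pools. Within one
replicate the matched tags of a size group are drawn *without* replacement,
mirroring the fact that the AVS is a set of distinct tags — with-replacement
draws would inflate the null variance through duplicates. A track's score
is the number of tags whose block touches an interval; significance is the
add-one empirical p (1 + #{null ≥ obs})/(n_sets + 1), Bonferroni-corrected
across tracks. We report this exact empirical p rather than a Box–Cox
normalized score: at a few hundred null sets the empirical tail needs no
distributional assumption, and a z-score is still emitted for plotting.

## Synthetic data

The generator works directly in summary-statistics space. An LD block is an
AR(1) correlation matrix R with R[i,j] = ρ^|i−j|; the observed z-vector per
trait is z = R·λ + ε with ε ~ MVN(0, R) and λ the planted non-centralities
(expected z at causal variants, sign = direction of effect). This is the
standard summary-statistics model: it gives exact control of signal
strength, LD and the four architectures (shared same/opposite sign,
distinct nearby causals, single-trait, null) without simulating phenotypes.
Statistics are reassembled backwards: p = 2Φ(−|z|),
se = 1/√(2·n_eff·maf·(1−maf)) (binary-trait approximation, n_eff = 5000 by
default), beta = z·se, maf ~ U(0.05, 0.5), info ~ U(0.85, 1).

The reference panel (n = 400 by default) is drawn from the same R through a
Gaussian copula: two latent haplotypes per individual are thresholded at
the allele-frequency quantile and summed to dosages. Thresholding
attenuates correlations relative to R — panel r² is realistic but not equal
to the latent ρ², which is why tests that need a specific panel r² build
genotypes directly.

The default desk genome is 4 chromosomes × 25 blocks × 40 SNPs (4000
variants) at 5-kb spacing with 200-kb inter-block gaps, ρ = 0.9. ρ = 0.9–
0.95 (rather than looser LD) is needed for a planted z ≈ 8 signal to carry
≥ 10 SNPs past the 1e-3/1e-5 region thresholds, emulating densely imputed
coverage around a hit; with ρ = 0.8 a signal's footprint is only ~9 SNPs
wide and region detection is not reliable — a property of the thresholds,
not a tuning knob. What the generator does *not* model: realistic human LD
maps, case-control ascertainment, imputation error beyond the info column,
allele-frequency-dependent architectures. Passing tests therefore
demonstrate internal statistical correctness of the methods, not
performance on real cohorts.

## Calibration study designs

Three suite-level calibrations deserve explanation because their study
conditions matter:

* **Permutation type-I error.** A pure-null genome gives an expected
  both-low count of ~0.4 at t = 0.01, so the count is so discrete that
  P(p < 0.05) ≈ 0.008 — the test would look ultra-conservative for a purely
  arithmetic reason. The calibration genome instead plants independent
  polygenic effects (per-variant ncp ~ N(0,1), independent between traits):
  still no shared basis, but marginal signal inflates the both-low count to
  a smooth distribution, and the observed rejection rate at 0.05 sits in
  [0.02, 0.09] over 200 genomes.
* **Reshuffle null.** Regions are planted at SNP positions; the null
  relocates them continuously over the SNP territory. With large gaps
  between blocks the two mechanisms disagree (block-grid placement offers
  fewer close-pair opportunities than continuous relocation) and the
  empirical p is visibly conservative; on a contiguous-coverage genome the
  mechanisms align and p is approximately uniform (KS).
* **VSE null.** The empirical p is a discrete rank statistic; approximate
  uniformity requires the overlap score to take many values, hence a large
  LD-free pool (2000 SNPs), several hundred tags and mid-range track
  coverage. With small scores the add-one-with-ties estimator is visibly
  super-uniform — expected, and preferable to under-coverage.

## Numerical and degenerate-input choices

* Fisher tails < 1e-6: direct log-space summation (see above); the empty
  table returns p = 1.
* Coloc H3 term uses log1p(−exp(S12 − S1 − S2)) with clamping against
  roundoff; regions need ≥ 2 variants (H3 undefined otherwise).
* AR(1) Cholesky gets a 1e-10 jitter only if roundoff breaks positive
  definiteness near ρ → 1.
* Monomorphic reference columns are fatal in r²/D′; the generator inserts a
  single heterozygote if a simulated panel column comes out constant.
* Summary statistics are written with 17 significant digits and read with
  round-trip float parsing, so write→read→write is byte-identical.
* Lead-SNP and pruning tie-breaks are positional, making every pipeline
  stage deterministic for a fixed seed.

## Problem sizes used by tests and the acceptance script

Monte-Carlo suites use 100–200 replicate genomes of 40–4000 variants each,
1000 permutation replicates, 500 reshuffle replicates and 200–500 matched
null sets — sizes at which every statistical bound above is stable across
seed choices while the whole suite completes on a laptop-class single core.
The acceptance script reports each quantity with the replication count it
used.

## Known limitations

* The one-causal-per-trait assumption of the colocalization model is
  violated by allelic heterogeneity; posteriors then favor H3/H4
  unpredictably, as with any single-causal colocalization method.
* Palindromic-SNP dropping loses a few percent of variants; frequency-based
  rescue is deliberately not implemented.
* D′ from unphased dosages is an EM estimate; for very small panels or
  near-monomorphic SNPs it is noisy, and values are clipped to [0, 1].
* The reshuffle null relocates only trait-A regions (a documented
  asymmetry; the pair count itself is symmetric).
* Multi-trait (> 2) colocalization and genome-wide prior estimation are out
  of scope.
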