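# Methods

`rnadx` implements three complementary screens for pathogenic regulatory
defects in a rare-disease RNA-seq cohort — aberrant expression, aberrant
splicing and mono-allelic expression (MAE) — together with a synthetic
cohort generator that provides ground truth for every stage. This note
records the models, the numerical choices, and what the synthetic
validation does and does not establish.

## Aberrant expression

**Model.** Read counts of gene *i* in sample *j* follow a negative
binomial, K_ij ~ NB(mu_ij, alpha_i) with Var = mu + alpha mu^2,
log mu_ij = log s_j + x_j' beta_i, where s_j are DESeq-style
median-of-ratios size factors (computed after the expressed-gene
filter), and x_j carries an intercept, the patient-of-interest indicator
(1 for all replicates of the tested patient) and dummy-coded batch, sex
and biopsy-site covariates. The reference level of each covariate is its
lexicographically smallest value, so the coding is stable; a covariate
level confounded with the patient indicator is dropped with a warning.
Genes whose 95th percentile of counts across samples (linear
interpolation) is below 10 reads are considered not expressed and
removed; genes exactly at 10 are kept.

**Fitting.** The one-vs-rest scan fits on the order of
n_samples x n_genes models, so the IRLS loop and the dispersion search
are batched across genes in numpy rather than fitted gene by gene.
Dispersion is estimated per gene by maximising the Cox-Reid adjusted
profile likelihood (ternary search on log10 alpha over [1e-8, 1e2], 80
iterations); the unadjusted profile MLE is biased low by roughly the
number of mean parameters over n and that bias destroys tail
calibration. Non-convergent fits fall back to a method-of-moments
dispersion and are flagged. No information is shared across genes: the
dispersion-shrinkage machinery of dedicated differential-expression
packages is deliberately out of scope, which makes single-gene
dispersions noisier than practitioners of those packages may expect.

**Testing.** Two p-values are reported per (gene, patient):

* `wald_pvalue` — the Wald test on the patient coefficient of the NB
  GLM (normal reference). For a single-sample patient the GLM
  factorises exactly: the covariate coefficients equal the
  leave-one-out fit and the patient coefficient saturates its own
  observation, giving beta1 = log(k / mu_pred) with variance
  (1 + alpha k)/k plus the prediction variance.
* `pvalue` — the p-value used for outlier calling: the exact two-sided
  NB tail probability 2 min{P(K <= k), P(K >= k)} of the patient's
  count under the covariate-only NB fit estimated from *all other
  samples*. Replicates are Sidak-combined over the patient's samples.

The distinction matters. The patient coefficient is identified by a
single observation, and the normal approximation to its Wald statistic
is anti-conservative deep in the tails where multiple-testing-corrected
calls live (measured per-sample family-wise error 0.12-0.22 at nominal
0.05 on null simulations); the tail probability of the count under the
fitted NB is exact given the parameters, and leaving the tested patient
out of its own null fit prevents the outlier from masking itself by
inflating its gene's dispersion. Three refinements keep the exact test
honest about estimation error: the dispersion entering the tail is
widened by the prediction variance Var[x' beta] of the fitted mean; the
dispersion's own estimation uncertainty is integrated out by three-point
Gauss-Hermite quadrature over its profile-likelihood posterior on the
log scale (which brings the measured null family-wise error to its
nominal level); and a second pass re-fits any null model whose samples
included a cell called aberrant in the first pass (iterative outlier
masking), so one patient's extreme count cannot distort a neighbour's
test.

**Calling.** Z-scores divide the log2 fold change by the standard
deviation of log2(k/s + 1) across *all* samples (pseudocount 1 avoids
-inf at zero; including the patient in the s.d. is the conservative
reading). An expression outlier requires Hochberg-adjusted p < 0.05
(family: all genes tested for that patient) and |Z| > 3. Genes with
zero variance or all-zero counts are flagged not testable.

## Aberrant splicing

**Clustering.** Junctions (introns supported by split reads; 0-based
half-open coordinates, donor = intron start, acceptor = intron end) are
clustered annotation-free into connected components over shared
donor/acceptor sites, with parameters chosen for the rare-disease
setting: introns longer than 500,000 bp removed, junctions carrying
less than 1e-5 of their cluster's cohort reads pruned iteratively, and
clusters with fewer than 30 reads dropped. Split-read counts are
assumed pre-filtered to mapping quality > 10. Intron retention produces
no split reads and is out of reach of this representation.

**Differential test.** Each cluster is tested per patient with a
Dirichlet-multinomial likelihood-ratio test: junction counts per sample
follow DM(N_s, gamma p), with proportions p shared (null) or separate
for patient and rest (alternative) and the concentration gamma shared
and ML-estimated (floor 0.01; softmax parametrisation, L-BFGS-B). The
statistic is referred to chi-square with J-1 degrees of freedom and
Hochberg-adjusted per patient. For two-junction clusters the model is
exactly a beta-binomial contrast, which provides an independent oracle
in the tests. The null fit is shared across patients for speed.

**Psi and the splice-site strength mixture.** Psi5(D,A) =
n(D,A)/sum_A' n(D,A') and Psi3 analogously over donors; undefined where
the denominator is zero. For the genome-wide strength model, each
junction side contributes one (n, N) pair pooled over samples, psi5 and
psi3 observations pooled together, stratified by the junction's
annotation group s in {0, 1, 2} (number of splice sites at annotated
exon boundaries; strand-aware matching, either orientation when the
strand is unknown). The mixture

    n | N, s ~ sum_c pi_{s,c} BetaBin(n; N, alpha_c, beta_c)

has three components (background, weak, strong) with shapes shared
across groups and group-specific mixing proportions, fitted by EM:
initial hard assignment at psi < 0.001 / < 0.1 / >= 0.1, closed-form pi
updates, bounded quasi-Newton shape updates accepted only when they
improve the weighted likelihood (so the EM objective is monotone),
convergence at relative log-likelihood change < 1e-8 (max 1,000
iterations), beta-binomial densities via log-gamma throughout.
Component collapse triggers up to two perturbed restarts. Posterior
classification breaks ties toward the lower class.

**Event taxonomy.** Significant clusters are classified by rules
against the exon annotation: a patient-dominant junction joining two
annotated boundaries across a fully contained exon is exon skipping;
one annotated end with the other inside an exon is truncation, in the
intron is elongation; two patient-elevated junctions whose unannotated
inner ends flank a novel interval between annotated exons are a new
exon; no annotation overlap at all is unclassified; anything else is
complex. The fraction of new-exon (private) events whose shared-site
observations are classed weak, over the cohort-wide weak fraction,
quantifies the enrichment of private exons at weak splice sites.

## Mono-allelic expression

Heterozygous SNVs with one alternative allele and at least 10 reads of
RNA coverage are tested independently (no phasing). The two allele
counts are modelled as NB with dispersion fixed at alpha = 0.05 for all
variants and size factors 1 (both alleles share one library). The test
is the likelihood ratio of allele-specific means (saturated; MLE of the
shared null mean is the average of the two counts) against a shared
mean, chi-square with 1 df. The likelihood ratio was preferred over the
Wald form because it is symmetric in the alleles, monotone in the
imbalance at fixed coverage, and finite at zero counts without
pseudocounts — the Wald statistic degenerates at the boundary and loses
monotonicity at extreme imbalance. A variant is called MAE of the
alternative allele when the alternative allele frequency is >= 0.8
(the allele-frequency form of a 4-fold cutoff: 4/(1+4)) and the
Benjamini-Hochberg adjusted p (per sample across its testable variants)
is < 0.05; reference-direction imbalance is reported under a separate
flag. Rare means population minor allele frequency < 0.001.
Reference-allele mapping bias is not modelled.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume,
with ground-truth labels, at desk scale. Defaults (all configurable):

* 1,000 genes x 60 samples; baseline means log-normal (median 250,
  log-sd 1.5); dispersions 1/alpha ~ Gamma(shape 4, scale 5), i.e.
  mean alpha about 0.05, matching the average gene-level dispersion the
  MAE test fixes; size factors log-normal (sd 0.2); batch (3), sex (2)
  and site (2) effects multiplicative with log-fold effects ~ N(0, 0.1)
  — small against the injected outliers but enough to exercise the
  covariate control.
* Expression outliers at rate 0.002 of (gene, sample) cells (about one
  call per sample at desk scale, matching the cohort-median scale of
  real screens), alternating up/down by index. The injected cell's
  count is set to mean * 2^(+/- z * sd) with z = 6 by default — the
  documented *target* |Z| — rather than redrawn with NB noise, so the
  realised effect hits the target instead of being centred on it.
* 150 junction clusters, each one canonical intron plus a cryptic exon
  pair inside it; donor/acceptor annotation flags Bernoulli(0.85)
  generate the three annotation groups, classes drawn from pi_{s,c},
  psi from the class beta, counts Binomial(coverage, psi) with cluster
  coverage NB(mean 150). Splicing outliers (rate 0.05 of clusters, one
  random sample each) force the cryptic pair weak and flanking exons
  annotated, then switch that sample's pair to strong-class psi — the
  private-new-exon mechanism arising from weak splice sites.
* 1,000 variants x 60 samples; coverage NB(mean 50) so the 10-read
  filter bites occasionally; balanced variants Binomial(cov, 0.5);
  injected MAE (rate 0.003 of cells, the per-testable-variant rate of
  real cohorts) with alt fraction ~ Beta(50, 2); population allele
  frequencies rare (< 0.001, log-uniform) with probability 0.1.

Features of real data deliberately not emulated: read-level structure
(mapping bias, positional coverage), gene length and GC effects,
correlated co-expression and latent confounders, linkage between
variants, multi-isoform splicing graphs beyond one cluster topology,
and annotation errors. Passing the recovery and calibration tests
therefore demonstrates the statistical machinery is correct under its
own assumptions, not that real-cohort performance will match.

Independent generator streams are derived from the seed per data type,
so each generator is byte-reproducible in isolation.

## Problem sizes and tolerances in the test suite

The heavy checks run at sizes chosen to make Monte-Carlo bounds
meaningful on a laptop-class machine: mixture recovery at 50,000
junction sides (mixing proportions within +/-0.02 of truth),
expression calibration and power on 100-sample, 400-gene cohorts
(family-wise error within three Monte-Carlo standard errors of 0.05;
sensitivity and precision >= 0.9 for |Z| = 6 injections, estimated over
two independent injected cohorts because a single 80-injection cohort
measures both with about +/-0.03 Monte-Carlo noise), and an
end-to-end run on a 60-sample cohort with injections of all three
kinds (>= 90% recovered in the merged candidate table; MAE recovery is
judged on rare variants with >= 30 reads, since only rare variants
enter the candidate list and a handful of reads carries no allelic
signal). Oracle-equivalence tests pin the Hochberg/BH adjustments to
brute-force enumeration, the MAE test to direct two-observation
likelihood optimisation (1e-6 relative), and the two-junction splicing
test to an independently parametrised beta-binomial maximiser.

## Known limitations

* No dispersion moderation across genes; single-gene dispersions are
  noisy at small n, partially compensated by the Cox-Reid adjustment,
  predictive widening and outlier masking.
* The splicing LRT relies on chi-square asymptotics with a single
  patient sample; two-junction behaviour is oracle-checked but small
  clusters with very low counts are conservative at best.
* The event classifier automates a taxonomy that was designed for
  visual curation; complex real loci will land in "complex" more often
  than a curator would.
* MAE ignores reference-mapping bias and phasing; compound
  heterozygotes are only visible as two independent variant calls.
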