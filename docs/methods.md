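# Methods

## The statistical problem

Quantitative-trait GWAS in sibship cohorts faces three coupled issues that
`cnvjoint` addresses together:

1. **Copy-number variation.** A SNP-only analysis must either discard
   non-diploid genotype calls or force them into a two-copy state. CNV-aware
   callers instead report, per locus, the counts `(a, b)` of each SNP allele
   over however many copies a sample carries. The joint model regresses the
   trait on both axes of that call,

       y = alpha + beta1*(a - b) + beta2*(a + b) + ...,

   so `beta1` is the additive SNP-allele effect and `beta2` the additive
   copy-number effect. The null hypothesis `beta1 = beta2 = 0` is tested
   with a 2-df Wald chi-square; when either axis is invariant in the sample
   (the common case — most of the genome is copy-number invariant) the test
   collapses to the 1-df test of the remaining axis.

2. **Relatedness.** Siblings share family environment and half their
   genome, so observations are not exchangeable. Family enters the model as
   a random intercept: `gamma_f ~ N(0, sigma2_family)` on top of
   `eps ~ N(0, sigma2_resid)`. Because sibships have no genotyped parents,
   no richer pedigree structure is identifiable, and none is modelled.

3. **Admixture.** In an admixed cohort, ancestry correlates with both
   allele frequencies and the trait, inflating naive tests. The leading
   principal components of the genotype matrix are included as fixed
   covariates (four by default; an eigenvalue-gap rule is also provided).

The full per-marker model for the log-scale trait is

    ln(y) = alpha + beta1*(a-b) + beta2*(a+b)
          + sum_j phi_j PC_j + phi_age*Age + phi_age2*Age^2
          + phi_sex*Sex + phi_center*Center + gamma_family + eps.

## Two-stage scan (GRAMMAR screen, then full refit)

REML-refitting the mixed model at every one of ~10^6 markers is wasteful;
the package uses the GRAMMAR residual strategy:

* **Stage 1.** Fit the mixed model once *without* genotype terms, form the
  conditional residuals `Y* = y - X*beta_hat - gamma_hat` (the family BLUP
  `gamma_hat_f` is the shrunken family residual mean,
  `s_f*sigma2_family / (sigma2_resid + s_f*sigma2_family) * mean residual`),
  and regress `Y*` on each marker's `(a-b, a+b)` by OLS with a joint Wald
  chi-square. `Y*` is exactly orthogonal to the null design
  (`Y* = sigma2_resid * V^{-1} r`), so stage 1 needs no covariates.
  The screen is deliberately *conservative*: shrinking out the family effect
  also removes part of any true genetic signal, depressing the test
  statistic (genomic inflation factor lambda < 1 under a family-variance
  null — about 0.68 at a family-variance share of 0.4 in the packaged
  simulations, returning to ~1 when the family variance is zero).

* **Stage 2.** The `k` markers with the smallest stage-1 p-values (default
  `k = 1000`) are refit with the full mixed model, re-estimating the
  variance components per marker, and tested with the joint Wald
  chi-square. Genome-wide significance is declared at `p < 5e-7` (strict),
  on the stage-2 p-value only.

Ranking is highly consistent across stages (the packaged checks require at
least nine of the exhaustive-scan top ten to survive screening at
`k = 500` over 5,000 markers, and observe ten of ten).

## REML computation

The marginal covariance is block diagonal with exchangeable blocks
`V_f = sigma2_resid*I + sigma2_family*11'`. Writing
`theta = sigma2_family/sigma2_resid`, all quantities reduce to per-family
scalars: `V_f^{-1} = (I - c_f 11')/sigma2_resid` with
`c_f = theta/(1 + s_f theta)`, and `log|V_f|` has closed form. The
restricted log-likelihood therefore costs O(n p^2) via per-family column
sums; a dense-matrix evaluation is kept in the test suite as an independent
oracle (agreement to 1e-10 on all fixtures up to 50 samples, and a
cross-check against `lme4::lmer(REML=TRUE)` on variance components, fixed
effects and their standard errors).

Estimation profiles the restricted likelihood over `theta >= 0`:
`sigma2_resid(theta)` and the GLS fixed effects have closed forms at each
`theta`, so a 31-point log grid on `[1e-4, 1e3]` (plus the boundary 0) is
scanned and the bracket around the best point refined with bounded Brent
search (`xatol = 1e-8`). When the profile at the boundary is within 1e-9 of
the interior optimum, the boundary is preferred; this both implements the
`sigma2_family >= 0` constraint and resolves the all-singleton case, where
only the variance total is identified. Under a null family variance the
estimate lands on the boundary in roughly half of replicates, as theory
predicts. Wald (not F) tests are used, matching the large-n GWAS setting;
p-values for the variance components themselves are not computed.

**Term dropping.** A genotype term is dropped as *invariant* when its
sample variance is below 1e-12, and the copy-total term as *collinear*
when the smallest singular value of the centred genotype block is below
1e-8 times the largest (e.g. a monomorphic SNP inside a deletion, where
`a - b = -(a + b)`). The reported df always equals the number of retained
terms; with none retained the marker is reported with p = 1 (stage 1) or a
missing stage-2 p, never silently skipped.

## Data layer

Calls are consumed from a self-contained tab-separated table
(`marker_id chrom pos allele_a allele_b` then one `a,b,conf` triplet or `.`
per sample) rather than any caller-specific container: the counts, not the
container, are what the model needs. Confidence scores follow the
lower-is-better convention of HMM-based CNV-aware callers; only calls with
confidence strictly below 0.1 are used, per those callers' guidance.
Missing calls are excluded per marker (complete-case within marker; the
conditional residuals are *not* recomputed per marker, faithful to the
one-null-fit design of the screen). Marker QC removes call rates below
0.95 and minor-allele frequencies (counted over all copies,
`min(sum a, sum b)/sum(a+b)`) below 0.01 by default; both are configurable,
and Mendelian checks are out of scope because parents are ungenotyped in a
sibship design. Positions are 1-based; autosomes only. `max_copy`
defaults to 4, the usual copy-state ceiling of array-based callers.

PCA excludes loci with more than 1% non-diploid calls (dosage scaling
assumes diploidy), mean-imputes residual missing calls, scales by
`sqrt(p(1-p))` and fixes each component's sign so its loading sum is
non-negative. PCs are computed on all individuals including relatives; with
large sibships the leading components can partially reflect family
structure rather than ancestry — a known artifact, acceptable here because
the components are consumed only as covariates.

## Synthetic cohort generator

The simulator emulates the HyperGEN African American sibship design and is
the package's test bed. Families follow the published family-size histogram
(421 families, 1,086 individuals) by default; all members of a family are
full sibs of two latent, never-emitted parents. Per marker, parental
haplotypes are drawn from family-level allele frequencies produced by a
two-founder-population Balding–Nichols model (divergence parameter 0.1 by
default, per-family admixture Beta(1,1)); children inherit one haplotype
per parent independently at each marker, so markers are unlinked and the
mean sib-pair genotype correlation is 0.5. At a configurable fraction of
loci a rare deletion (or duplication) allele (frequency 0.005, matching a
"< 1%" CNV regime) rides on haplotypes and segregates Mendelianly;
copy number is the number of surviving copies and `(a, b)` count the SNP
alleles on them.

Phenotypes are generated exactly from the model above. Defaults, chosen
once from the published cohort descriptives and held fixed:

| parameter | default | rationale |
|---|---|---|
| `alpha` | ln(3.26) | trait mean 3.26 cm; covariate means are folded into the intercept so the simulated mean stays there |
| `sigma2_family`, `sigma2_resid` | 0.0053, 0.0079 | family share 0.4 of a total ln-scale variance 0.0132 (CV ~= 0.117, i.e. 3.26 +/- 0.38 cm) |
| `phi_age`, `phi_age2` | 0.003 /yr, -1e-5 | mild, slightly concave age trend |
| `phi_sex` | -0.08 (female) | smaller aortic roots in women |
| `phi_center` | 0.01 | small site effect |
| `phi_ancestry` | 0.15 | trait-ancestry confounding that makes PC adjustment consequential |
| age | N(43.9, 13.4^2) truncated to [18, 85] | cohort descriptives |
| sex, center | 66.6% female; 856:230 site split (site is family-level) | cohort descriptives |
| confidence | Beta(0.5, 30) | ~1.2% of calls exceed the 0.1 filter, exercising it without defeating the 0.95 call-rate QC |
| `maf_range` | (0.16, 0.44) | the MAF range of the published top markers |

What the generator does **not** emulate: linkage disequilibrium between
markers (all loci independent), genotyping batch effects, multi-locus CNV
segments (each CNV locus segregates independently, whereas real CNVs span
many probes in near-perfect LD), age/sex-dependent ascertainment, and
measurement error in the trait. Passing tests therefore demonstrate the
statistical machinery under the stated generative model, not robustness to
those real-data features.

## Calibration checks and problem sizes

The packaged acceptance checks (also recomputed by
`scripts/acceptance.py`) use: a 5,000-marker diploid null genome on 200
sibships of 3 (600 individuals, family-variance share 0.4) for stage-2
type-I error (pooled rejection at alpha = 0.05 inside the 99% binomial
band) and stage-1 conservativeness; the full 1,086-individual roster with
5 causal markers (`beta1 = 0.05` on the ln scale) among 5,000 for two-stage
consistency; 100 replicates of 500 sib pairs for effect recovery (mean
estimate within 10%, SE calibration within 15%); and a 2,000-marker,
600-singleton admixed null for stratification control (lambda in
[0.9, 1.1] with 4 PCs, > 1.1 without). These sizes were chosen as the
smallest at which the Monte-Carlo bands above are decisive.

## Known limitations

* The Wald chi-square is mildly anticonservative at small n; an F-variant
  is not provided because the intended regime is n in the hundreds or more.
* Stage-2 p-values for screened markers are unconditional on selection;
  as in any screen-then-test design, inflation diagnostics on the screened
  subset alone reflect selection, not miscalibration.
* Out-of-sample PC projection is not implemented; PCs are computed on the
  analysis cohort.
* No imputation of missing calls and no LD-aware pruning or annotation.
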