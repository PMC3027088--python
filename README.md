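# cnvjoint

Two-stage mixed-model genome-wide association for quantitative traits in
sibship cohorts, with **joint SNP-allele and copy-number tests**.

## Who this is for

Statistical geneticists analyzing family-based cohorts (sibships without
genotyped parents, such as the HyperGEN hypertension networks) whose
genotypes come from a CNV-aware caller: each locus carries counts `(a, b)`
of the two SNP alleles over however many genomic copies the sample has
there, plus a call confidence. `cnvjoint` tests SNP and copy-number effects
simultaneously instead of discarding or coercing non-diploid calls, while
controlling for relatedness (family random intercept), admixture (genotype
principal components) and standard covariates.

## The model

For individual *i* in family *f*, with log-scale trait *y*:

```
ln(y_i) = α + β₁(a−b)ᵢ + β₂(a+b)ᵢ + Σⱼ φⱼ PCᵢⱼ
        + φ_age Ageᵢ + φ_age² Ageᵢ² + φ_sex Sexᵢ + φ_ctr Centerᵢ
        + γ_f(i) + ε_i ,      γ_f ~ N(0, σ²_family),  ε ~ N(0, σ²_resid)
```

`β₁` is the additive SNP-allele effect (per copy of allele A, on the
contrast `a−b`), `β₂` the additive copy-number effect (on the total
`a+b`). The null `β₁ = β₂ = 0` is tested with a joint 2-df Wald chi-square
that collapses to 1 df wherever an axis is invariant (most of the genome is
copy-number invariant) or collinear.

Because REML-refitting this model at every marker is expensive, the scan is
two-staged (the GRAMMAR strategy): **stage 1** fits the model once without
genotypes, takes the conditional residuals `Y* = y − Xβ̂ − γ̂` (family BLUP
removed) and screens all markers by fast OLS of `Y*` on `(a−b, a+b)`;
**stage 2** refits the full mixed model for the top *k* screened markers
(default 1,000) and applies the genome-wide threshold `p < 5×10⁻⁷` to the
stage-2 p-value. The screen is intentionally conservative (its genomic
inflation factor λ sits below 1 under family variance); the refit restores
calibrated tests. See `docs/methods.md` for the estimation details.

A seeded simulator generates sibship studies with the exact structure the
model assumes — published family-size histogram (421 families, 1,086
individuals), Mendelian inheritance from latent parents, two-population
admixture, rare deletion/duplication alleles, and phenotypes drawn from the
model above — so the whole pipeline is testable with no external data.

## Worked example

```python
import cnvjoint as cj

cfg = cj.SimConfig(n_markers=2000, n_causal=1, beta1=0.06, seed=11,
                   family_size_histogram=cj.HYPERGEN_FAMILY_HISTOGRAM)
study = cj.simulate_study(cfg)                    # 1,086 people, 421 families
scan = cj.TwoStageScan(k=200, seed=11).fit(study.genotypes,
                                           study.roster, study.pheno)
print(scan.results_.sort_values("stage2_p").head(3)[
    ["marker_id", "chrom", "maf", "beta1", "se1", "stage2_df",
     "stage2_p", "significant"]].to_string(index=False))
print(scan.report_.to_text())
```

prints

```
marker_id chrom      maf    beta1      se1  stage2_df      stage2_p  significant
  m001767    20 0.321963 0.061644 0.002767          1 6.364749e-110         True
  m001344    15 0.401586 0.010551 0.003088          1  6.346401e-04        False
  m000305     4 0.389767 0.010232 0.003135          1  1.097870e-03        False
run report
==========
seed: 11
input: individuals=1086, families=421, markers=2000
post_qc: markers=2000
null_model: individuals=1086, families=421
stage2: markers=200
lambda_stage1: 0.7245
lambda_stage2: 8.87
stage1_cutoff: 0.1755
...
```

The single simulated causal marker (`m001767`, true β₁ = 0.06) is ranked
first with β̂₁ = 0.0616 (SE 0.0028) and flagged genome-wide significant;
the test used 1 df because the marker is copy-number invariant.
`lambda_stage1 = 0.72` shows the expected conservativeness of the GRAMMAR
screen under family variance (λ is the median observed association
chi-square over its null median); `lambda_stage2` here is computed on the
*screened* subset, so it reflects selection, not miscalibration.
`stage1_cutoff` is the largest screen p-value admitted to stage 2
(≈ k/n_markers under the null).

The same run is available from the shell:

```sh
cnvjoint simulate --seed 11 --n-markers 2000 --n-causal 1 --out-prefix study
cnvjoint run --genotypes study.genotypes.tsv --roster study.roster.tsv \
             --pheno study.pheno.tsv --k 200 --out-prefix run
cnvjoint report --results run.results.tsv --out-prefix diag   # λ, QQ, Manhattan
```

All file formats are plain TSV and documented in `cnvjoint/io.py`.

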