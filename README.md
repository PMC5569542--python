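# gbcpred

Genomic prediction that fits a G-BLUP background term *simultaneously* with a
Bayes-C large-effect SNP term using a deterministic iterative conditional
expectation (ICE) algorithm, plus the two comparison engines (plain G-BLUP and
MCMC Bayes-C) and the full evaluation protocol (reliability-scaled accuracy,
bias regression, bootstrap standard errors, Hotelling–Williams tests).

## What it does

* **core**: genotype containers, allele frequencies, MAF filtering,
  centring (`M_ij = x_ij − 2p_j`), the genomic relationship matrix
  `G = MM′ / 2Σp_j(1−p_j)`, and relatedness summaries
  (meanRel / Relmax / Rel5 / Rel10).
* **gblup**: dense mixed-model-equation solver returning the mean, breeding
  values and the full prediction-error-variance (PEV) matrix; validation
  prediction by `G_vr G_rr⁻¹ ĝ_r`.
* **bayesc**: spike-and-slab single-site Gibbs sampler with fixed slab /
  residual variances (optionally sampled), defaults 20,000 iterations,
  2,000 burn-in, thinning 100.
* **gbc**: the combined model `y = 1μ + Mq + g + e` fitted by ICE.  Each SNP's
  posterior inclusion probability comes from prior odds times a likelihood
  ratio with a PEV quadratic-form correction for the uncertainty of the other
  genetic effects; the effect update is the posterior probability times the
  BLUP solution.  Hyperparameters (π, large-effect variance fraction) can be
  selected by k-fold cross-validation over the standard π grid
  {1, 5, 10, 15, 20, 25, 30}%.
* **evaluation**: response reliability `d_e/(d_e + K)` with `K = (4 − h²)/h²`,
  accuracy `corr/√(mean reliability)`, bias (OLS slope of response on
  prediction), paired bootstrap SEs, Hotelling–Williams test of dependent
  correlations.
* **simulate**: half-sib family genotype simulator (validation animals are
  offspring of reference sires, top relationships near 0.5), sparse
  large-QTL + polygenic architectures, and DYD-like responses whose precision
  is driven by an effective record count.

## CLI

```bash
# synthetic data bundle (genotypes, phenotypes, truth, ref/val split)
gbcpred simulate --preset tiny --seed 1 --out-dir work/

# fit the three models
gbcpred gblup  --geno work/geno.tsv --pheno work/pheno.tsv \
    --h2 0.25 --var-g 1.0 --var-e 0.3 --val-ids work/val_ids.txt --out-dir work/
gbcpred bayesc --geno work/geno.tsv --pheno work/pheno.tsv \
    --h2 0.25 --var-g 1.0 --var-e 0.3 --val-ids work/val_ids.txt \
    --pi 0.1 --seed 1 --out-dir work/
gbcpred gbc    --geno work/geno.tsv --pheno work/pheno.tsv \
    --h2 0.25 --var-g 1.0 --var-e 0.3 --val-ids work/val_ids.txt \
    --cv --seed 1 --out-dir work/

# compare methods on the validation animals
gbcpred evaluate --pheno work/pheno.tsv --h2 0.25 \
    --gebv gblup=work/gebv_gblup.tsv --gebv gbc=work/gebv_gbc.tsv \
    --out work/report.json

# relatedness of validation animals to the reference set
gbcpred relatedness --geno work/geno.tsv --val-ids work/val_ids.txt
```

Genotype input is either a tab/comma-separated matrix (header of SNP ids,
first column the animal id, entries 0/1/2/NA) or a PLINK RAW additive file
(`FID IID PAT MAT SEX PHENOTYPE` + per-SNP allele counts).  Exit codes:
0 success, 2 validation error, 3 non-convergence with `--strict`.

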