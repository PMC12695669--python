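# fame

Randomized Method-of-Moments estimation and testing of **marginal epistasis**
— the aggregate contribution to trait variance of all pairwise interactions
between one target SNP and the rest of the genome — on biobank-style
PLINK-format genotype panels.

For a standardized genotype matrix `X` (N × M), target SNP `t` and the
interaction design `E_t = X_{-t} ⊙ X_{:t}`, the package fits

    y = Xβ + E_t α_t + ε,   Cov(y) = σ²_g·XXᵀ/M + σ²_gxg·E_tE_tᵀ/(M−1) + σ²_e·I

by Method of Moments: `T σ² = q` with `T_kl = tr(K_k K_l)`, `q_k = yᵀK_k y`.
The expensive traces are sketched with B shared Gaussian probe vectors
(Hutchinson estimator, B = 100 by default) in streaming passes over SNP
blocks, so memory stays O(N·B) regardless of M. Standard errors come from
the plug-in sandwich `Cov[σ̃²] = T⁻¹Cov[q]T⁻¹` and each component gets a
two-sided z-test. Around the core estimator the package provides genotype QC
and standardization, inverse-rank phenotype normalization, covariate and
LD-block residualization (the step that keeps GWAS-selected targets
calibrated), GWAS target selection with sliding-window LD pruning, per-pair
interaction regression, genomic-inflation diagnostics, and a synthetic-data
module that generates all validation inputs.

Intended users: statistical-genetics researchers testing gene–gene
interaction at GWAS loci in large cohorts, and methodologists studying
variance-component estimators.

## Worked example

Everything below runs from a shell with no external data; the `simulate`
command writes a PLINK 1 panel and a phenotype with known architecture
(here N = 2000, M = 500, additive variance 0.3, marginal epistasis 0.05 at
the panel's middle SNP):

```
fame simulate --n 2000 --m 500 --sigma2-gxg 0.05 --seed 7 --out-prefix panel
printf "snp\nsnp250\n" > targets.tsv     # the simulated target (panel.truth.json)
fame test --bed panel.bed --pheno panel.pheno.tsv \
     --targets targets.tsv --probes 100 --seed 1 --out fits.tsv
```

`fits.tsv` holds one row per (target, scope); abridged:

```
target_snp  sigma2_additive  sigma2_gxg  se_gxg   z_gxg    p_gxg    h2_gxg   negative_flag
snp250      0.23261          0.05088     0.01825  2.78858  0.00529  0.05183  False
```

Read: at this target an estimated 5.1% of trait variance (SE 1.8%) is
attributable to interactions between snp250 and the rest of the panel —
matching the simulated 5% — and the two-sided test rejects the no-epistasis
null at p ≈ 0.005. Negative estimates (common at null targets) are reported
with `negative_flag` and excluded from discovery lists. In a real analysis
the target list would come from `fame gwas`, which writes a
genome-wide scan plus an LD-pruned significant-SNP list
(`<out>.targets.tsv`) that `fame test` consumes directly.

The same pipeline is available as library calls
(`fame.fit_marginal_epistasis`, `fame.gwas_scan`, …); `fame calibrate` and
`fame power` run the null-calibration and power experiments end to end.

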