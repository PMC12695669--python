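# Methods

## Model

For `N` individuals genotyped at `M` SNPs, let `X` be the column-standardized
genotype matrix, `t` a target SNP, and `E_t = X_{-t} ⊙ X_{:t}` the
`N × (M−1)` interaction design whose columns are elementwise products of the
target's standardized genotype with every other SNP's. The trait is modeled as

    y = X β + E_t α_t + ε,
    β ~ N(0, σ²_g / M · I),  α_t ~ N(0, σ²_gxg / (M−1) · I),  ε ~ N(0, σ²_e I),

so that

    Cov(y) = σ²_g K₁ + σ²_gxg K₂ + σ²_e K₃,
    K₁ = XXᵀ/M,  K₂ = E_tE_tᵀ/(M−1),  K₃ = I.

σ²_gxg is the *marginal epistasis* variance at the target: the aggregate
contribution of all pairwise interactions involving `t`. Interaction effects
are assumed independent of main effects (uncoordinated epistasis); only
quantitative traits are supported.

## Estimation

Method of Moments: equating `yyᵀ` to its expectation under the Frobenius norm
gives normal equations `T σ² = q` with `T_kl = tr(K_k K_l)` and
`q_k = yᵀ K_k y`. Traces between the two non-identity kernels are estimated
with `B` shared standard-normal probe vectors (Hutchinson):

    T̂_kl = (1 / B M_k M_l) Σ_b vᵀ_b Z_k Z_kᵀ Z_l Z_lᵀ v_b.

Using the identity `vᵀ A Aᵀ B Bᵀ v = (A Aᵀ v)·(B Bᵀ v)`, one streaming pass
per component accumulates the `N × B` matrix `Z_k Z_kᵀ V`, from which every
pairwise stochastic trace follows; entries involving the identity are exact
(`tr(K_k) = ‖Z_k‖²_F / M_k`, `tr(I) = N`). `q` is always exact. Standard
errors come from the sandwich `Cov[σ̃²] = T⁻¹ Cov[q] T⁻¹` with the plug-in

    Cov[q]_kl = 2 Σ_t σ̃²_t · w_kᵀ (Z_t Z_tᵀ / M_t) w_l,   w_k = K_k y,

computed exactly in a second streaming pass. Each component is tested
two-sided with `z = σ̃² / SE`; negative estimates are reported and flagged,
never truncated, and the CLI's discovery flag excludes flagged results from
significance lists.

Implementation notes:

- **Sketch layout.** Per-component aggregates are stored as `N × B` arrays
  (`Z Zᵀ V`), not `M_k × B`, bounding memory at `O(N·B + N·block)` regardless
  of panel size. This is a pass-structure choice; the estimator is unchanged.
- **Probes.** One probe set is shared across all components and entries of a
  fit, `B = 100` by default (empirically sufficient: two probe seeds give
  −log₁₀ p correlations above 0.99 in our stability check). Gaussian entries
  by default; Rademacher probes are available behind a flag.
- **Conditioning.** `T̂` with condition number above 1e12 raises instead of
  being regularized. The SE formula conditions on `T̂` (probe noise in `T̂` is
  not propagated); with `B = 100` this contribution is negligible next to the
  sampling noise in `q`.
- **Dense products.** Matrix products are blocked dense BLAS calls; no
  special-cased {0,1,2} multiplication is used, so asymptotic-speedup claims
  of such schemes are out of scope here.
- **Heritability fractions.** `h²_gxg = σ̃²_gxg / Σ_k σ̃²_k` with negative
  components floored at zero in the sum (the total-variance denominator is a
  documented convention choice). `h²_gwas = β̂²` for a standardized-genotype,
  variance-1-phenotype GWAS effect, and the gxg/gwas ratio is taken from
  unrounded estimates.

## Preprocessing and calibration

Order of operations: inverse-rank normal transform (Blom offsets
`(r − 3/8)/(N + 1/4)`, average ranks on ties) → covariate residualization
(phenotype-side projection; covariates are not projected out of genotypes or
probes, a documented simplification) → regression of the phenotype on all
standardized SNPs in the target's LD block (plus intercept). The LD block
comes from a BED3 block map when supplied, otherwise a ±1 Mb window around
the target. Block SNPs, the MHC (chr6:25–35 Mb), and the target itself are
excluded from `E_t`; the additive component runs over all SNPs outside the
block. This regress-out step is what keeps GWAS-selected targets calibrated;
without it their interaction p-values are inflated.

Because the rank transform runs first, all downstream statistics are exactly
invariant to strictly monotone transformations of the raw trait.

Genotype QC (missingness > 1%, MAF < 1%, 1-df HWE χ² at 1e-7, MHC region)
filters in a fixed order with first-failure accounting; missing hard calls
are mean-imputed per SNP; standardization divides by the population SD so
that each column has sum of squares exactly `N` and `tr(K₁) = N` holds as an
exact test oracle.

## Target selection and localization

The GWAS scan regresses the residualized trait on each standardized SNP
(Frisch–Waugh phenotype-side shortcut; exact per-SNP multiple regression is
available behind a flag), flags SNPs at `P < 5×10⁻⁸` (configurable), and
prunes them greedily in position order: within a sliding 500-SNP window the
later SNP of any pair with `r² > 0.1` is removed. The positional tie-break
(later SNP dropped) is a documented choice. Interaction scopes `local`
(target's chromosome minus its LD block) and `distal` (all other
chromosomes) partition the genome-wide column set exactly. The per-pair
GxGWAS test is OLS of `y` on `{1, x_t, x_j, x_t⊙x_j}`, skipping pairs with
`r² > 0.99`. Genomic inflation is the median implied 1-df χ² over 0.4549364,
with a bootstrap CI.

## Synthetic data

The generator emulates a biobank-style panel of unrelated individuals:
hard-call dosages Binomial(2, f), `f ~ U(0.01, 0.5)`, independent SNPs by
default or block LD from a first-order haplotype-copying process (adjacent-SNP
correlation ≈ `block_r`). SNPs sit on a 100 kb grid so the ±1 Mb fallback LD
window spans ~21 SNPs. Phenotypes follow the generative model above with 10%
additive-causal and 10% epistatic-causal SNPs (disjoint, epistatic set
outside the target's LD block), `σ²_g = 0.3` (0.25 with 1% causal for the
calibration runs) and total variance 1. Interaction effect variances are
scaled by the realized product-column variances so the expected interaction
variance equals `σ²_gxg` — the one bookkeeping approximation worth noting.

What this does not emulate: realistic coalescent LD, relatedness, population
stratification, MAF spectra from demography, or binary traits. Passing
calibration/power checks on these panels validates the estimator's
statistics, not robustness to those real-data features.

Misspecification scenarios perturb the null (functional forms and defaults
are this package's choices, all exposed in `SimConfig`): quadratic covariate
effect `w + 0.5(w²−1)` with only `w` modeled; hidden gene–environment term
`(Xγ)⊙e` with a 10% variance share; t₃ noise scaled to `σ²_e`;
noise SD affine in a covariate (slope 0.5, normalized); causal variants on a
3× denser hidden panel with every third SNP observed; and additive effect
variances ∝ `[f(1−f)]^(1+a)`, `a = 0.25`.

## Study conditions and problem sizes

Validation runs use desk-scale sizes chosen so the full suite completes on a
single CPU: calibration at `N = 4000, M = 2000` with ~300 GWAS-selected
targets; misspecification at `N = 4000, M = 500` with 150 replicates per
scenario (at substantially smaller N the normal approximation to the
component z-statistic is visibly pre-asymptotic and the hidden-GxE scenario
shows mild inflation, so the scenario suite keeps N at desk scale);
power/recovery at `N = 4000, M = 1000` with 50 replicates per
`σ²_gxg ∈ {0.01, 0.025, 0.05}`. At these sizes the smallest detectable
interaction variance is necessarily larger than it would be on a
multi-hundred-thousand-sample biobank panel; `scripts/acceptance.py`
records exactly what it measures at the sizes it runs.

## Known limitations

- Covariates are projected out of the phenotype only; with covariates highly
  correlated with genotypes the additive component can absorb part of the
  covariate signal.
- The local/distal split inherits the LD-block definition; signals inside
  the block or in long-range LD with the target are deliberately not tested.
- Negative variance estimates are expected at null targets (roughly half);
  they are reported with flags rather than constrained, so σ̃² is not a
  variance in the parameter-space sense for individual fits.
- Binary traits, REML/likelihood fitting, dosage genotypes and PLINK 2
  inputs are out of scope.
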