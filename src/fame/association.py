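"""GWAS target selection, LD pruning, pairwise interaction tests and
genomic-inflation diagnostics.

The per-SNP scan regresses the covariate-residualized phenotype on each
standardized genotype column (a Frisch-Waugh phenotype-side shortcut to the
full per-SNP multiple regression; the exact refit is available behind
``exact_covariates``).  Significant SNPs are greedily LD-pruned in position
order with a 500-SNP sliding window and an r^2 > 0.1 rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeSource, StandardizedSource
from .preprocessing import (PhenotypeVector, CovariateMatrix,
                            inverse_rank_normalize, residualize_covariates)

__all__ = ["GwasResult", "gwas_scan", "ld_prune", "pairwise_interaction_test",
           "genomic_inflation"]

GWAS_THRESHOLD = 5e-8
CHI2_1_MEDIAN = 0.4549364  # median of the 1-df chi-square distribution


@dataclass
class GwasResult:
    table: pd.DataFrame  # snp, chr, pos, beta, se, p, significant
    threshold: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def gwas_scan(genotypes: GenotypeSource, y: PhenotypeVector,
              covariates: CovariateMatrix | None = None,
              threshold: float = GWAS_THRESHOLD,
              exact_covariates: bool = False) -> GwasResult:
    """Per-SNP additive scan on the inverse-rank-normalized, residualized trait.

    Effect sizes are on the standardized-genotype scale; with a variance-1
    phenotype, beta^2 is the variance explained by the SNP.
    """
    if y.transform_tag == "raw":
        y = inverse_rank_normalize(y)
    if covariates is not None and not exact_covariates:
        y = residualize_covariates(y, covariates)
    yv = y.values - y.values.mean()
    n = yv.size
    std = StandardizedSource(genotypes)
    rows = []
    yty = float(yv @ yv)
    for block in std.iter_blocks():
        x = block.dosage
        if exact_covariates and covariates is not None:
            w = covariates.values
            for j, snp in enumerate(block.snps):
                design = np.column_stack([x[:, j], w])
                coef, _, _, _ = np.linalg.lstsq(design, yv, rcond=None)
                resid = yv - design @ coef
                dof = n - design.shape[1]
                xtx = float(x[:, j] @ x[:, j])
                # se of the genotype coefficient from the inverse Gram matrix
                gram_inv = np.linalg.pinv(design.T @ design)
                se = float(np.sqrt(gram_inv[0, 0] * (resid @ resid) / dof))
                tstat = coef[0] / se
                rows.append((snp.snp_id, snp.chromosome, snp.position_bp,
                             coef[0], se, 2 * stats.t.sf(abs(tstat), dof)))
            continue
        # simple regression on standardized columns: ||x_j||^2 = N exactly
        beta = x.T @ yv / n
        rss = np.clip(yty - n * beta ** 2, 0, None)
        se = np.sqrt(rss / (n - 2) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.inf)
        p = 2 * stats.t.sf(np.abs(tstat), n - 2)
        for j, snp in enumerate(block.snps):
            rows.append((snp.snp_id, snp.chromosome, snp.position_bp,
                         float(beta[j]), float(se[j]), float(p[j])))
    table = pd.DataFrame(rows, columns=["snp", "chr", "pos", "beta", "se", "p"])
    table["p"] = table["p"].clip(lower=np.nextafter(0, 1))
    table["significant"] = table["p"] < threshold
    return GwasResult(table, threshold)


def ld_prune(significant_snps: pd.DataFrame, genotypes: GenotypeSource,
             r2_threshold: float = 0.1, window: int = 500) -> pd.DataFrame:
    """Greedy positional LD pruning of a candidate SNP table.

    SNPs are visited in (chr, pos) order; a SNP is dropped when its squared
    correlation with any *kept* SNP among the previous ``window`` candidates
    exceeds ``r2_threshold`` (the later SNP of an offending pair is removed;
    the window then slides by one SNP).
    """
    if significant_snps.empty:
        return significant_snps
    cand = significant_snps.sort_values(["chr", "pos"], kind="stable").reset_index(drop=True)
    panel_pos = {s.snp_id: j for j, s in enumerate(genotypes.snps)}
    idx = [panel_pos[s] for s in cand["snp"]]
    std = StandardizedSource(genotypes)
    cols = std.materialize(idx)
    # materialize() returns columns for the sorted unique indices; re-align to cand order
    sorted_unique = sorted(set(idx))
    col_of = {g: k for k, g in enumerate(sorted_unique)}
    x = np.column_stack([cols[:, col_of[g]] for g in idx])
    n = x.shape[0]
    kept: list[int] = []
    for i in range(len(cand)):
        lo = max(0, i - window)
        prev = [k for k in kept if k >= lo and cand.loc[k, "chr"] == cand.loc[i, "chr"]]
        drop = False
        for k in prev:
            r = float(x[:, k] @ x[:, i]) / n
            if r * r > r2_threshold:
                drop = True
                break
        if not drop:
            kept.append(i)
    return cand.loc[kept].reset_index(drop=True)


def pairwise_interaction_test(x_t: np.ndarray, x_j: np.ndarray,
                              y: PhenotypeVector,
                              covariates: CovariateMatrix | None = None
                              ) -> tuple[float, float, float, bool]:
    """OLS of y on {1, x_t, x_j, x_t*x_j}; two-sided test of the product term.

    Returns (beta_pairwise, se, p, skipped).  Skipped (with NaNs) when the two
    genotypes are nearly collinear (r^2 > 0.99).
    """
    x_t = np.asarray(x_t, float)
    x_j = np.asarray(x_j, float)
    if y.transform_tag == "raw":
        y = inverse_rank_normalize(y)
    if covariates is not None:
        y = residualize_covariates(y, covariates)
    yv = y.values
    n = yv.size
    r = np.corrcoef(x_t, x_j)[0, 1]
    if r * r > 0.99:
        return float("nan"), float("nan"), float("nan"), True
    design = np.column_stack([np.ones(n), x_t, x_j, x_t * x_j])
    coef, _, _, _ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ coef
    dof = n - design.shape[1]
    sigma2 = float(resid @ resid) / dof
    gram_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * gram_inv[3, 3]))
    tstat = coef[3] / se
    p = float(2 * stats.t.sf(abs(tstat), dof))
    return float(coef[3]), se, p, False


def genomic_inflation(p_values, ci: bool = False, n_boot: int = 10_000,
                      seed: int = 0) -> float | tuple[float, tuple[float, float]]:
    """Genomic inflation factor: median 1-df chi-square statistic implied by
    the p-values over the null median 0.4549364.

    With ``ci=True`` also returns a bootstrap 95% interval over the p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 20:
        raise ValueError(f"need at least 20 p-values, got {p.size}")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    if not ci:
        return lam
    rng = np.random.default_rng(seed)
    boots = np.median(
        rng.choice(chi2, size=(n_boot, chi2.size), replace=True), axis=1) / CHI2_1_MEDIAN
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return lam, (float(lo), float(hi))
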