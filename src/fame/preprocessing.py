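"""Phenotype normalization, covariate residualization and LD-block handling.

The canonical preprocessing order for a marginal-epistasis fit is

    inverse-rank normalize -> residualize covariates -> regress out the
    target SNP's LD block

applied to the phenotype only.  Because the rank-based normal transform comes
first, every downstream statistic is invariant to strictly monotone
transformations of the raw trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeBlock, SnpMeta

__all__ = [
    "PhenotypeVector",
    "CovariateMatrix",
    "LdBlockMap",
    "inverse_rank_normalize",
    "residualize_covariates",
    "ld_block_for_target",
    "regress_out_ld_block",
    "read_phenotype_tsv",
    "read_covariate_tsv",
]

# Fallback half-window around the target when no LD-block file is supplied.
FALLBACK_WINDOW_BP = 1_000_000


@dataclass
class PhenotypeVector:
    sample_ids: list[str]
    values: np.ndarray
    transform_tag: str = "raw"  # raw | ivrt | residualized

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.sample_ids) != self.values.size:
            raise ValueError("phenotype values must be a vector aligned with sample_ids")


@dataclass
class CovariateMatrix:
    """Named covariates; an intercept column is always present."""

    sample_ids: list[str]
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if "intercept" not in self.names:
            self.names = ["intercept"] + list(self.names)
            self.values = np.column_stack(
                [np.ones(len(self.sample_ids)), self.values]) if self.values.size else \
                np.ones((len(self.sample_ids), 1))


@dataclass(frozen=True)
class LdBlockMap:
    """Non-overlapping 1-based inclusive genomic intervals per chromosome."""

    intervals: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_bed3(cls, path) -> "LdBlockMap":
        """Load BED3 (0-based half-open) blocks, converting to 1-based inclusive."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split()[:3]
                rows.append((chrom.removeprefix("chr"), int(start) + 1, int(end)))
        return cls(tuple(rows))

    def block_containing(self, chrom: str, pos: int) -> tuple[str, int, int] | None:
        for c, s, e in self.intervals:
            if c == chrom.removeprefix("chr") and s <= pos <= e:
                return (c, s, e)
        return None


def inverse_rank_normalize(y: PhenotypeVector) -> PhenotypeVector:
    """Rank-based inverse normal transform with Blom offsets.

    Maps value of rank r (average ranks for ties) to Phi^-1((r - 3/8)/(N + 1/4)).
    """
    v = y.values
    if np.isnan(v).any():
        raise ValueError("missing phenotype values must be dropped before ivrt")
    if np.ptp(v) == 0:
        raise ValueError("constant phenotype carries no rank information")
    n = v.size
    n_dup = n - np.unique(v).size
    if n_dup > 0.2 * n:
        warnings.warn(f"{n_dup}/{n} tied phenotype values; using average ranks")
    ranks = stats.rankdata(v, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return PhenotypeVector(y.sample_ids, z, transform_tag="ivrt")


def _ols_residual(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residual of y on design via pivoted least squares (rank-deficiency safe)."""
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def residualize_covariates(y: PhenotypeVector, W: CovariateMatrix) -> PhenotypeVector:
    """Project the covariate span out of the phenotype: y - W (W^T W)^-1 W^T y."""
    if list(W.sample_ids) != list(y.sample_ids):
        raise ValueError("covariate and phenotype sample ids are not aligned")
    design = W.values
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("collinear covariate columns; dropping redundant directions")
    resid = _ols_residual(y.values, design)
    return PhenotypeVector(y.sample_ids, resid, transform_tag="residualized")


def ld_block_for_target(target: SnpMeta, blocks: LdBlockMap | None,
                        panel: list[SnpMeta], fallback: bool = True) -> set[int]:
    """Panel indices (target included) inside the LD block containing the target.

    With no block map, falls back to a +/-1 Mb window around the target.
    """
    if blocks is not None:
        hit = blocks.block_containing(target.chromosome, target.position_bp)
        if hit is None and not fallback:
            raise ValueError(
                f"no LD block covers {target.snp_id} at "
                f"{target.chromosome}:{target.position_bp} and fallback is disabled")
    else:
        hit = None
    if hit is None:
        lo = target.position_bp - FALLBACK_WINDOW_BP
        hi = target.position_bp + FALLBACK_WINDOW_BP
        chrom = target.chromosome
    else:
        chrom, lo, hi = hit
    out = {j for j, s in enumerate(panel)
           if s.chromosome == chrom and lo <= s.position_bp <= hi}
    out |= {j for j, s in enumerate(panel) if s.snp_id == target.snp_id}
    return out


def regress_out_ld_block(y: PhenotypeVector, block_genotypes: GenotypeBlock | None
                         ) -> PhenotypeVector:
    """OLS residual of y on the standardized LD-block SNPs jointly (plus intercept).

    Removes additive effects tagged by the target's LD block so that
    GWAS-selected targets give calibrated interaction tests.
    """
    if block_genotypes is None or block_genotypes.n_snps == 0:
        return y
    if not block_genotypes.standardized:
        raise ValueError("LD-block genotypes must be standardized")
    if block_genotypes.n_snps >= y.values.size:
        raise ValueError("LD block has as many SNPs as samples; cannot regress out")
    design = np.column_stack([np.ones(y.values.size), block_genotypes.dosage])
    resid = _ols_residual(y.values, design)
    return PhenotypeVector(y.sample_ids, resid, transform_tag="residualized")


def _read_fid_iid_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected FID, IID and at least one value column")
    return df


def read_phenotype_tsv(path, column: str | None = None) -> PhenotypeVector:
    """Read one trait from a header TSV with FID, IID then value columns."""
    df = _read_fid_iid_table(path)
    col = column if column is not None else df.columns[2]
    sub = df[[df.columns[1], col]].dropna()
    return PhenotypeVector(list(sub.iloc[:, 0]), sub[col].to_numpy(float))


def read_covariate_tsv(path) -> CovariateMatrix:
    """Read covariates from a header TSV with FID, IID then covariate columns."""
    df = _read_fid_iid_table(path)
    names = list(df.columns[2:])
    return CovariateMatrix(list(df.iloc[:, 1]), names, df[names].to_numpy(float))
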