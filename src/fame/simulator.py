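"""Synthetic genotypes and phenotypes for validating the marginal-epistasis test.

Genotypes are hard-call dosages drawn per SNP as Binomial(2, f) with f uniform
over a MAF range, either independently per SNP or with block-wise LD from a
first-order haplotype-copying process.  Phenotypes follow the generative model

    y = X beta + E_t alpha_t + eps

with beta nonzero on a random 10% additive-causal set M_a (variance
sigma2_g / |M_a| each), alpha_t nonzero on a disjoint 10% epistatic-causal
set M_e that also avoids the target's LD block (total interaction variance
sigma2_gxg), and eps ~ N(0, sigma2_e).  Defaults follow the validation study
conditions: sigma2_g = 0.3 (0.25 for the null/calibration runs), total
variance 1, sigma2_gxg swept over [0.001, 0.1].

Misspecification scenarios (nonlinear covariate effect, hidden gene by
environment interaction, heavy-tailed noise, heteroskedastic noise, untyped
causal variants, MAF-dependent effect-size architecture) perturb the null
model to probe test calibration; their functional forms and default
parameters are this package's own choices, exposed in :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genotype_io import MatrixSource, SnpMeta, StandardizedSource
from .preprocessing import PhenotypeVector, FALLBACK_WINDOW_BP
from .association import gwas_scan, ld_prune, genomic_inflation
from .estimator import fit_marginal_epistasis

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotype",
           "apply_misspecification", "simulate_dataset",
           "run_calibration_experiment", "run_power_experiment"]

SCENARIOS = ("baseline", "null", "nonlinear_covariate", "hidden_gxe",
             "heavy_tail", "heteroskedastic", "untyped_causal", "maf_ld_arch")

# Genome-wide-scale calibration benchmark (biobank panel, not desk scale):
# genomic inflation 0.958 and 1.053 for causal ratios 0.01 and 0.10.
REFERENCE_FULL_SCALE_LAMBDA_GC = {0.01: 0.958, 0.10: 1.053}


@dataclass
class SimConfig:
    N: int = 4000
    M: int = 2000
    maf_range: tuple[float, float] = (0.01, 0.5)
    sigma2_g: float = 0.3
    sigma2_gxg: float = 0.0
    sigma2_e: float | None = None  # defaults to 1 - sigma2_g - sigma2_gxg
    causal_frac_additive: float = 0.1
    causal_frac_gxg: float = 0.1
    target_index: int | None = None  # defaults to M // 2
    scenario: str = "baseline"
    seed: int = 0
    # genotype generation
    ld_mode: str = "independent"  # independent | blocky
    block_r: float = 0.6
    block_len: int = 20
    n_chromosomes: int = 1
    spacing_bp: int = 100_000
    # misspecification parameters (package defaults, all configurable)
    quad_coef: float = 0.5
    gxe_share: float = 0.1
    t_dof: float = 3.0
    hetero_slope: float = 0.5
    maf_ld_exponent: float = 0.25
    hidden_panel_factor: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0.01, 0.5]")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "null":
            self.sigma2_gxg = 0.0
        if self.sigma2_e is None:
            self.sigma2_e = 1.0 - self.sigma2_g - self.sigma2_gxg
        if min(self.sigma2_g, self.sigma2_gxg, self.sigma2_e) < 0:
            raise ValueError("variance components must be nonnegative")

    @property
    def target(self) -> int:
        return self.M // 2 if self.target_index is None else self.target_index


@dataclass
class SimTruth:
    beta: np.ndarray
    alpha_t: np.ndarray
    causal_additive: np.ndarray
    causal_gxg: np.ndarray
    target_index: int
    ld_block: np.ndarray
    sigma2_g: float
    sigma2_gxg: float
    sigma2_e: float
    realized_fractions: dict
    scenario: str
    covariate: np.ndarray | None = None
    hidden_info: dict | None = None


def simulate_genotypes(N: int, M: int, maf_range=(0.01, 0.5),
                       ld_mode: str = "independent", seed: int = 0,
                       block_r: float = 0.6, block_len: int = 20,
                       n_chromosomes: int = 1,
                       spacing_bp: int = 100_000) -> MatrixSource:
    """Hard-call genotype panel with per-SNP metadata.

    ``independent``: Binomial(2, f_j) per SNP.  ``blocky``: within blocks of
    ``block_len`` SNPs sharing one allele frequency, each haplotype allele is
    copied from its left neighbour with probability ``block_r`` (giving
    adjacent-SNP correlation near ``block_r``) and redrawn otherwise.
    """
    rng = np.random.default_rng(seed)
    if ld_mode == "independent":
        freqs = rng.uniform(*maf_range, size=M)
        dosage = rng.binomial(2, freqs, size=(N, M)).astype(float)
    elif ld_mode == "blocky":
        n_blocks = (M + block_len - 1) // block_len
        freqs = np.repeat(rng.uniform(*maf_range, size=n_blocks), block_len)[:M]
        hap = np.empty((N, M, 2))
        for a in range(2):
            hap[:, 0, a] = rng.random(N) < freqs[0]
            for j in range(1, M):
                fresh = rng.random(N) < freqs[j]
                same_block = (j % block_len) != 0
                if same_block:
                    copy = rng.random(N) < block_r
                    hap[:, j, a] = np.where(copy, hap[:, j - 1, a], fresh)
                else:
                    hap[:, j, a] = fresh
        dosage = hap.sum(axis=2)
    else:
        raise ValueError(f"unknown ld_mode {ld_mode!r}")
    per_chrom = (M + n_chromosomes - 1) // n_chromosomes
    snps = []
    for j in range(M):
        chrom = str(1 + j // per_chrom)
        pos = 1 + (j % per_chrom) * spacing_bp
        snps.append(SnpMeta(f"snp{j}", chrom, pos, allele_ref="A", allele_alt="G",
                            maf=float(min(freqs[j], 1 - freqs[j]))))
    return MatrixSource(dosage, snps)


def _standardized_matrix(source: MatrixSource) -> np.ndarray:
    if getattr(source, "standardized", False):
        return source.materialize()
    return StandardizedSource(source).materialize()


def _ld_block_indices(snps: Sequence[SnpMeta], t: int) -> np.ndarray:
    ts = snps[t]
    return np.array([j for j, s in enumerate(snps)
                     if s.chromosome == ts.chromosome
                     and abs(s.position_bp - ts.position_bp) <= FALLBACK_WINDOW_BP])


def simulate_phenotype(X: MatrixSource, cfg: SimConfig
                       ) -> tuple[PhenotypeVector, SimTruth]:
    """Draw one phenotype replicate from the generative model.

    The interaction effects are scaled by the realized sample variances of the
    product columns so that the expected variance contributed equals
    ``cfg.sigma2_gxg`` under the simulated MAFs.
    """
    rng = np.random.default_rng(cfg.seed)
    xs = _standardized_matrix(X)
    n, m = xs.shape
    if m != cfg.M:
        raise ValueError(f"panel has {m} SNPs but config says {cfg.M}")
    t = cfg.target
    block = _ld_block_indices(X.snps, t)

    n_a = max(1, round(cfg.causal_frac_additive * m))
    causal_a = rng.choice(m, size=n_a, replace=False)
    beta = np.zeros(m)
    if cfg.sigma2_g > 0:
        if cfg.scenario == "maf_ld_arch":
            f = np.array([min(max(s.maf, 1e-3), 0.5) for s in X.snps])[causal_a]
            w = (f * (1 - f)) ** (1.0 + cfg.maf_ld_exponent)
            w *= n_a / w.sum()
            beta[causal_a] = rng.normal(0, np.sqrt(cfg.sigma2_g / n_a * w))
        else:
            beta[causal_a] = rng.normal(0, np.sqrt(cfg.sigma2_g / n_a), size=n_a)
    y_add = xs @ beta

    eligible = np.setdiff1d(np.arange(m), np.union1d(causal_a, block))
    n_e = max(1, round(cfg.causal_frac_gxg * m))
    alpha = np.zeros(0)
    causal_e = np.zeros(0, dtype=int)
    y_gxg = np.zeros(n)
    if cfg.sigma2_gxg > 0:
        if eligible.size == 0:
            raise ValueError("no SNPs eligible for epistatic effects")
        n_e = min(n_e, eligible.size)
        causal_e = np.sort(rng.choice(eligible, size=n_e, replace=False))
        prod = xs[:, causal_e] * xs[:, [t]]
        col_var = prod.var(axis=0)
        alpha = rng.normal(0, np.sqrt(cfg.sigma2_gxg / col_var.sum()), size=n_e)
        y_gxg = prod @ alpha

    genetic = y_add + y_gxg
    covariate = None
    if cfg.scenario in ("baseline", "null", "untyped_causal", "maf_ld_arch"):
        eps = rng.normal(0, np.sqrt(cfg.sigma2_e), size=n)
        y_values = genetic + eps
    else:
        y_pv, covariate, eps = _scenario_terms(genetic, xs, cfg, rng)
        y_values = y_pv

    var_y = y_values.var()
    truth = SimTruth(
        beta=beta, alpha_t=alpha, causal_additive=np.sort(causal_a),
        causal_gxg=causal_e, target_index=t, ld_block=block,
        sigma2_g=cfg.sigma2_g, sigma2_gxg=cfg.sigma2_gxg, sigma2_e=cfg.sigma2_e,
        realized_fractions={
            "additive": float(y_add.var() / var_y),
            "gxg": float(y_gxg.var() / var_y),
            "noise": float(np.var(eps) / var_y),
        },
        scenario=cfg.scenario, covariate=covariate)
    ids = [f"iid{i}" for i in range(n)]
    return PhenotypeVector(ids, y_values, "raw"), truth


def _scenario_terms(genetic: np.ndarray, xs: np.ndarray, cfg: SimConfig,
                    rng: np.random.Generator):
    """Noise and extra terms for the misspecification scenarios."""
    n, m = xs.shape
    covariate = None
    if cfg.scenario == "nonlinear_covariate":
        covariate = rng.standard_normal(n)
        extra = covariate + cfg.quad_coef * (covariate ** 2 - 1.0)
        eps = rng.normal(0, np.sqrt(cfg.sigma2_e), size=n)
        y = genetic + extra + eps
    elif cfg.scenario == "hidden_gxe":
        # noise drawn first so that gxe_share = 0 reproduces baseline exactly
        noise = rng.normal(0, np.sqrt(cfg.sigma2_e), size=n)
        env = rng.standard_normal(n)
        gamma = rng.normal(0, 1.0, size=m) * np.sqrt(cfg.gxe_share / m)
        y = genetic + (xs @ gamma) * env + noise
        eps = y - genetic
    elif cfg.scenario == "heavy_tail":
        raw = rng.standard_t(cfg.t_dof, size=n)
        scale = np.sqrt(cfg.sigma2_e / (cfg.t_dof / (cfg.t_dof - 2.0)))
        eps = raw * scale
        y = genetic + eps
    elif cfg.scenario == "heteroskedastic":
        covariate = rng.standard_normal(n)
        sd = np.clip(1.0 + cfg.hetero_slope * covariate, 0.1, None)
        sd *= np.sqrt(cfg.sigma2_e) / np.sqrt(np.mean(sd ** 2))
        eps = rng.standard_normal(n) * sd
        y = genetic + eps
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    return y, covariate, eps


def apply_misspecification(y: PhenotypeVector, X: MatrixSource,
                           cfg: SimConfig, seed: int | None = None
                           ) -> PhenotypeVector:
    """Apply the configured scenario's noise/extra terms to a noiseless
    genetic phenotype.  Errors on baseline/null (nothing to apply)."""
    if cfg.scenario in ("baseline", "null"):
        raise ValueError("no misspecification to apply under baseline/null")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    xs = _standardized_matrix(X)
    if cfg.scenario in ("untyped_causal", "maf_ld_arch"):
        vals = y.values + rng.normal(0, np.sqrt(cfg.sigma2_e), size=y.values.size)
        return PhenotypeVector(y.sample_ids, vals, "raw")
    vals, _, _ = _scenario_terms(y.values, xs, cfg, rng)
    return PhenotypeVector(y.sample_ids, vals, "raw")


def simulate_dataset(cfg: SimConfig, genotypes: MatrixSource | None = None
                     ) -> tuple[MatrixSource, PhenotypeVector, SimTruth]:
    """Genotypes plus one phenotype replicate, handling the untyped-causal
    scenario (causal effects drawn on a denser hidden panel, every
    ``hidden_panel_factor``-th SNP exposed to the analyst)."""
    if cfg.scenario == "untyped_causal":
        factor = cfg.hidden_panel_factor
        if genotypes is not None:
            if genotypes.n_snps != cfg.M * factor:
                raise ValueError("untyped_causal expects the hidden panel "
                                 f"({cfg.M * factor} SNPs) as fixed genotypes")
            hidden = genotypes
        else:
            hidden = simulate_genotypes(
                cfg.N, cfg.M * factor, cfg.maf_range, cfg.ld_mode, cfg.seed,
                cfg.block_r, cfg.block_len, cfg.n_chromosomes, cfg.spacing_bp)
        hidden_cfg = replace(cfg, M=cfg.M * factor, scenario="untyped_causal",
                             target_index=cfg.target * factor)
        y, truth = simulate_phenotype(hidden, hidden_cfg)
        observed_idx = np.arange(0, cfg.M * factor, factor)
        obs_dosage = hidden.materialize(observed_idx)
        obs_snps = [hidden.snps[j] for j in observed_idx]
        source = MatrixSource(obs_dosage, obs_snps)
        truth.hidden_info = {"factor": factor, "observed_indices": observed_idx}
        truth.target_index = cfg.target
        return source, y, truth
    if genotypes is None:
        genotypes = simulate_genotypes(
            cfg.N, cfg.M, cfg.maf_range, cfg.ld_mode, cfg.seed,
            cfg.block_r, cfg.block_len, cfg.n_chromosomes, cfg.spacing_bp)
    y, truth = simulate_phenotype(genotypes, cfg)
    return genotypes, y, truth


def _child_seeds(seed: int, k: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=k)


def run_calibration_experiment(cfg: SimConfig, n_reps: int, *, seed: int = 0,
                               gwas_threshold: float = 5e-8,
                               max_targets_per_rep: int = 5,
                               B: int = 100, alpha: float = 0.05) -> dict:
    """Null-architecture calibration: GWAS -> LD prune -> marginal-epistasis
    test at the selected targets, pooling interaction p-values.

    Genotypes are held fixed across replicates (as when phenotypes are
    simulated on a real panel); each replicate redraws effects and noise.
    """
    if cfg.sigma2_gxg != 0:
        raise ValueError("calibration experiment requires a null architecture")
    raw = simulate_genotypes(cfg.N, cfg.M, cfg.maf_range, cfg.ld_mode, cfg.seed,
                             cfg.block_r, cfg.block_len, cfg.n_chromosomes,
                             cfg.spacing_bp)
    std = MatrixSource(StandardizedSource(raw).materialize(), raw.snps,
                       standardized=True)
    seeds = _child_seeds(seed, 2 * n_reps)
    p_values: list[float] = []
    estimates: list[float] = []
    n_targets = 0
    for rep in range(n_reps):
        rep_cfg = replace(cfg, seed=int(seeds[2 * rep]))
        y, _ = simulate_phenotype(std, rep_cfg)
        scan = gwas_scan(std, y, threshold=gwas_threshold)
        sig = scan.significant
        if sig.empty:
            continue
        pruned = ld_prune(sig, std)
        targets = pruned.sort_values("p").head(max_targets_per_rep)
        for _, row in targets.iterrows():
            fit = fit_marginal_epistasis(std, y, None, str(row["snp"]),
                                         B=B, seed=int(seeds[2 * rep + 1]))
            k = fit.labels.index(f"gxg_{fit.scope}")
            p_values.append(float(fit.p[k]))
            estimates.append(float(fit.sigma2[k]))
            n_targets += 1
    report: dict = {
        "n_reps": n_reps, "n_targets": n_targets, "seed": seed,
        "p_values": p_values, "gxg_estimates": estimates,
        "rejection_rate_alpha": (float(np.mean(np.array(p_values) < alpha))
                                 if p_values else float("nan")),
        "alpha": alpha,
        "n_significant_genomewide": int(np.sum(np.array(p_values) < gwas_threshold))
        if p_values else 0,
        "full_scale_benchmark_lambda_gc": REFERENCE_FULL_SCALE_LAMBDA_GC,
    }
    if len(p_values) >= 20:
        lam, ci = genomic_inflation(p_values, ci=True, seed=seed)
        report["lambda_gc"] = lam
        report["lambda_gc_ci"] = ci
    return report


def run_power_experiment(sigma2_gxg_grid: Sequence[float], n_reps: int,
                         cfg: SimConfig | None = None, *, seed: int = 0,
                         alpha_list: Sequence[float] = (0.05, 5e-8),
                         B: int = 100, n_boot: int = 2000) -> dict:
    """Power and estimation accuracy over a grid of interaction variances,
    with the target SNP treated as known (the accuracy protocol)."""
    cfg = cfg if cfg is not None else SimConfig(sigma2_g=0.3)
    raw = simulate_genotypes(cfg.N, cfg.M, cfg.maf_range, cfg.ld_mode, cfg.seed,
                             cfg.block_r, cfg.block_len, cfg.n_chromosomes,
                             cfg.spacing_bp)
    std = MatrixSource(StandardizedSource(raw).materialize(), raw.snps,
                       standardized=True)
    rng = np.random.default_rng(seed)
    settings = []
    for s2 in sigma2_gxg_grid:
        seeds = _child_seeds(int(rng.integers(2 ** 31 - 1)), 2 * n_reps)
        pvals = np.empty(n_reps)
        ests = np.empty(n_reps)
        for rep in range(n_reps):
            rep_cfg = replace(cfg, sigma2_gxg=float(s2), sigma2_e=None,
                              seed=int(seeds[2 * rep]))
            y, truth = simulate_phenotype(std, rep_cfg)
            fit = fit_marginal_epistasis(std, y, None, truth.target_index,
                                         B=B, seed=int(seeds[2 * rep + 1]))
            k = fit.labels.index("gxg_genome")
            pvals[rep] = fit.p[k]
            ests[rep] = fit.sigma2[k]
        entry = {"sigma2_gxg": float(s2),
                 "mean_estimate": float(ests.mean()),
                 "bias": float(ests.mean() - s2),
                 "estimate_se": float(ests.std(ddof=1) / np.sqrt(n_reps)),
                 "power": {}}
        boot_rng = np.random.default_rng(seed + 17)
        for a in alpha_list:
            hits = pvals < a
            boots = boot_rng.choice(hits.astype(float), size=(n_boot, n_reps)).mean(axis=1)
            lo, hi = np.quantile(boots, [0.025, 0.975])
            entry["power"][a] = {"estimate": float(hits.mean()),
                                 "ci": (float(lo), float(hi))}
        settings.append(entry)
    return {"settings": settings, "n_reps": n_reps, "seed": seed, "B": B,
            "alpha_list": list(alpha_list)}
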