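"""Randomized Method-of-Moments estimation of marginal-epistasis variance components.

Model: for a standardized genotype panel X (N x M), target SNP t and
interaction design E_t,

    y = X beta + E_t alpha_t + eps,
    beta   ~ N(0, sigma2_g / M),
    alpha_t~ N(0, sigma2_gxg / (M-1)),
    eps    ~ N(0, sigma2_e I),

so Cov(y) = sigma2_g K1 + sigma2_gxg K2 + sigma2_e K3 with K1 = X X^T / M,
K2 = E_t E_t^T / (M-1), K3 = I.  Equating yy^T to its expectation in the
Frobenius norm yields normal equations T sigma2 = q with T_kl = tr(K_k K_l)
and q_k = y^T K_k y.

Traces between two non-identity components are estimated stochastically with
B shared Gaussian probes (Hutchinson): using v^T A A^T B B^T v =
(A A^T v) . (B B^T v), one streaming pass per component accumulates
Z_k Z_k^T V (N x B) from which every pairwise trace follows.  Entries
involving the identity are exact: tr(K_k) = ||Z_k||_F^2 / M_k.  q and the
plug-in Cov[q] are computed exactly; only T carries probe noise.

Standard errors come from the sandwich Cov[sigma2~] = T^-1 Cov[q] T^-1 with
Cov[q]_kl = 2 sum_t sigma2_t~ w_k^T (Z_t Z_t^T / M_t) w_l, w_k = K_k y.
Each component is tested two-sided with z = sigma2~ / SE; negative estimates
are reported and flagged rather than truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

from .genotype_io import GenotypeSource, StandardizedSource, SnpMeta, MHC_REGION
from .preprocessing import (PhenotypeVector, CovariateMatrix, LdBlockMap,
                            inverse_rank_normalize, residualize_covariates,
                            ld_block_for_target, regress_out_ld_block)
from .genotype_io import GenotypeBlock
from .interaction import InteractionSpec, InteractionSource, permute_interaction_rows

__all__ = [
    "ComponentDef", "ProbeSet", "MomEquations", "FameFit",
    "GenotypeColumnSource", "draw_probes", "sketch_component", "assemble_T",
    "compute_q", "solve_normal_equations", "plugin_cov_q", "cov_sigma",
    "test_component", "heritability_fractions", "gwas_h2", "gxg_gwas_ratio",
    "exact_moments_oracle", "fit_marginal_epistasis",
]

CONDITION_LIMIT = 1e12
DENSE_ORACLE_N_CAP = 2000


class GenotypeColumnSource:
    """Adapter exposing a subset of a standardized genotype source as plain
    N x b column blocks for the sketching passes."""

    def __init__(self, std_source: GenotypeSource, keep: Sequence[int] | None = None):
        self.base = std_source
        self.keep = None if keep is None else np.asarray(sorted(set(map(int, keep))))
        self.n_samples = std_source.n_samples
        self.n_columns = std_source.n_snps if self.keep is None else self.keep.size

    def iter_blocks(self) -> Iterator[np.ndarray]:
        for block in self.base.iter_blocks():
            if not block.standardized:
                raise ValueError("column source requires standardized genotypes")
            if self.keep is None:
                yield block.dosage
                continue
            lo, hi = int(block.indices[0]), int(block.indices[-1])
            sel = self.keep[(self.keep >= lo) & (self.keep <= hi)] - lo
            if sel.size:
                yield block.dosage[:, sel]


@dataclass
class ComponentDef:
    """One variance component K_k = Z_k Z_k^T / M_k (identity special-cased)."""

    label: str
    kind: str  # genotype_additive | interaction | identity
    column_source: object | None = None
    divisor: int = 1

    def __post_init__(self) -> None:
        if self.kind == "identity":
            self.divisor = 1
        else:
            if self.column_source is None:
                raise ValueError(f"{self.label}: non-identity component needs columns")
            if self.divisor != self.column_source.n_columns:
                raise ValueError(
                    f"{self.label}: divisor {self.divisor} != column count "
                    f"{self.column_source.n_columns}")


@dataclass
class ProbeSet:
    probe_matrix: np.ndarray  # N x B
    seed: int
    B: int


@dataclass
class ComponentSketch:
    """Streaming aggregates for one component, shared by T, q and Cov[q].

    Stored as N-dimensional quantities (never M_k x B), so memory is O(N B).
    """

    label: str
    divisor: int
    kzv_raw: np.ndarray      # Z_k Z_k^T V, N x B (V itself for identity)
    kzy_raw: np.ndarray      # Z_k Z_k^T y, N     (y for identity)
    zty_sq: float            # ||Z_k^T y||^2      (||y||^2 for identity)
    frob_sq: float           # ||Z_k||_F^2        (N for identity)
    is_identity: bool


@dataclass
class MomEquations:
    T_hat: np.ndarray
    q: np.ndarray
    B: int
    seed: int
    labels: list[str]


@dataclass
class FameFit:
    labels: list[str]
    sigma2: np.ndarray
    cov_sigma2: np.ndarray
    z: np.ndarray
    p: np.ndarray
    negative_flags: np.ndarray
    h2_gxg: float
    h2_additive: float
    B: int
    seed: int
    component_sizes: dict
    scope: str = "genome"
    target_snp: str | None = None
    permuted: bool = False

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_sigma2), 0, None))

    def __getitem__(self, label: str) -> float:
        return float(self.sigma2[self.labels.index(label)])


def draw_probes(N: int, B: int = 100, seed: int = 0,
                distribution: str = "gaussian") -> ProbeSet:
    """B mean-zero, identity-covariance probe vectors, reproducible from seed.

    Gaussian by default; Rademacher available for variance comparisons.
    """
    if N < 1 or B < 1:
        raise ValueError("N and B must be positive")
    rng = np.random.default_rng(seed)
    if distribution == "gaussian":
        v = rng.standard_normal((N, B))
    elif distribution == "rademacher":
        v = rng.integers(0, 2, size=(N, B)).astype(float) * 2 - 1
    else:
        raise ValueError(f"unknown probe distribution {distribution!r}")
    return ProbeSet(v, seed=seed, B=B)


def sketch_component(comp: ComponentDef, probes: ProbeSet,
                     y: np.ndarray) -> ComponentSketch:
    """One streaming pass over Z_k accumulating Z_k Z_k^T V, Z_k Z_k^T y,
    ||Z_k^T y||^2 and ||Z_k||_F^2."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if probes.probe_matrix.shape[0] != n:
        raise ValueError("probes and phenotype have mismatched sample counts")
    if comp.kind == "identity":
        return ComponentSketch(comp.label, 1, probes.probe_matrix, y,
                               float(y @ y), float(n), True)
    kzv = np.zeros((n, probes.B))
    kzy = np.zeros(n)
    zty_sq = 0.0
    frob_sq = 0.0
    for zb in comp.column_source.iter_blocks():
        if zb.shape[0] != n:
            raise ValueError("component block sample count mismatch")
        s = zb.T @ probes.probe_matrix      # b x B
        kzv += zb @ s
        u = zb.T @ y                        # b
        kzy += zb @ u
        zty_sq += float(u @ u)
        frob_sq += float((zb ** 2).sum())
    return ComponentSketch(comp.label, comp.divisor, kzv, kzy, zty_sq, frob_sq, False)


def assemble_T(sketches: Sequence[ComponentSketch], probes: ProbeSet) -> np.ndarray:
    """Normal-equation matrix T with stochastic entries between non-identity
    pairs and exact entries wherever the identity is involved."""
    c = len(sketches)
    T = np.empty((c, c))
    for k in range(c):
        sk = sketches[k]
        for l in range(k, c):
            sl = sketches[l]
            if sk.is_identity and sl.is_identity:
                val = sk.frob_sq  # = N
            elif sk.is_identity:
                val = sl.frob_sq / sl.divisor  # tr(K_l), exact
            elif sl.is_identity:
                val = sk.frob_sq / sk.divisor
            else:
                val = float((sk.kzv_raw * sl.kzv_raw).sum()) / (
                    probes.B * sk.divisor * sl.divisor)
            T[k, l] = T[l, k] = val
    return T


def compute_q(sketches: Sequence[ComponentSketch]) -> np.ndarray:
    """q_k = y^T K_k y = ||Z_k^T y||^2 / M_k, exact (no probe randomness)."""
    return np.array([s.zty_sq / s.divisor for s in sketches])


def solve_normal_equations(T_hat: np.ndarray, q: np.ndarray,
                           labels: Sequence[str] | None = None) -> np.ndarray:
    """Unconstrained solve of T sigma2 = q; negative entries are allowed and
    flagged downstream rather than truncated."""
    cond = np.linalg.cond(T_hat)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        names = list(labels) if labels is not None else list(range(len(q)))
        raise np.linalg.LinAlgError(
            f"normal-equation matrix ill-conditioned (cond={cond:.3g}); "
            f"components {names} are nearly collinear")
    return np.linalg.solve(T_hat, q)


def plugin_cov_q(sketches: Sequence[ComponentSketch],
                 components: Sequence[ComponentDef],
                 sigma2: np.ndarray) -> np.ndarray:
    """Cov[q]_kl = 2 sum_t sigma2_t~ w_k^T (Z_t Z_t^T / M_t) w_l with w_k = K_k y.

    Exact given the plug-in covariance; needs one more streaming pass per
    non-identity component to form Z_t^T W.
    """
    c = len(sketches)
    W = np.column_stack([s.kzy_raw / s.divisor for s in sketches])  # N x C
    cov = np.zeros((c, c))
    for t, (sk_t, comp_t) in enumerate(zip(sketches, components)):
        if sigma2[t] == 0.0:
            continue
        if sk_t.is_identity:
            g = W.T @ W
        else:
            g = np.zeros((c, c))
            for zb in comp_t.column_source.iter_blocks():
                zw = zb.T @ W
                g += zw.T @ zw
            g /= sk_t.divisor
        cov += 2.0 * sigma2[t] * g
    return cov


def cov_sigma(T_hat: np.ndarray, Cov_q: np.ndarray) -> np.ndarray:
    """Sandwich covariance T^-1 Cov[q] T^-1, symmetrized, diagonal clipped at 0."""
    cond = np.linalg.cond(T_hat)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise np.linalg.LinAlgError(f"ill-conditioned T (cond={cond:.3g})")
    Tinv = np.linalg.inv(T_hat)
    out = Tinv @ Cov_q @ Tinv
    out = 0.5 * (out + out.T)
    d = np.diag(out)
    if np.any(d < 0):
        warnings.warn("negative variance on cov_sigma diagonal clipped to 0")
        out[np.diag_indices_from(out)] = np.clip(d, 0, None)
    return out


def test_component(sigma2: np.ndarray, cov_sigma2: np.ndarray,
                   component_index: int) -> tuple[float, float, bool]:
    """Two-sided normal test of H0: sigma2_k = 0.  Returns (z, p, negative_flag)."""
    est = float(sigma2[component_index])
    se = float(np.sqrt(max(cov_sigma2[component_index, component_index], 0.0)))
    if se == 0.0:
        raise ZeroDivisionError("zero standard error; test undefined")
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p, est < 0.0


def heritability_fractions(sigma2: np.ndarray, labels: Sequence[str]
                           ) -> tuple[float, float]:
    """(h2_gxg, h2_additive): each component over the total variance.

    Negative components are floored at 0 in both numerator candidates and the
    denominator (flagged estimates keep their sign in ``sigma2`` itself).
    """
    floored = np.clip(sigma2, 0, None)
    total = float(floored.sum())
    if total <= 0:
        raise ValueError("non-positive total variance; fractions undefined")
    lab = list(labels)
    gxg = sum(floored[i] for i, l in enumerate(lab) if l.startswith("gxg"))
    add = sum(floored[i] for i, l in enumerate(lab) if l.startswith("additive"))
    return gxg / total, add / total


def gwas_h2(beta_standardized: float) -> float:
    """Variance explained by a single SNP: squared standardized GWAS effect."""
    return float(beta_standardized) ** 2


def gxg_gwas_ratio(h2_gxg: float, h2_gwas: float) -> float:
    """Ratio of marginal-epistasis to single-SNP additive variance, from
    unrounded inputs.  Undefined (NaN) when h2_gwas is zero."""
    if h2_gwas == 0:
        return float("nan")
    return h2_gxg / h2_gwas


def exact_moments_oracle(components: Sequence[ComponentDef], y: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense reference: exact T_kl = tr(K_k K_l), q, and plug-in Cov[q] using
    full kernel materialization.  Testing aid; guarded to N <= 2000."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n > DENSE_ORACLE_N_CAP:
        raise MemoryError(f"dense oracle limited to N <= {DENSE_ORACLE_N_CAP}")
    kernels = []
    for comp in components:
        if comp.kind == "identity":
            kernels.append(np.eye(n))
        else:
            z = np.hstack(list(comp.column_source.iter_blocks()))
            kernels.append(z @ z.T / comp.divisor)
    c = len(kernels)
    T = np.array([[np.trace(kernels[k] @ kernels[l]) for l in range(c)]
                  for k in range(c)])
    q = np.array([y @ kernels[k] @ y for k in range(c)])
    sigma2 = np.linalg.solve(T, q)
    Sigma = sum(s * K for s, K in zip(sigma2, kernels))
    # plug-in form 2 y^T K_k Sigma~ K_l y (one Sigma replaced by yy^T),
    # matching what the streaming covariance pass computes
    cov_q = np.array([[2.0 * (y @ kernels[k] @ Sigma @ kernels[l] @ y)
                       for l in range(c)] for k in range(c)])
    return T, q, cov_q


def _mhc_indices(panel: list[SnpMeta]) -> set[int]:
    c, s, e = MHC_REGION
    return {j for j, snp in enumerate(panel)
            if snp.chromosome.removeprefix("chr") == c and s <= snp.position_bp <= e}


def fit_marginal_epistasis(genotypes: GenotypeSource,
                           y: PhenotypeVector,
                           covariates: CovariateMatrix | None,
                           target: int | str,
                           *,
                           B: int = 100,
                           seed: int = 0,
                           scope: str = "genome",
                           ld_blocks: LdBlockMap | None = None,
                           permute: bool = False,
                           rescale_interactions: bool = False,
                           skip_ivrt: bool = False,
                           probe_distribution: str = "gaussian") -> FameFit:
    """Full marginal-epistasis fit for one target SNP.

    Pipeline: inverse-rank normalize -> residualize covariates -> regress out
    the target's LD block -> build the additive component over SNPs outside
    the LD block and the interaction component per scope (excluding the LD
    block, the MHC and the target) -> shared-probe sketches -> normal
    equations -> plug-in sandwich covariance -> two-sided component tests.

    ``genotypes`` must already be QC-filtered; raw dosages are standardized on
    the fly.  Deterministic given ``seed``.
    """
    panel = genotypes.snps
    if isinstance(target, str):
        try:
            t_idx = next(j for j, s in enumerate(panel) if s.snp_id == target)
        except StopIteration:
            raise KeyError(f"target SNP {target!r} not in panel") from None
    else:
        t_idx = int(target)
    t_meta = panel[t_idx]

    std = StandardizedSource(genotypes)

    # Phenotype pipeline.
    if not skip_ivrt and y.transform_tag == "raw":
        y = inverse_rank_normalize(y)
    if covariates is not None:
        y = residualize_covariates(y, covariates)
    else:
        yv = y.values - y.values.mean()
        y = PhenotypeVector(y.sample_ids, yv, "residualized")

    block_idx = ld_block_for_target(t_meta, ld_blocks, panel)
    block_sorted = np.asarray(sorted(block_idx))
    block_cols = std.materialize(block_sorted)
    t_local = int(np.searchsorted(block_sorted, t_idx))
    x_target = block_cols[:, t_local].copy()
    y = regress_out_ld_block(
        y, GenotypeBlock(std.n_samples, [panel[j] for j in block_sorted],
                         block_cols, block_sorted, standardized=True))
    yv = y.values

    # Components.
    additive_keep = [j for j in range(len(panel)) if j not in block_idx]
    if not additive_keep:
        raise ValueError("no SNPs left outside the target's LD block")
    add_src = GenotypeColumnSource(std, additive_keep)
    spec = InteractionSpec(
        target_index=t_idx,
        excluded_indices=frozenset(block_idx) | _mhc_indices(panel) | {t_idx},
        scope=scope,
        rescale_columns=rescale_interactions,
        target_chromosome=t_meta.chromosome)
    e_src = InteractionSource(std, x_target, spec)
    if e_src.n_columns == 0:
        raise ValueError("interaction scope retains no SNPs")
    if permute:
        e_src = permute_interaction_rows(e_src, (seed + 1_000_003) % 2 ** 31)

    components = [
        ComponentDef("additive", "genotype_additive", add_src, add_src.n_columns),
        ComponentDef(f"gxg_{scope}", "interaction", e_src, e_src.n_columns),
        ComponentDef("residual", "identity"),
    ]
    probes = draw_probes(std.n_samples, B=B, seed=seed,
                         distribution=probe_distribution)
    sketches = [sketch_component(c, probes, yv) for c in components]
    T_hat = assemble_T(sketches, probes)
    q = compute_q(sketches)
    labels = [c.label for c in components]
    sigma2 = solve_normal_equations(T_hat, q, labels)
    cov_q = plugin_cov_q(sketches, components, sigma2)
    cs = cov_sigma(T_hat, cov_q)
    zs, ps, flags = zip(*(test_component(sigma2, cs, k) for k in range(len(labels))))
    h2_gxg, h2_add = heritability_fractions(sigma2, labels)
    return FameFit(
        labels=labels, sigma2=sigma2, cov_sigma2=cs,
        z=np.array(zs), p=np.array(ps), negative_flags=np.array(flags),
        h2_gxg=h2_gxg, h2_additive=h2_add, B=B, seed=seed,
        component_sizes={"additive": add_src.n_columns,
                         "interaction": e_src.n_columns,
                         "ld_block": len(block_idx)},
        scope=scope, target_snp=t_meta.snp_id, permuted=permute)
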