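"""Construction of the marginal-epistasis design E_t.

E_t pairs the standardized target genotype x_t with every retained SNP j by
elementwise product: column j of E_t is x_t * x_j.  SNPs in the target's LD
block, the MHC, and the target itself are excluded.  Columns are generated
lazily per genotype block; the full N x (M-1) matrix is never materialized.

By default product columns are used as-is (the interaction-effect prior is
written over that matrix); optional re-centering/re-scaling of product columns
to sum of squares N is available behind ``rescale_columns``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .genotype_io import GenotypeBlock, GenotypeSource

__all__ = ["InteractionSpec", "build_interaction_block",
           "InteractionSource", "permute_interaction_rows"]

SCOPES = ("genome", "local", "distal")


@dataclass
class InteractionSpec:
    target_index: int
    excluded_indices: frozenset[int]
    scope: str = "genome"
    rescale_columns: bool = False
    target_chromosome: str | None = None

    def __post_init__(self) -> None:
        self.excluded_indices = frozenset(self.excluded_indices)
        if self.target_index not in self.excluded_indices:
            raise ValueError("target SNP must be in the exclusion set "
                             "(it never interacts with itself)")
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")
        if self.scope != "genome" and self.target_chromosome is None:
            raise ValueError("local/distal scope requires the target chromosome")

    def retains(self, panel_index: int, chromosome: str) -> bool:
        if panel_index in self.excluded_indices:
            return False
        if self.scope == "local":
            return chromosome == self.target_chromosome
        if self.scope == "distal":
            return chromosome != self.target_chromosome
        return True


def build_interaction_block(x_target: np.ndarray, block: GenotypeBlock,
                            spec: InteractionSpec) -> GenotypeBlock:
    """Product columns x_t * x_j for every SNP j of the block retained by spec."""
    if not block.standardized:
        raise ValueError("interaction columns require standardized genotypes")
    x_target = np.asarray(x_target, dtype=float)
    if x_target.size != block.sample_count:
        raise ValueError("target column length does not match block samples")
    keep = [j for j, snp in enumerate(block.snps)
            if spec.retains(int(block.indices[j]), snp.chromosome)]
    prod = block.dosage[:, keep] * x_target[:, None]
    if spec.rescale_columns and prod.size:
        prod = prod - prod.mean(axis=0)
        scale = np.sqrt((prod ** 2).sum(axis=0) / block.sample_count)
        if np.any(scale == 0):
            raise ValueError("degenerate interaction column under rescaling")
        prod = prod / scale
    return GenotypeBlock(block.sample_count, [block.snps[j] for j in keep],
                         prod, block.indices[keep], standardized=True)


class InteractionSource:
    """Streaming column source for E_t over a standardized genotype source.

    Yields plain arrays (N x b); an optional row permutation is applied to the
    product columns only (not to X or y), the control used to null out genuine
    interaction signal while preserving marginal structure.
    """

    def __init__(self, std_source: GenotypeSource, x_target: np.ndarray,
                 spec: InteractionSpec, row_permutation: np.ndarray | None = None):
        self.base = std_source
        self.x_target = np.asarray(x_target, dtype=float)
        self.spec = spec
        self.row_permutation = row_permutation
        self.n_samples = std_source.n_samples
        self.n_columns = sum(
            1 for j, s in enumerate(std_source.snps) if spec.retains(j, s.chromosome))

    def iter_blocks(self) -> Iterator[np.ndarray]:
        for block in self.base.iter_blocks():
            prod = build_interaction_block(self.x_target, block, self.spec)
            if prod.n_snps == 0:
                continue
            out = prod.dosage
            if self.row_permutation is not None:
                out = out[self.row_permutation, :]
            yield out


def permute_interaction_rows(e_source: InteractionSource, seed: int) -> InteractionSource:
    """Return a copy of the source with one seeded row permutation applied
    consistently to every block."""
    perm = np.random.default_rng(seed).permutation(e_source.n_samples)
    return InteractionSource(e_source.base, e_source.x_target, e_source.spec,
                             row_permutation=perm)
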