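import numpy as np
import pytest

from fame.genotype_io import MatrixSource, SnpMeta, StandardizedSource
from fame.simulator import simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_snps(m, chrom="1", spacing=100_000, start=1):
    return [SnpMeta(f"snp{j}", chrom, start + j * spacing, "A", "G")
            for j in range(m)]


@pytest.fixture
def small_panel():
    """Raw hard-call panel, 200 samples x 40 SNPs."""
    return simulate_genotypes(200, 40, maf_range=(0.1, 0.5), seed=7)


@pytest.fixture
def std_panel(small_panel):
    """Same panel with standardized dosages held in memory."""
    return MatrixSource(StandardizedSource(small_panel).materialize(),
                        small_panel.snps, standardized=True)
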