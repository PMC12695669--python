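"""Streaming PLINK 1 genotype input, QC filtering and standardization.

Genotypes are consumed as a stream of :class:`GenotypeBlock` objects (all N
samples by a bounded number of SNPs), so that downstream variance-component
passes hold at most ``N x block_size`` dosages in memory regardless of panel
size.  Dosages count copies of the bim A1 allele; missing calls are NaN until
imputation.

Standardization uses *population* scaling: each column is mean-centered and
divided by sqrt(mean squared deviation), so its sum of squares is exactly N.
Under this convention tr(X X^T / M) = N, which downstream trace estimators
rely on as an exact identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SnpMeta",
    "GenotypeBlock",
    "QcThresholds",
    "QcReport",
    "GenotypeSource",
    "BedSource",
    "MatrixSource",
    "FilteredSource",
    "StandardizedSource",
    "open_genotypes",
    "apply_qc",
    "standardize_block",
    "write_plink",
]

# Default exclusion: the extended MHC on chromosome 6, 25-35 Mb (1-based inclusive).
MHC_REGION = ("6", 25_000_000, 35_000_000)


@dataclass(frozen=True)
class SnpMeta:
    """Per-SNP metadata; ``maf``/``missing_rate``/``hwe_p`` are filled by QC."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_ref: str
    allele_alt: str
    maf: float = float("nan")
    missing_rate: float = float("nan")
    hwe_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"position_bp must be >= 1, got {self.position_bp}")


@dataclass
class GenotypeBlock:
    """All-samples slice of consecutive SNPs.

    ``dosage`` is N x b; hard calls in {0, 1, 2} with NaN for missing before
    standardization, real-valued afterwards.  ``indices`` are the positions of
    the block's columns in the originating panel.
    """

    sample_count: int
    snps: list[SnpMeta]
    dosage: np.ndarray
    indices: np.ndarray
    standardized: bool = False

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass(frozen=True)
class QcThresholds:
    max_missing: float = 0.01
    min_maf: float = 0.01
    hwe_alpha: float = 1e-7
    exclude_regions: tuple[tuple[str, int, int], ...] = (MHC_REGION,)

    def __post_init__(self) -> None:
        for name in ("max_missing", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for chrom, start, end in self.exclude_regions:
            if start >= end:
                raise ValueError(f"region {chrom}:{start}-{end} has start >= end")


@dataclass
class QcReport:
    n_input_snps: int = 0
    n_pass_snps: int = 0
    n_fail_missing: int = 0
    n_fail_maf: int = 0
    n_fail_hwe: int = 0
    n_fail_region: int = 0


class GenotypeSource:
    """Re-iterable provider of :class:`GenotypeBlock` objects in panel order."""

    snps: list[SnpMeta]
    n_samples: int
    block_size: int

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def iter_blocks(self) -> Iterator[GenotypeBlock]:  # pragma: no cover
        raise NotImplementedError

    def __iter__(self) -> Iterator[GenotypeBlock]:
        return self.iter_blocks()

    def materialize(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """Collect the requested columns (default: all) into a dense array."""
        if indices is None:
            return np.hstack([b.dosage for b in self.iter_blocks()])
        wanted = np.asarray(sorted(set(int(i) for i in indices)))
        out = np.empty((self.n_samples, wanted.size))
        for block in self.iter_blocks():
            lo, hi = block.indices[0], block.indices[-1]
            sel = (wanted >= lo) & (wanted <= hi)
            if sel.any():
                out[:, np.nonzero(sel)[0]] = block.dosage[:, wanted[sel] - lo]
        return out


# --- PLINK 1 binary codec -------------------------------------------------
#
# bed layout: magic 0x6c 0x1b, mode 0x01 (SNP-major), then ceil(N/4) bytes per
# SNP.  Within a byte, sample i occupies bits 2*(i%4)..2*(i%4)+1:
#   00 -> two copies of A1, 01 -> missing, 10 -> het, 11 -> zero copies of A1.

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

_DECODE_TABLE = np.empty((256, 4))
for _byte in range(256):
    for _slot in range(4):
        _DECODE_TABLE[_byte, _slot] = _CODE_TO_DOSAGE[(_byte >> (2 * _slot)) & 0b11]


def _decode_snp(raw: np.ndarray, n_samples: int) -> np.ndarray:
    return _DECODE_TABLE[raw].reshape(-1)[:n_samples]


def _encode_snp(dosage: np.ndarray) -> np.ndarray:
    codes = np.where(np.isnan(dosage), 1, np.select(
        [dosage == 2, dosage == 1, dosage == 0], [0, 2, 3], default=1)).astype(np.uint8)
    pad = (-len(codes)) % 4
    codes = np.concatenate([codes, np.full(pad, 3, dtype=np.uint8)])
    codes = codes.reshape(-1, 4)
    byte = (codes[:, 0] | (codes[:, 1] << 2) | (codes[:, 2] << 4) | (codes[:, 3] << 6))
    return byte.astype(np.uint8)


class BedSource(GenotypeSource):
    """Streaming reader over a PLINK 1 bed/bim/fam trio."""

    def __init__(self, bed_path, bim_path, fam_path, block_size: int = 1024):
        self.bed_path = Path(bed_path)
        self.block_size = int(block_size)
        self.sample_ids: list[str] = []
        with open(fam_path) as fh:
            for line in fh:
                parts = line.split()
                if parts:
                    self.sample_ids.append(parts[1])
        self.n_samples = len(self.sample_ids)
        self.snps = []
        with open(bim_path) as fh:
            for line in fh:
                chrom, snp_id, _cm, pos, a1, a2 = line.split()[:6]
                self.snps.append(SnpMeta(snp_id, chrom, int(pos), allele_ref=a2, allele_alt=a1))
        nbytes = self.bed_path.stat().st_size
        self._bytes_per_snp = (self.n_samples + 3) // 4
        with open(self.bed_path, "rb") as fh:
            if fh.read(3) != _BED_MAGIC:
                raise ValueError(f"{self.bed_path}: not a SNP-major PLINK 1 bed file")
        if nbytes - 3 != self._bytes_per_snp * len(self.snps):
            raise ValueError(
                f"{self.bed_path}: payload of {nbytes - 3} bytes does not match "
                f"{self.n_samples} samples x {len(self.snps)} SNPs")

    def iter_blocks(self) -> Iterator[GenotypeBlock]:
        bs = self.block_size
        with open(self.bed_path, "rb") as fh:
            fh.seek(3)
            for start in range(0, self.n_snps, bs):
                snps = self.snps[start:start + bs]
                raw = np.frombuffer(fh.read(self._bytes_per_snp * len(snps)), dtype=np.uint8)
                raw = raw.reshape(len(snps), self._bytes_per_snp)
                dosage = np.stack(
                    [_decode_snp(raw[j], self.n_samples) for j in range(len(snps))], axis=1)
                yield GenotypeBlock(self.n_samples, list(snps), dosage,
                                    np.arange(start, start + len(snps)))


class MatrixSource(GenotypeSource):
    """In-memory panel exposed through the streaming interface."""

    def __init__(self, dosage: np.ndarray, snps: Sequence[SnpMeta],
                 block_size: int = 1024, standardized: bool = False):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape[1] != len(snps):
            raise ValueError("dosage column count does not match SNP metadata")
        self._dosage = dosage
        self.snps = list(snps)
        self.n_samples = dosage.shape[0]
        self.block_size = int(block_size)
        self.standardized = standardized

    def iter_blocks(self) -> Iterator[GenotypeBlock]:
        for start in range(0, self.n_snps, self.block_size):
            stop = min(start + self.block_size, self.n_snps)
            yield GenotypeBlock(self.n_samples, self.snps[start:stop],
                                self._dosage[:, start:stop], np.arange(start, stop),
                                standardized=self.standardized)


class FilteredSource(GenotypeSource):
    """View of a base source restricted to a subset of SNP indices."""

    def __init__(self, base: GenotypeSource, keep: np.ndarray,
                 snps: Sequence[SnpMeta] | None = None):
        self.base = base
        self.keep = np.asarray(keep, dtype=int)
        base_snps = list(base.snps) if snps is None else list(snps)
        self.snps = [base_snps[i] for i in self.keep] if snps is None else base_snps
        self.n_samples = base.n_samples
        self.block_size = base.block_size

    def iter_blocks(self) -> Iterator[GenotypeBlock]:
        out_pos = 0
        for block in self.base.iter_blocks():
            lo, hi = block.indices[0], block.indices[-1] + 1
            sel = self.keep[(self.keep >= lo) & (self.keep < hi)] - lo
            if sel.size == 0:
                continue
            snps = [self.snps[out_pos + j] for j in range(sel.size)]
            yield GenotypeBlock(block.sample_count, snps, block.dosage[:, sel],
                                np.arange(out_pos, out_pos + sel.size),
                                standardized=block.standardized)
            out_pos += sel.size


class StandardizedSource(GenotypeSource):
    """Applies :func:`standardize_block` to every block of a base source."""

    def __init__(self, base: GenotypeSource):
        self.base = base
        self.snps = base.snps
        self.n_samples = base.n_samples
        self.block_size = base.block_size

    def iter_blocks(self) -> Iterator[GenotypeBlock]:
        for block in self.base.iter_blocks():
            yield block if block.standardized else standardize_block(block)


def open_genotypes(bed_path, bim_path, fam_path, block_size: int = 1024) -> BedSource:
    """Open a PLINK 1 trio for block-wise streaming in bim order."""
    return BedSource(bed_path, bim_path, fam_path, block_size=block_size)


def _snp_stats(col: np.ndarray) -> tuple[float, float, float]:
    """(maf, missing_rate, hwe_p) from one hard-call dosage column."""
    miss = np.isnan(col)
    obs = col[~miss]
    n_obs = obs.size
    missing_rate = miss.mean() if col.size else 1.0
    if n_obs == 0:
        return 0.0, 1.0, 1.0
    freq = obs.sum() / (2 * n_obs)
    maf = min(freq, 1 - freq)
    # 1-df chi-square HWE test on genotype counts, no continuity correction.
    n2 = int((obs == 2).sum())
    n1 = int((obs == 1).sum())
    n0 = n_obs - n1 - n2
    exp = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq ** 2]) * n_obs
    if freq in (0.0, 1.0):
        hwe_p = 1.0
    else:
        chi2 = float(np.sum((np.array([n0, n1, n2]) - exp) ** 2 / exp))
        hwe_p = float(stats.chi2.sf(chi2, df=1))
    return float(maf), float(missing_rate), hwe_p


def _in_region(snp: SnpMeta, regions) -> bool:
    return any(snp.chromosome == c and s <= snp.position_bp <= e for c, s, e in regions)


def apply_qc(source: GenotypeSource,
             thresholds: QcThresholds = QcThresholds()) -> tuple[GenotypeSource, QcReport]:
    """Filter SNPs by missingness, MAF, HWE and region, in that fixed order.

    Each SNP is counted against the first rule it fails, so the report is
    reproducible regardless of block boundaries.
    """
    report = QcReport(n_input_snps=source.n_snps)
    keep: list[int] = []
    kept_meta: list[SnpMeta] = []
    for block in source.iter_blocks():
        if block.standardized:
            raise ValueError("QC must run on raw (unstandardized) dosages")
        for j, snp in enumerate(block.snps):
            maf, miss, hwe_p = _snp_stats(block.dosage[:, j])
            if miss > thresholds.max_missing:
                report.n_fail_missing += 1
            elif maf < thresholds.min_maf:
                report.n_fail_maf += 1
            elif hwe_p < thresholds.hwe_alpha:
                report.n_fail_hwe += 1
            elif _in_region(snp, thresholds.exclude_regions):
                report.n_fail_region += 1
            else:
                keep.append(int(block.indices[j]))
                kept_meta.append(replace(snp, maf=maf, missing_rate=miss, hwe_p=hwe_p))
    report.n_pass_snps = len(keep)
    if not keep:
        raise ValueError("QC removed every SNP in the panel")
    filtered = FilteredSource(source, np.array(keep))
    filtered.snps = kept_meta
    return filtered, report


def standardize_block(block: GenotypeBlock) -> GenotypeBlock:
    """Mean-impute missing calls, then center and scale each column to sum of
    squares N (population scaling)."""
    x = block.dosage.astype(float, copy=True)
    n = block.sample_count
    col_mean = np.nanmean(x, axis=0)
    miss = np.isnan(x)
    if miss.any():
        x[miss] = np.broadcast_to(col_mean, x.shape)[miss]
    x -= x.mean(axis=0)
    scale = np.sqrt((x ** 2).sum(axis=0) / n)
    if np.any(scale == 0):
        bad = [block.snps[j].snp_id for j in np.nonzero(scale == 0)[0]]
        raise ValueError(f"zero-variance column(s) after imputation: {bad}")
    x /= scale
    return GenotypeBlock(n, block.snps, x, block.indices, standardized=True)


def write_plink(prefix, dosage: np.ndarray, snps: Sequence[SnpMeta],
                sample_ids: Sequence[str] | None = None) -> tuple[Path, Path, Path]:
    """Write hard-call dosages (NaN = missing) as a PLINK 1 bed/bim/fam trio."""
    prefix = Path(prefix)
    n, m = dosage.shape
    if m != len(snps):
        raise ValueError("dosage column count does not match SNP metadata")
    if sample_ids is None:
        sample_ids = [f"iid{i}" for i in range(n)]
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(m):
            fh.write(_encode_snp(dosage[:, j]).tobytes())
    with open(bim, "w") as fh:
        for s in snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\t{s.allele_alt}\t{s.allele_ref}\n")
    with open(fam, "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    return bed, bim, fam
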