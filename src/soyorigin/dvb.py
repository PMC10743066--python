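"""Dense-variation-block segmentation and InDel candidate discovery.

Soybean chromosomes partition into sparse variation blocks (sVBs), nearly
monomorphic between cultivars, and dense variation blocks (dVBs) where SNPs
cluster at ~100 kb scale. Markers for allele-specific PCR are drawn from
InDels inside dVBs, where cultivars actually differ. This module tiles a
chromosome into fixed windows, classes each window by SNP density against a
threshold, merges adjacent same-class windows into blocks, and extracts
qualifying InDel candidates from the dense blocks.

Coordinates: VCF input is 1-based; all intervals here are 0-based
half-open, so a variant at VCF position p falls in the window whose
half-open interval contains p - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000  # bp; the characteristic dVB scale

SNP = "SNP"
INDEL = "InDel"
DVB = "dVB"
SVB = "sVB"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"variant position must be >= 1, got {self.pos}")

    @property
    def type(self) -> str:
        return INDEL if len(self.ref) != len(self.alt) else SNP

    @property
    def indel_length(self) -> int:
        """Absolute allele-length difference (0 for SNPs)."""
        return abs(len(self.ref) - len(self.alt))


@dataclass(frozen=True)
class VariationBlock:
    chrom: str
    start: int  # 0-based half-open
    end: int
    block_class: str  # dVB or sVB
    variant_density: float  # variants per kb

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("block end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class WindowDensity:
    chrom: str
    start: int
    end: int
    density: float  # variants per kb


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read biallelic records from a VCF (plain or bgzipped).

    Multiallelic records are skipped with a logged count; split them
    upstream (e.g. ``bcftools norm -m-``) to keep them.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    n_multi = 0
    vcf = VCF(str(path))
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        records.append(
            VariantRecord(chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0])
        )
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multiallelic records in %s", n_multi, path)
    return records


def window_density(
    variants: Sequence[VariantRecord],
    chrom_length: int,
    window: int = DEFAULT_WINDOW,
    count: str = "snp",
) -> list[WindowDensity]:
    """Tile one chromosome into fixed windows and measure variant density.

    The chromosome [0, chrom_length) is cut into consecutive ``window``-bp
    tiles (the last may be shorter). Density is the count of SNPs (default;
    ``count='all'`` includes InDels) divided by the tile length in kb.
    """
    if window <= 0:
        raise InputError("window must be positive")
    if chrom_length <= 0:
        raise InputError("chrom_length must be positive")
    chroms = {v.chrom for v in variants}
    if len(chroms) > 1:
        raise InputError(f"variants span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else ""
    kept = [v for v in variants if count == "all" or v.type == SNP]
    positions = np.array([v.pos for v in kept], dtype=np.int64)
    if positions.size and positions.max() > chrom_length:
        raise InputError(
            f"variant at {positions.max()} beyond chromosome end {chrom_length}"
        )

    edges = list(range(0, chrom_length, window)) + [chrom_length]
    counts = np.histogram(positions - 1, bins=edges)[0] if positions.size else (
        np.zeros(len(edges) - 1, dtype=np.int64)
    )
    out = []
    for (start, end), n in zip(zip(edges[:-1], edges[1:]), counts):
        out.append(
            WindowDensity(
                chrom=chrom, start=start, end=end,
                density=float(n) / ((end - start) / 1000.0),
            )
        )
    return out


def segment_blocks(
    densities: Sequence[WindowDensity],
    threshold: float,
) -> list[VariationBlock]:
    """Class windows as dVB (density >= threshold) or sVB and merge runs.

    Adjacent same-class windows merge into one block carrying the
    length-weighted mean density; blocks tile the chromosome exactly.
    """
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    blocks: list[VariationBlock] = []
    run: list[WindowDensity] = []

    def flush() -> None:
        if not run:
            return
        total = sum(w.end - w.start for w in run)
        mean_density = sum(w.density * (w.end - w.start) for w in run) / total
        blocks.append(
            VariationBlock(
                chrom=run[0].chrom,
                start=run[0].start,
                end=run[-1].end,
                block_class=DVB if run[0].density >= threshold else SVB,
                variant_density=mean_density,
            )
        )

    for w in densities:
        if run and ((w.density >= threshold) != (run[0].density >= threshold)):
            flush()
            run = []
        run.append(w)
    flush()
    return blocks


def two_means_threshold(densities: Sequence[WindowDensity]) -> float:
    """Data-driven density cutoff from the dVB/sVB bimodality.

    Exact 1-D two-means split of log(density + pseudocount) over all
    windows; returns the midpoint of the two cluster means mapped back to
    density units. The pseudocount is half a variant per window so empty
    windows participate.
    """
    if len(densities) < 2:
        raise InputError("need at least two windows to split")
    window_kb = (densities[0].end - densities[0].start) / 1000.0
    eps = 0.5 / window_kb
    x = np.sort(np.log([w.density + eps for w in densities]))
    # exact 1-D 2-means: best split point by within-cluster SSE
    csum = np.cumsum(x)
    total = csum[-1]
    n = len(x)
    best_sse, best_k = np.inf, 1
    sq = np.cumsum(x**2)
    for k in range(1, n):
        left_mean = csum[k - 1] / k
        right_mean = (total - csum[k - 1]) / (n - k)
        sse = (sq[k - 1] - k * left_mean**2) + (
            (sq[-1] - sq[k - 1]) - (n - k) * right_mean**2
        )
        if sse < best_sse:
            best_sse, best_k = sse, k
    mid = 0.5 * (csum[best_k - 1] / best_k + (total - csum[best_k - 1]) / (n - best_k))
    return float(np.exp(mid) - eps)


def select_indel_candidates(
    blocks: Sequence[VariationBlock],
    variants: Sequence[VariantRecord],
    min_len: int = 5,
    max_len: int = 50,
) -> list[VariantRecord]:
    """InDels inside dVBs with allele-length difference in [min_len, max_len].

    These are the marker candidates: long enough for a robust allele-specific
    PCR product difference, short enough to amplify cleanly. Output is sorted
    by (chrom, pos) and independent of input order.
    """
    if min_len < 1:
        raise InputError("min_len must be >= 1")
    if max_len < min_len:
        raise InputError("max_len must be >= min_len")
    dvbs: dict[str, list[VariationBlock]] = {}
    for b in blocks:
        if b.block_class == DVB:
            dvbs.setdefault(b.chrom, []).append(b)
    out = [
        v
        for v in variants
        if v.type == INDEL
        and min_len <= v.indel_length <= max_len
        and any(b.contains(v.pos) for b in dvbs.get(v.chrom, []))
    ]
    return sorted(out, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


def write_bed(blocks: Iterable[VariationBlock], path: str | Path) -> None:
    """Write blocks as BED5-style lines: chrom start end class density."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_class}\t"
                f"{b.variant_density:.4f}\n"
            )


def dvb_fraction_recovered(
    truth_blocks: Sequence[tuple[int, int]],
    called_blocks: Sequence[VariationBlock],
) -> float:
    """Fraction of planted dVB length covered by called dVBs (evaluation aid)."""
    total = sum(e - s for s, e in truth_blocks)
    if total == 0:
        return 1.0
    covered = 0
    for s, e in truth_blocks:
        for b in called_blocks:
            if b.block_class == DVB:
                covered += max(0, min(e, b.end) - max(s, b.start))
    return covered / total
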