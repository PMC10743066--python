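"""Synthetic study data: variety fingerprints, noisy grain profiles, lots, VCFs.

No grain-level genotype data from the reference collection is deposited, so
the pipeline is exercised on simulated inputs shaped like the study design:
a set of variety fingerprints (binary marker patterns) per origin, per-grain
amplification profiles copied from a fingerprint with PCR dropout /
false-amplification noise, 24-grain lots of pure or admixed origin, and
block-structured VCFs with alternating SNP-dense and SNP-sparse segments
carrying planted InDels.

The generator targets the assay's combinatorics, not soybean breeding
history: fingerprints are independent draws, with no linkage or pedigree
structure.

Every sub-generator derives its own RNG stream from the one config seed and
a fixed stream id, so adding draws to one stage never shifts another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError
from .panel import (
    AmplificationProfile,
    MarkerPanel,
    load_default_panel,
    profile_from_value,
)

_STREAMS = {"varieties": 1, "noise": 2, "lots": 3, "vcf": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the reference collection: 53 domestic and 70 foreign
    distinct fingerprints (the numbers of distinct judgment values observed
    per origin), ~10 grains per variety (the reference tables average
    630/53 ≈ 12 and 466/70 ≈ 7 samples per value), 24-grain lots, and
    low-but-nonzero per-marker assay noise.
    """

    seed: int = 0
    n_domestic_varieties: int = 53
    n_foreign_varieties: int = 70
    samples_per_variety: int = 10
    dropout_rate: float = 0.01
    false_amp_rate: float = 0.01
    lot_size: int = 24
    mixture_fraction: float = 0.2
    marker_presence: float = 0.5  # P(marker amplifies) for markers 2..n
    force_separable: bool = False

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "false_amp_rate", "mixture_fraction",
                     "marker_presence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be a probability, got {v}")
        if self.lot_size < 1:
            raise InputError("lot_size must be >= 1")


def generate_varieties(
    config: SimulationConfig, panel: MarkerPanel | None = None
) -> list[AmplificationProfile]:
    """Draw one fingerprint per variety; marker 1 is always present.

    With ``force_separable`` the domestic and foreign judgment-value sets are
    disjoint and values are distinct within each origin, so a noiseless
    population is perfectly classifiable. Only 2^(n-1) distinct fingerprints
    exist with the control fixed true (1024 for the 11-marker panel).
    """
    panel = panel or load_default_panel()
    n_dom, n_for = config.n_domestic_varieties, config.n_foreign_varieties
    if n_dom < 0 or n_for < 0 or n_dom + n_for < 1:
        raise InputError("need at least one variety")
    capacity = 2 ** (panel.size - 1)
    rng = _rng(config.seed, "varieties")
    free_scores = np.array(panel.scores[1:], dtype=np.int64)

    def draw_value() -> int:
        mask = rng.random(panel.size - 1) < config.marker_presence
        return 1 + int(free_scores[mask].sum())

    varieties: list[AmplificationProfile] = []
    if config.force_separable:
        if n_dom + n_for > capacity:
            raise InputError(
                f"{n_dom + n_for} distinct varieties requested but only "
                f"{capacity} distinct fingerprints exist"
            )
        seen: set[int] = set()
        values: list[int] = []
        # rejection sampling keeps the per-marker presence distribution
        while len(values) < n_dom + n_for:
            v = draw_value()
            if v not in seen:
                seen.add(v)
                values.append(v)
    else:
        values = [draw_value() for _ in range(n_dom + n_for)]

    for i, value in enumerate(values):
        origin = "domestic" if i < n_dom else "imported"
        name = f"{'dom' if i < n_dom else 'for'}_var{i if i < n_dom else i - n_dom:03d}"
        varieties.append(
            profile_from_value(
                value, panel, sample_id=name, origin_label=origin, variety=name
            )
        )
    return varieties


def _apply_noise(
    calls: np.ndarray, rng: np.random.Generator, config: SimulationConfig
) -> np.ndarray:
    """Flip markers 2..n: present->absent at dropout_rate, absent->present at
    false_amp_rate. Marker 1 (the control) never flips."""
    out = calls.copy()
    u = rng.random(calls.size - 1)
    body = calls[1:]
    flip = np.where(body, u < config.dropout_rate, u < config.false_amp_rate)
    out[1:] = body ^ flip
    return out


def generate_population(
    varieties: Sequence[AmplificationProfile],
    config: SimulationConfig,
) -> list[AmplificationProfile]:
    """Per-grain profiles: ``samples_per_variety`` noisy copies of each fingerprint."""
    rng = _rng(config.seed, "noise")
    samples: list[AmplificationProfile] = []
    for var in varieties:
        base = np.array(var.calls, dtype=bool)
        for j in range(config.samples_per_variety):
            calls = _apply_noise(base, rng, config)
            samples.append(
                AmplificationProfile(
                    sample_id=f"{var.variety}_g{j:03d}",
                    calls=tuple(bool(c) for c in calls),
                    origin_label=var.origin_label,
                    variety=var.variety,
                )
            )
    return samples


@dataclass(frozen=True)
class SimulatedLot:
    lot_id: str
    true_label: str  # domestic | foreign | mixed
    grains: tuple[AmplificationProfile, ...]


def generate_lots(
    varieties: Sequence[AmplificationProfile],
    config: SimulationConfig,
    n_pure_domestic: int = 5,
    n_pure_foreign: int = 5,
    n_mixed: int = 5,
) -> list[SimulatedLot]:
    """Simulate grain lots: pure single-origin lots and admixed lots.

    A mixed lot draws each grain from the foreign pool with probability
    ``mixture_fraction``, else from the domestic pool; each grain picks a
    variety uniformly within its pool and then passes through assay noise.
    """
    rng = _rng(config.seed, "lots")
    dom = [v for v in varieties if v.origin_label == "domestic"]
    forn = [v for v in varieties if v.origin_label in ("imported", "foreign")]
    if (n_pure_domestic or n_mixed) and not dom:
        raise InputError("no domestic varieties available")
    if (n_pure_foreign or n_mixed) and not forn:
        raise InputError("no foreign varieties available")

    lots: list[SimulatedLot] = []

    def make_lot(lot_id: str, label: str) -> SimulatedLot:
        grains = []
        for g in range(config.lot_size):
            if label == "mixed":
                pool = forn if rng.random() < config.mixture_fraction else dom
            else:
                pool = dom if label == "domestic" else forn
            var = pool[rng.integers(len(pool))]
            calls = _apply_noise(np.array(var.calls, dtype=bool), rng, config)
            grains.append(
                AmplificationProfile(
                    sample_id=f"{lot_id}_g{g:02d}",
                    calls=tuple(bool(c) for c in calls),
                    origin_label=var.origin_label,
                    variety=var.variety,
                )
            )
        return SimulatedLot(lot_id=lot_id, true_label=label, grains=tuple(grains))

    for i in range(n_pure_domestic):
        lots.append(make_lot(f"lot_dom{i:02d}", "domestic"))
    for i in range(n_pure_foreign):
        lots.append(make_lot(f"lot_for{i:02d}", "foreign"))
    for i in range(n_mixed):
        lots.append(make_lot(f"lot_mix{i:02d}", "mixed"))
    return lots


# ---------------------------------------------------------------------------
# Block-structured VCF simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VcfTruth:
    """Ground truth of a simulated chromosome: planted blocks and InDels."""

    chrom: str
    chrom_length: int
    dvb_intervals: tuple[tuple[int, int], ...]  # 0-based half-open
    indel_positions: tuple[int, ...]  # 1-based, qualifying InDels inside dVBs


def generate_vcf(
    chrom_length: int,
    dvb_layout: Sequence[tuple[int, int]],
    snp_density_dvb: float,
    snp_density_svb: float,
    indels_per_dvb: int,
    seed: int,
    chrom: str = "Chr01",
    indel_len_range: tuple[int, int] = (5, 30),
    decoy_indels_per_svb: int = 2,
) -> tuple[str, VcfTruth]:
    """Write a biallelic VCF with planted dense blocks and InDels.

    SNPs are placed as a homogeneous Poisson process at ``snp_density_dvb``
    (per kb) inside the dVB intervals and ``snp_density_svb`` elsewhere.
    Each dVB receives ``indels_per_dvb`` qualifying InDels with length drawn
    uniformly from ``indel_len_range``; each sVB gap receives
    ``decoy_indels_per_svb`` 1-bp InDels that a [min_len, max_len] filter
    must reject. Returns the VCF text and the truth record. A fixed seed
    gives byte-identical output.
    """
    if chrom_length <= 0:
        raise InputError("chrom_length must be positive")
    for s, e in dvb_layout:
        if not 0 <= s < e <= chrom_length:
            raise InputError(f"bad dVB interval ({s}, {e})")
    ordered = sorted(dvb_layout)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise InputError("dVB intervals overlap")

    rng = _rng(seed, "vcf")
    # complementary sVB gaps
    svb_gaps: list[tuple[int, int]] = []
    cursor = 0
    for s, e in ordered:
        if s > cursor:
            svb_gaps.append((cursor, s))
        cursor = e
    if cursor < chrom_length:
        svb_gaps.append((cursor, chrom_length))

    taken: set[int] = set()

    def place(n: int, start: int, end: int) -> list[int]:
        out = []
        for _ in range(n):
            for _attempt in range(1000):
                p = int(rng.integers(start, end)) + 1  # 1-based
                if p not in taken:
                    taken.add(p)
                    out.append(p)
                    break
        return out

    records: list[tuple[int, str, str]] = []

    def random_base() -> str:
        return str(_BASES[rng.integers(4)])

    def random_seq(n: int) -> str:
        return "".join(_BASES[rng.integers(4, size=n)])

    def add_snp(pos: int) -> None:
        ref = random_base()
        alt = str(_BASES[(np.flatnonzero(_BASES != ref))[rng.integers(3)]])
        records.append((pos, ref, alt))

    def add_indel(pos: int, length: int) -> None:
        anchor = random_base()
        if rng.random() < 0.5:  # insertion
            records.append((pos, anchor, anchor + random_seq(length)))
        else:  # deletion
            records.append((pos, anchor + random_seq(length), anchor))

    for (start, end), density in [
        *(((s, e), snp_density_dvb) for s, e in ordered),
        *(((s, e), snp_density_svb) for s, e in svb_gaps),
    ]:
        n_snps = int(rng.poisson(density * (end - start) / 1000.0))
        for pos in place(n_snps, start, end):
            add_snp(pos)

    indel_positions: list[int] = []
    lo, hi = indel_len_range
    for s, e in ordered:
        for pos in place(indels_per_dvb, s, e):
            add_indel(pos, int(rng.integers(lo, hi + 1)))
            indel_positions.append(pos)
    for s, e in svb_gaps:
        for pos in place(min(decoy_indels_per_svb, e - s), s, e):
            add_indel(pos, 1)

    records.sort(key=lambda r: r[0])
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={chrom_length}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    lines += [
        f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t." for pos, ref, alt in records
    ]
    truth = VcfTruth(
        chrom=chrom,
        chrom_length=chrom_length,
        dvb_intervals=tuple(ordered),
        indel_positions=tuple(sorted(indel_positions)),
    )
    return "\n".join(lines) + "\n", truth
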