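"""Qualitative performance statistics of the discrimination table.

The classifier is qualitative (PCR band present/absent), so its performance
is summarised the way qualitative food-assay validation does:

    sensitivity = TD / (TD + FD) * 100
    selectivity = TF / (TF + FF) * 100
    efficiency  = (TD + TF) / (TD + FD + TF + FF) * 100

where TD counts domestic reference samples the table recovers as domestic,
FD domestic samples it fails to recover (their value overlaps both origins),
and TF/FF symmetrically for foreign samples. Efficiency is therefore the
count-weighted mean of sensitivity and selectivity. Predictive rates apply
the same arithmetic to an independent validation set.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import InputError, UndefinedMetricError
from .tables import DiscriminationTable, find_overlaps


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed report precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TD/FD tallies for domestic samples, TF/FF for imported ones.

    TD + FD is the number of domestic reference samples; TF + FF the number
    of imported ones. FD and FF are the samples stuck at unresolved overlap
    values — failures of the assay on their own true side.
    """

    TD: int
    FD: int
    TF: int
    FF: int

    def __post_init__(self) -> None:
        if min(self.TD, self.FD, self.TF, self.FF) < 0:
            raise InputError("confusion counts must be non-negative")


def confusion_from_table(table: DiscriminationTable) -> ConfusionCounts:
    """Tally the table's own reference samples against its classifications.

    A sample at a value unique to its origin is correctly recovered; a sample
    at an unresolved overlap value cannot be called and counts as a failure
    on its own side. Morphology-resolved values count as recovered on both
    sides, since the registered external evidence settles each sample.
    """
    overlaps = find_overlaps(table)
    dom_total = table.total_count("domestic")
    for_total = table.total_count("foreign")
    fd = sum(
        e.duplicate_count
        for v, e in table.domestic_entries.items()
        if v in overlaps
    )
    ff = sum(
        e.duplicate_count
        for v, e in table.foreign_entries.items()
        if v in overlaps
    )
    return ConfusionCounts(TD=dom_total - fd, FD=fd, TF=for_total - ff, FF=ff)


def sensitivity(c: ConfusionCounts, ndigits: int = 1) -> float:
    """Percentage of domestic samples recovered as domestic."""
    if c.TD + c.FD == 0:
        raise UndefinedMetricError("no domestic samples: sensitivity undefined")
    return round_half_up(100.0 * c.TD / (c.TD + c.FD), ndigits)


def selectivity(c: ConfusionCounts, ndigits: int = 1) -> float:
    """Percentage of imported samples recovered as foreign."""
    if c.TF + c.FF == 0:
        raise UndefinedMetricError("no imported samples: selectivity undefined")
    return round_half_up(100.0 * c.TF / (c.TF + c.FF), ndigits)


def efficiency(c: ConfusionCounts, ndigits: int = 1) -> float:
    """Overall percentage of samples recovered on their true side."""
    total = c.TD + c.FD + c.TF + c.FF
    if total == 0:
        raise UndefinedMetricError("no samples: efficiency undefined")
    return round_half_up(100.0 * (c.TD + c.TF) / total, ndigits)


@dataclass(frozen=True)
class PerformanceSummary:
    sensitivity: float
    selectivity: float
    efficiency: float


def summarize(c: ConfusionCounts, ndigits: int = 1) -> PerformanceSummary:
    return PerformanceSummary(
        sensitivity=sensitivity(c, ndigits),
        selectivity=selectivity(c, ndigits),
        efficiency=efficiency(c, ndigits),
    )


def predictive_rates(
    domestic_correct: int,
    domestic_total: int,
    foreign_correct: int,
    foreign_total: int,
    ndigits: int = 1,
) -> tuple[float, float, float]:
    """Validation-set rates: (domestic %, foreign %, overall %)."""
    if domestic_total <= 0 or foreign_total <= 0:
        raise UndefinedMetricError("validation totals must be positive")
    if domestic_correct > domestic_total or foreign_correct > foreign_total:
        raise InputError("correct counts cannot exceed totals")
    dom = round_half_up(100.0 * domestic_correct / domestic_total, ndigits)
    forn = round_half_up(100.0 * foreign_correct / foreign_total, ndigits)
    overall = round_half_up(
        100.0 * (domestic_correct + foreign_correct)
        / (domestic_total + foreign_total),
        ndigits,
    )
    return dom, forn, overall


@dataclass(frozen=True)
class OverlapStats:
    """How much of the table the origin-ambiguous values occupy."""

    n_overlap_values: int
    value_fraction: float  # % of the union of distinct judgment values
    n_undetermined_samples: int
    sample_fraction: float  # % of all reference samples


def overlap_stats(table: DiscriminationTable, ndigits: int = 1) -> OverlapStats:
    """Fraction of values and of samples left undetermined by overlaps.

    The value denominator is the union of distinct judgment values across
    both origins (shared values counted once), the sample denominator the
    total reference collection size.
    """
    overlaps = find_overlaps(table)
    n_values = len(table.distinct_values())
    n_samples = table.total_count("domestic") + table.total_count("foreign")
    undetermined = sum(
        table.entries(origin)[v].duplicate_count
        for origin in ("domestic", "foreign")
        for v in overlaps
        if v in table.entries(origin)
    )
    return OverlapStats(
        n_overlap_values=len(overlaps),
        value_fraction=(
            round_half_up(100.0 * len(overlaps) / n_values, ndigits) if n_values else 0.0
        ),
        n_undetermined_samples=undetermined,
        sample_fraction=(
            round_half_up(100.0 * undetermined / n_samples, ndigits) if n_samples else 0.0
        ),
    )
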