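"""Grain-level sampling statistics for soybean lots.

A lot (a 200 g retail or port sample) is assayed by genotyping a fixed
number of individual grains — 24 by default, the count needed for 95%
confidence of catching an admixed minority at realistic contamination
levels. This module gives the detection power of an n-grain draw, the
minimum grain count for a target reliability, and the aggregation of grain
verdicts into a lot verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import hypergeom

from .errors import InputError
from .tables import Classification, Verdict

DEFAULT_LOT_SIZE = 24
DEFAULT_CONFIDENCE = 0.95


def detection_power(
    n_grains: int,
    contaminant_fraction: float,
    lot_size: int | None = None,
) -> float:
    """Probability that >= 1 contaminant grain appears among ``n_grains``.

    Under independent draws this is 1 - (1 - p)^n. Pass ``lot_size`` to use
    the finite-lot hypergeometric instead (contaminant count rounded to the
    nearest grain), relevant only when the lot is not much larger than the
    draw.
    """
    if n_grains < 1:
        raise InputError("n_grains must be >= 1")
    if not 0.0 <= contaminant_fraction <= 1.0:
        raise InputError("contaminant_fraction must be in [0, 1]")
    if lot_size is None:
        return 1.0 - (1.0 - contaminant_fraction) ** n_grains
    if n_grains > lot_size:
        raise InputError("cannot draw more grains than the lot holds")
    n_bad = round(contaminant_fraction * lot_size)
    return float(hypergeom.sf(0, lot_size, n_bad, n_grains))


def min_grains(
    contaminant_fraction: float,
    confidence: float = DEFAULT_CONFIDENCE,
) -> int:
    """Smallest n with detection_power(n, p) >= confidence.

    Closed form ceil(log(1-confidence) / log(1-p)) under independent draws;
    e.g. a contaminant fraction of ~11.75% needs 24 grains at 95%.
    """
    if not 0.0 < contaminant_fraction <= 1.0:
        raise InputError("contaminant_fraction must be in (0, 1]; p=0 needs infinite n")
    if not 0.0 < confidence < 1.0:
        raise InputError("confidence must be in (0, 1)")
    if contaminant_fraction == 1.0:
        return 1
    n = math.ceil(math.log(1.0 - confidence) / math.log(1.0 - contaminant_fraction))
    n = max(n, 1)
    # guard against float edge cases right at the boundary
    while detection_power(n, contaminant_fraction) < confidence:
        n += 1
    while n > 1 and detection_power(n - 1, contaminant_fraction) >= confidence:
        n -= 1
    return n


@dataclass(frozen=True)
class LotResult:
    lot_id: str
    grain_classifications: tuple[Classification, ...]
    lot_verdict: str  # domestic | foreign | mixed | undetermined
    n_informative: int


_INFORMATIVE = {Verdict.DOMESTIC, Verdict.FOREIGN}


def aggregate_lot(
    grains: Sequence[Classification], lot_id: str = ""
) -> LotResult:
    """Fold grain verdicts into a lot verdict.

    All informative grains domestic -> domestic; all foreign -> foreign;
    both present -> mixed; no informative grain (every grain undetermined,
    unknown or invalid) -> undetermined.
    """
    if not grains:
        raise InputError("a lot needs at least one grain classification")
    informative = [g.verdict for g in grains if g.verdict in _INFORMATIVE]
    if not informative:
        verdict = "undetermined"
    elif all(v is Verdict.DOMESTIC for v in informative):
        verdict = "domestic"
    elif all(v is Verdict.FOREIGN for v in informative):
        verdict = "foreign"
    else:
        verdict = "mixed"
    return LotResult(
        lot_id=lot_id,
        grain_classifications=tuple(grains),
        lot_verdict=verdict,
        n_informative=len(informative),
    )
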