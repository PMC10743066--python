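"""Marker panel definition and judgment-value encoding.

The assay genotypes each grain with a panel of allele-specific PCR markers
whose amplification is a binary call. Marker 1 targets an endogenous soybean
gene and acts as the assay-validity control (score 1); every further marker k
scores 2^(k-1). The *judgment value* of a grain is the sum of scores of all
amplified markers — a binary fingerprint packed into one odd integer in
[1, 2^m - 1] for an m-marker panel. The mapping between amplification
profiles and judgment values is bijective, so the value can always be
decoded back into the exact marker subset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, InputError, NotSoybeanError

_DNA_RE = re.compile(r"^[ACGT]+$")

DOMESTIC = "domestic"
IMPORTED = "imported"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class Marker:
    """One allele-specific PCR marker of the panel."""

    index: int
    score: int
    amplicon_size: int
    multiplex_set: str
    forward_primer: str
    reverse_primer: str
    final_conc: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise InputError(f"marker index must be >= 1, got {self.index}")
        expected = 1 if self.index == 1 else 2 ** (self.index - 1)
        if self.score != expected:
            raise InputError(
                f"marker {self.index} must score {expected}, got {self.score}"
            )
        if self.amplicon_size <= 0:
            raise InputError("amplicon size must be positive")
        for primer in (self.forward_primer, self.reverse_primer):
            if not _DNA_RE.match(primer):
                raise InputError(f"primer is not a plain A/C/G/T string: {primer!r}")


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered marker panel; marker 1 is the mandatory endogenous control."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        indices = [m.index for m in self.markers]
        if indices != list(range(1, len(indices) + 1)):
            raise InputError(f"marker indices must be 1..n in order, got {indices}")
        scores = [m.score for m in self.markers]
        if any(b <= a for a, b in zip(scores, scores[1:])):
            raise InputError("marker scores must be strictly increasing")

    @property
    def size(self) -> int:
        return len(self.markers)

    @property
    def scores(self) -> tuple[int, ...]:
        return tuple(m.score for m in self.markers)

    @property
    def max_value(self) -> int:
        return sum(self.scores)

    @property
    def multiplex_sets(self) -> dict[str, list[int]]:
        """Mapping multiplex-set label -> marker indices co-amplified in one PCR."""
        sets: dict[str, list[int]] = {}
        for m in self.markers:
            sets.setdefault(m.multiplex_set, []).append(m.index)
        return sets

    @classmethod
    def from_file(cls, path: str | Path) -> "MarkerPanel":
        """Load a panel from a delimited definition file.

        Columns: ``set, marker, final_conc, forward, reverse, size`` (any
        whitespace/tab delimited; rows may appear in multiplex-set order).
        """
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"set", "marker", "final_conc", "forward", "reverse", "size"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"panel file missing columns: {sorted(missing)}")
        markers = []
        for row in df.itertuples(index=False):
            idx = int(row.marker)
            markers.append(
                Marker(
                    index=idx,
                    score=1 if idx == 1 else 2 ** (idx - 1),
                    amplicon_size=int(row.size),
                    multiplex_set=str(row.set),
                    forward_primer=str(row.forward).strip().upper(),
                    reverse_primer=str(row.reverse).strip().upper(),
                    final_conc=float(row.final_conc),
                )
            )
        markers.sort(key=lambda m: m.index)
        return cls(markers=tuple(markers))


def load_default_panel() -> MarkerPanel:
    """The packaged 11-marker soybean origin panel (multiplex sets A-F)."""
    with resources.as_file(
        resources.files("soyorigin.data").joinpath("panel_markers.tsv")
    ) as p:
        return MarkerPanel.from_file(p)


@dataclass(frozen=True)
class AmplificationProfile:
    """One grain's binary amplification calls across the panel."""

    sample_id: str
    calls: tuple[bool, ...]
    origin_label: str | None = None
    variety: str | None = None

    @property
    def is_soybean(self) -> bool:
        """True iff the endogenous control (marker 1) amplified."""
        return bool(self.calls) and self.calls[0]


def encode_judgment_value(profile: AmplificationProfile, panel: MarkerPanel) -> int:
    """Sum the scores of all amplified markers into the judgment value.

    Raises
    ------
    NotSoybeanError
        If marker 1 did not amplify (the sample fails the assay gate).
    InputError
        If the call count does not match the panel size.
    """
    if len(profile.calls) != panel.size:
        raise InputError(
            f"profile {profile.sample_id!r} has {len(profile.calls)} calls, "
            f"panel has {panel.size} markers"
        )
    if not profile.is_soybean:
        raise NotSoybeanError(profile.sample_id)
    return sum(s for s, c in zip(panel.scores, profile.calls) if c)


def decode_judgment_value(value: int, panel: MarkerPanel) -> set[int]:
    """Invert the encoding: return the marker-index subset summing to ``value``.

    Scores are distinct powers of two, so the decomposition is the binary
    expansion and is unique; ``encode(decode(v)) == v`` for every valid v.
    """
    if not isinstance(value, int) or isinstance(value, bool):
        raise InputError(f"judgment value must be an integer, got {value!r}")
    if value < 1 or value > panel.max_value:
        raise InputError(
            f"judgment value {value} out of range [1, {panel.max_value}]"
        )
    if value % 2 == 0:
        raise InputError(
            f"judgment value {value} is even: marker 1 (score 1) missing, "
            "so the sample would not be soybean"
        )
    remainder = value
    members: set[int] = set()
    for marker in reversed(panel.markers):
        if marker.score <= remainder:
            remainder -= marker.score
            members.add(marker.index)
    if remainder != 0:  # unreachable for power-of-two panels; guards odd configs
        raise InputError(f"value {value} is not representable by the panel scores")
    return members


def profile_from_value(
    value: int,
    panel: MarkerPanel,
    sample_id: str = "",
    origin_label: str | None = None,
    variety: str | None = None,
) -> AmplificationProfile:
    """Build the amplification profile whose judgment value is ``value``."""
    members = decode_judgment_value(value, panel)
    calls = tuple(m.index in members for m in panel.markers)
    return AmplificationProfile(
        sample_id=sample_id, calls=calls, origin_label=origin_label, variety=variety
    )


def pattern_capacity(panel: MarkerPanel) -> int:
    """Number of theoretical binary amplification patterns: 2^m for m markers.

    The packaged 11-marker panel distinguishes 2048 patterns (half of which —
    the odd judgment values — correspond to valid soybean samples).
    """
    return 2 ** panel.size


@dataclass(frozen=True)
class MultiplexViolation:
    set_label: str
    marker_a: int
    marker_b: int
    gap_bp: int


def validate_multiplex(panel: MarkerPanel, margin: int = 20) -> list[MultiplexViolation]:
    """Check that co-amplified markers have separable amplicon sizes.

    Markers in one multiplex set are resolved on a gel by product size, so
    every pairwise size difference within a set must be at least ``margin``
    base pairs (default 20; the packaged panel's smallest gap is 26 bp).
    """
    if margin <= 0:
        raise InputError("margin must be positive")
    by_index = {m.index: m for m in panel.markers}
    violations: list[MultiplexViolation] = []
    for label, indices in sorted(panel.multiplex_sets.items()):
        for i, a in enumerate(indices):
            for b in indices[i + 1:]:
                gap = abs(by_index[a].amplicon_size - by_index[b].amplicon_size)
                if gap < margin:
                    violations.append(MultiplexViolation(label, a, b, gap))
    return violations


# ---------------------------------------------------------------------------
# Profile files: one row per grain, sample_id / origin / variety / m1..mN 0/1
# ---------------------------------------------------------------------------

def read_profiles(path: str | Path, n_markers: int = 11) -> list[AmplificationProfile]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    call_cols = [f"m{i}" for i in range(1, n_markers + 1)]
    missing = {"sample_id", *call_cols} - set(df.columns)
    if missing:
        raise FormatError(f"profile file missing columns: {sorted(missing)}")
    profiles = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        raw = [d[c] for c in call_cols]
        if not all(v in ("0", "1") for v in raw):
            raise FormatError(
                f"sample {d['sample_id']!r}: calls must be 0/1, got {raw}"
            )
        profiles.append(
            AmplificationProfile(
                sample_id=d["sample_id"],
                calls=tuple(v == "1" for v in raw),
                origin_label=d.get("origin") or None,
                variety=d.get("variety") or None,
            )
        )
    return profiles


def write_profiles(
    profiles: Iterable[AmplificationProfile], path: str | Path, n_markers: int = 11
) -> None:
    rows = []
    for p in profiles:
        row = {
            "sample_id": p.sample_id,
            "origin": p.origin_label or "",
            "variety": p.variety or "",
        }
        row.update({f"m{i + 1}": int(c) for i, c in enumerate(p.calls)})
        rows.append(row)
    cols = ["sample_id", "origin", "variety"] + [f"m{i}" for i in range(1, n_markers + 1)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
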