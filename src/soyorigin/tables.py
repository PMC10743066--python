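"""Origin discrimination tables and membership-based classification.

A discrimination table records, per origin (domestic vs foreign), the set of
judgment values observed in a labeled reference collection together with the
number of samples carrying each value. Classification of a new sample is pure
set membership: a value seen only among domestic references is called
domestic, only among foreign references foreign. A value observed on both
sides is an *overlap* — the genetic assay alone cannot resolve it, unless
external evidence (seed morphology) is registered for that value, in which
case a per-sample morphology call decides the side.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import panel as panel_mod
from .errors import FormatError, InputError, NotSoybeanError
from .panel import AmplificationProfile, MarkerPanel, load_default_panel

DOMESTIC = "domestic"
FOREIGN = "foreign"

_LABEL_TO_ORIGIN = {"domestic": DOMESTIC, "imported": FOREIGN, "foreign": FOREIGN}


class Verdict(enum.Enum):
    DOMESTIC = "domestic"
    FOREIGN = "foreign"
    UNDETERMINED_OVERLAP = "undetermined_overlap"
    UNKNOWN_VALUE = "unknown_value"
    INVALID_SAMPLE = "invalid_sample"


@dataclass(frozen=True)
class TableEntry:
    """One judgment value of one origin with its observed multiplicity."""

    judgment_value: int
    origin: str
    duplicate_count: int
    variety_note: str = ""

    def __post_init__(self) -> None:
        if self.origin not in (DOMESTIC, FOREIGN):
            raise InputError(f"origin must be domestic/foreign, got {self.origin!r}")
        if self.duplicate_count < 0:
            raise InputError("duplicate_count must be >= 0")
        if self.judgment_value < 1 or self.judgment_value % 2 == 0:
            raise InputError(
                f"judgment value must be odd and >= 1, got {self.judgment_value}"
            )


@dataclass(frozen=True)
class Classification:
    judgment_value: int | None
    verdict: Verdict
    note: str = ""


@dataclass
class DiscriminationTable:
    """Origin-labeled judgment-value sets with duplicate counts.

    ``resolved_values`` marks overlap values for which external (morphology)
    evidence is accepted: a sample at such a value is classified by its
    per-sample morphology hint instead of being left undetermined.
    """

    domestic_entries: dict[int, TableEntry] = field(default_factory=dict)
    foreign_entries: dict[int, TableEntry] = field(default_factory=dict)
    resolved_values: set[int] = field(default_factory=set)

    def entries(self, origin: str) -> dict[int, TableEntry]:
        if origin == DOMESTIC:
            return self.domestic_entries
        if origin == FOREIGN:
            return self.foreign_entries
        raise InputError(f"unknown origin {origin!r}")

    def total_count(self, origin: str) -> int:
        return sum(e.duplicate_count for e in self.entries(origin).values())

    def distinct_values(self) -> set[int]:
        """Union of judgment values observed in either origin."""
        return set(self.domestic_entries) | set(self.foreign_entries)

    def with_resolved(self, values: Iterable[int]) -> "DiscriminationTable":
        """Copy of the table with ``values`` marked as morphology-resolved."""
        return DiscriminationTable(
            domestic_entries=dict(self.domestic_entries),
            foreign_entries=dict(self.foreign_entries),
            resolved_values=set(self.resolved_values) | set(values),
        )


def build_table(
    profiles: Sequence[AmplificationProfile], panel: MarkerPanel
) -> DiscriminationTable:
    """Tally labeled reference profiles into a discrimination table.

    Every profile must carry an origin label (domestic or imported/foreign)
    and pass the marker-1 gate; offending sample ids are reported together.
    """
    unlabeled = [p.sample_id for p in profiles if _origin_of(p) is None]
    if unlabeled:
        raise InputError(f"profiles without origin label: {unlabeled}")
    not_soy = [p.sample_id for p in profiles if not p.is_soybean]
    if not_soy:
        raise NotSoybeanError(", ".join(not_soy))

    table = DiscriminationTable()
    notes: dict[tuple[str, int], list[str]] = {}
    counts: dict[tuple[str, int], int] = {}
    for p in profiles:
        origin = _origin_of(p)
        value = panel_mod.encode_judgment_value(p, panel)
        key = (origin, value)
        counts[key] = counts.get(key, 0) + 1
        if p.variety and p.variety not in notes.setdefault(key, []):
            notes[key].append(p.variety)
    for (origin, value), count in counts.items():
        table.entries(origin)[value] = TableEntry(
            judgment_value=value,
            origin=origin,
            duplicate_count=count,
            variety_note="/".join(notes.get((origin, value), [])),
        )
    return table


def _origin_of(profile: AmplificationProfile) -> str | None:
    label = (profile.origin_label or "").strip().lower()
    return _LABEL_TO_ORIGIN.get(label)


def find_overlaps(table: DiscriminationTable) -> set[int]:
    """Judgment values observed in both origins and not externally resolved."""
    both = set(table.domestic_entries) & set(table.foreign_entries)
    return both - table.resolved_values


def classify(
    value: int,
    table: DiscriminationTable,
    morphology_hint: str | None = None,
) -> Classification:
    """Classify a judgment value by table membership.

    ``morphology_hint`` ('domestic'/'foreign') is consulted only for values in
    ``table.resolved_values``; it is the per-sample seed-morphology call that
    the genetic assay cannot make itself.
    """
    if not isinstance(value, int) or isinstance(value, bool) or value < 1 or value % 2 == 0:
        raise InputError(f"invalid judgment value {value!r}")
    in_dom = value in table.domestic_entries
    in_for = value in table.foreign_entries
    if in_dom and in_for:
        if value in table.resolved_values:
            hint = _LABEL_TO_ORIGIN.get((morphology_hint or "").strip().lower())
            if hint == DOMESTIC:
                return Classification(value, Verdict.DOMESTIC, "resolved by morphology")
            if hint == FOREIGN:
                return Classification(value, Verdict.FOREIGN, "resolved by morphology")
            return Classification(
                value, Verdict.UNDETERMINED_OVERLAP, "resolvable, no morphology call"
            )
        return Classification(value, Verdict.UNDETERMINED_OVERLAP)
    if in_dom:
        return Classification(value, Verdict.DOMESTIC)
    if in_for:
        return Classification(value, Verdict.FOREIGN)
    return Classification(value, Verdict.UNKNOWN_VALUE)


def classify_profile(
    profile: AmplificationProfile,
    table: DiscriminationTable,
    panel: MarkerPanel,
    morphology_hint: str | None = None,
) -> Classification:
    """Encode a profile then classify; marker-1-negative grains are invalid."""
    try:
        value = panel_mod.encode_judgment_value(profile, panel)
    except NotSoybeanError:
        return Classification(None, Verdict.INVALID_SAMPLE, "marker 1 negative")
    return classify(value, table, morphology_hint=morphology_hint)


def reduce_panel(
    table: DiscriminationTable,
    dropped_markers: Iterable[int],
    panel: MarkerPanel,
) -> DiscriminationTable:
    """Project the table onto a reduced panel by dropping markers.

    Each judgment value loses the scores of dropped markers present in its
    decomposition; entries whose projected values collide merge, with their
    duplicate counts summed and variety notes concatenated. Marker 1 (the
    endogenous control) can never be dropped.
    """
    dropped = set(dropped_markers)
    if 1 in dropped:
        raise InputError("marker 1 is the mandatory endogenous control; cannot drop")
    bad = dropped - {m.index for m in panel.markers}
    if bad:
        raise InputError(f"markers not in panel: {sorted(bad)}")
    drop_mask = sum(m.score for m in panel.markers if m.index in dropped)

    reduced = DiscriminationTable()
    for origin in (DOMESTIC, FOREIGN):
        merged: dict[int, list[TableEntry]] = {}
        for entry in table.entries(origin).values():
            new_value = entry.judgment_value - (entry.judgment_value & drop_mask)
            merged.setdefault(new_value, []).append(entry)
        for new_value in sorted(merged):
            group = sorted(merged[new_value], key=lambda e: e.judgment_value)
            notes = [e.variety_note for e in group if e.variety_note]
            reduced.entries(origin)[new_value] = TableEntry(
                judgment_value=new_value,
                origin=origin,
                duplicate_count=sum(e.duplicate_count for e in group),
                variety_note="/".join(notes),
            )
    reduced.resolved_values = {
        v - (v & drop_mask) for v in table.resolved_values
    }
    return reduced


# ---------------------------------------------------------------------------
# Table files: one row per judgment value, explicit per-marker score columns
# ---------------------------------------------------------------------------

def read_table(
    path_or_paths: str | Path | Sequence[str | Path],
    panel: MarkerPanel | None = None,
) -> DiscriminationTable:
    """Read discrimination-table file(s) into one table.

    Each row carries the judgment value, one score column per marker (empty =
    marker absent), the duplicate count, the origin and an optional note. The
    score columns must re-sum to the value column — a transcription checksum.
    """
    panel = panel or load_default_panel()
    if isinstance(path_or_paths, (str, Path)):
        paths: Sequence[str | Path] = [path_or_paths]
    else:
        paths = list(path_or_paths)

    table = DiscriminationTable()
    score_cols = [f"m{i}" for i in range(1, panel.size + 1)]
    for path in paths:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
        missing = {"judgment_value", "duplicate_count", "origin", *score_cols} - set(
            df.columns
        )
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for row in df.itertuples(index=False):
            d = row._asdict()
            value = int(d["judgment_value"])
            bits = sum(int(d[c]) for c in score_cols if d[c].strip())
            if bits != value:
                raise FormatError(
                    f"{path}: marker columns sum to {bits} but judgment value "
                    f"column says {value}"
                )
            origin = _LABEL_TO_ORIGIN.get(d["origin"].strip().lower())
            if origin is None:
                raise FormatError(f"{path}: unknown origin {d['origin']!r}")
            if value in table.entries(origin):
                raise FormatError(
                    f"{path}: duplicate judgment value {value} within origin {origin}"
                )
            table.entries(origin)[value] = TableEntry(
                judgment_value=value,
                origin=origin,
                duplicate_count=int(d["duplicate_count"]),
                variety_note=d.get("note", "").strip(),
            )
    return table


def write_table(
    table: DiscriminationTable, path: str | Path, panel: MarkerPanel | None = None
) -> None:
    """Write a table in the same schema ``read_table`` accepts (lossless)."""
    panel = panel or load_default_panel()
    rows = []
    for origin in (DOMESTIC, FOREIGN):
        for value in sorted(table.entries(origin)):
            entry = table.entries(origin)[value]
            row = {"judgment_value": value}
            for m in panel.markers:
                row[f"m{m.index}"] = m.score if value & m.score else ""
            row["duplicate_count"] = entry.duplicate_count
            row["origin"] = origin
            row["note"] = entry.variety_note
            rows.append(row)
    cols = (
        ["judgment_value"]
        + [f"m{i}" for i in range(1, panel.size + 1)]
        + ["duplicate_count", "origin", "note"]
    )
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        if table.resolved_values:
            fh.write(f"# resolved_values: {sorted(table.resolved_values)}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_resolved_header(path: str | Path) -> set[int]:
    with open(path) as fh:
        for line in fh:
            if line.startswith("# resolved_values:"):
                inner = line.split(":", 1)[1].strip().strip("[]")
                return {int(v) for v in inner.split(",") if v.strip()}
            if not line.startswith("#"):
                break
    return set()


def read_table_with_resolved(
    path: str | Path, panel: MarkerPanel | None = None
) -> DiscriminationTable:
    table = read_table(path, panel=panel)
    table.resolved_values = _read_resolved_header(path)
    return table


def load_default_tables() -> DiscriminationTable:
    """The packaged reference tables: 630 domestic + 466 imported samples."""
    files = resources.files("soyorigin.data")
    with resources.as_file(files.joinpath("discrimination_domestic.tsv")) as dom, \
            resources.as_file(files.joinpath("discrimination_foreign.tsv")) as forn:
        return read_table([dom, forn])


def load_standard_samples() -> list[AmplificationProfile]:
    """The 16 standard varieties (15 Korean + Williams 82) as profiles."""
    files = resources.files("soyorigin.data")
    panel = load_default_panel()
    profiles = []
    with resources.as_file(files.joinpath("standard_samples.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for row in df.itertuples(index=False):
        d = row._asdict()
        calls = tuple(bool(d[f"m{i}"].strip()) for i in range(1, panel.size + 1))
        profiles.append(
            AmplificationProfile(
                sample_id=d["variety"],
                calls=calls,
                origin_label=d["origin"],
                variety=d["variety"],
            )
        )
    return profiles


def load_standard_values() -> dict[str, int]:
    """Variety -> printed judgment value for the 16 standard samples."""
    files = resources.files("soyorigin.data")
    with resources.as_file(files.joinpath("standard_samples.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return {r.variety: int(r.judgment_value) for r in df.itertuples(index=False)}
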