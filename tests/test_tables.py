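"""Discrimination-table construction, overlap handling, classification, reduction."""

import pytest

from soyorigin import (
    AmplificationProfile,
    DiscriminationTable,
    FormatError,
    InputError,
    NotSoybeanError,
    TableEntry,
    Verdict,
    build_table,
    classify,
    classify_profile,
    find_overlaps,
    profile_from_value,
    read_table,
    reduce_panel,
    write_table,
)
from soyorigin.tables import read_table_with_resolved

OVERLAPS = {671, 1183, 1215, 1695}


def expand_profiles(table, panel):
    """Replay a table as the per-sample profile list that produced it."""
    label = {"domestic": "domestic", "foreign": "imported"}
    out = []
    for origin in ("domestic", "foreign"):
        for value, entry in table.entries(origin).items():
            for k in range(entry.duplicate_count):
                out.append(
                    profile_from_value(
                        value, panel,
                        sample_id=f"{origin}_{value}_{k}",
                        origin_label=label[origin],
                    )
                )
    return out


class TestPackagedTables:
    def test_structure(self, reference_tables):
        """53 domestic / 70 foreign distinct values; 630 / 466 samples."""
        t = reference_tables
        assert len(t.domestic_entries) == 53
        assert len(t.foreign_entries) == 70
        assert t.total_count("domestic") == 630
        assert t.total_count("foreign") == 466

    def test_overlaps(self, reference_tables):
        assert find_overlaps(reference_tables) == OVERLAPS

    def test_morphology_resolution_removes_value(self, reference_tables):
        resolved = reference_tables.with_resolved([1215])
        assert find_overlaps(resolved) == OVERLAPS - {1215}
        # the original table is untouched
        assert find_overlaps(reference_tables) == OVERLAPS


class TestBuildTable:
    def test_rebuild_from_replayed_profiles(self, reference_tables, panel):
        """Tallying the per-sample replay reproduces the packaged table."""
        rebuilt = build_table(expand_profiles(reference_tables, panel), panel)
        for origin in ("domestic", "foreign"):
            want = {
                v: e.duplicate_count
                for v, e in reference_tables.entries(origin).items()
                if e.duplicate_count > 0
            }
            got = {
                v: e.duplicate_count for v, e in rebuilt.entries(origin).items()
            }
            assert got == want

    def test_empty_input(self, panel):
        t = build_table([], panel)
        assert t.domestic_entries == {} and t.foreign_entries == {}

    def test_unlabeled_profile_rejected(self, panel):
        p = profile_from_value(189, panel, sample_id="x")
        with pytest.raises(InputError, match="x"):
            build_table([p], panel)

    def test_marker1_negative_rejected_with_ids(self, panel):
        bad = AmplificationProfile(
            sample_id="ghost", calls=(False,) * 11, origin_label="domestic"
        )
        with pytest.raises(NotSoybeanError, match="ghost"):
            build_table([bad], panel)


class TestClassify:
    @pytest.mark.parametrize(
        "value, verdict",
        [
            (189, Verdict.DOMESTIC),  # Sinhwa's value, domestic only
            (2047, Verdict.FOREIGN),  # Williams82
            (671, Verdict.UNDETERMINED_OVERLAP),
            (3, Verdict.UNKNOWN_VALUE),  # never observed in either origin
        ],
    )
    def test_verdicts(self, reference_tables, value, verdict):
        assert classify(value, reference_tables).verdict is verdict

    def test_every_value_gets_exactly_one_verdict(self, reference_tables):
        for value in range(1, 2048, 2):
            assert classify(value, reference_tables).verdict in Verdict

    def test_resolved_value_needs_morphology_hint(self, reference_tables):
        t = reference_tables.with_resolved([1215])
        assert classify(1215, t).verdict is Verdict.UNDETERMINED_OVERLAP
        assert classify(1215, t, morphology_hint="domestic").verdict is Verdict.DOMESTIC
        assert classify(1215, t, morphology_hint="foreign").verdict is Verdict.FOREIGN
        # hints are ignored for ordinary overlap values
        assert (
            classify(671, t, morphology_hint="domestic").verdict
            is Verdict.UNDETERMINED_OVERLAP
        )

    def test_invalid_value_rejected(self, reference_tables):
        with pytest.raises(InputError):
            classify(188, reference_tables)

    def test_profile_classification_gates_on_control(self, reference_tables, panel):
        bad = AmplificationProfile(sample_id="x", calls=(False,) + (True,) * 10)
        assert (
            classify_profile(bad, reference_tables, panel).verdict
            is Verdict.INVALID_SAMPLE
        )


class TestReducePanel:
    def test_identity_when_nothing_dropped(self, reference_tables, panel):
        r = reduce_panel(reference_tables, set(), panel)
        for origin in ("domestic", "foreign"):
            assert r.entries(origin) == reference_tables.entries(origin)

    def test_toy_value_projection(self, panel):
        # 1563 contains score 1024 (marker 11); dropping it leaves 539
        t = DiscriminationTable(
            domestic_entries={1563: TableEntry(1563, "domestic", 2)}
        )
        r = reduce_panel(t, {11}, panel)
        assert set(r.domestic_entries) == {539}
        assert r.domestic_entries[539].duplicate_count == 2

    def test_counts_conserved(self, reference_tables, panel):
        for dropped in ({11}, {2, 11}, {5, 7, 9}):
            r = reduce_panel(reference_tables, dropped, panel)
            assert r.total_count("domestic") == 630
            assert r.total_count("foreign") == 466

    def test_distinct_values_never_increase(self, reference_tables, panel):
        r = reduce_panel(reference_tables, {11}, panel)
        assert len(r.domestic_entries) <= 53
        assert len(r.foreign_entries) <= 70

    def test_merged_counts_equal_preimage_sums(self, reference_tables, panel):
        """Brute-force preimage enumeration agrees with the merge."""
        r = reduce_panel(reference_tables, {11}, panel)
        for origin in ("domestic", "foreign"):
            for new_value, entry in r.entries(origin).items():
                preimage = sum(
                    e.duplicate_count
                    for v, e in reference_tables.entries(origin).items()
                    if v - (v & 1024) == new_value
                )
                assert entry.duplicate_count == preimage

    def test_overlap_image_contained_in_reduced_overlaps(
        self, reference_tables, panel
    ):
        r = reduce_panel(reference_tables, {11}, panel)
        projected = {v - (v & 1024) for v in find_overlaps(reference_tables)}
        assert projected <= find_overlaps(r)

    def test_control_marker_cannot_be_dropped(self, reference_tables, panel):
        with pytest.raises(InputError):
            reduce_panel(reference_tables, {1, 11}, panel)


class TestTableIO:
    def test_write_then_read_round_trip(self, reference_tables, panel, tmp_path):
        path = tmp_path / "table.tsv"
        t = reference_tables.with_resolved([1215])
        write_table(t, path, panel=panel)
        back = read_table_with_resolved(path, panel=panel)
        for origin in ("domestic", "foreign"):
            assert back.entries(origin) == t.entries(origin)
        assert back.resolved_values == {1215}

    def test_inconsistent_marker_columns_rejected(self, tmp_path, panel):
        path = tmp_path / "bad.tsv"
        header = "judgment_value\t" + "\t".join(f"m{i}" for i in range(1, 12)) + (
            "\tduplicate_count\torigin\tnote"
        )
        # columns sum to 25, value column claims 27
        row = "27\t1\t\t\t8\t16\t\t\t\t\t\t\t3\tdomestic\t"
        path.write_text(header + "\n" + row + "\n")
        with pytest.raises(FormatError, match="sum"):
            read_table(path, panel=panel)

    def test_duplicate_value_within_origin_rejected(self, tmp_path, panel):
        path = tmp_path / "dup.tsv"
        header = "judgment_value\t" + "\t".join(f"m{i}" for i in range(1, 12)) + (
            "\tduplicate_count\torigin\tnote"
        )
        row = "25\t1\t\t\t8\t16\t\t\t\t\t\t\t3\tdomestic\t"
        path.write_text(header + "\n" + row + "\n" + row + "\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_table(path, panel=panel)
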