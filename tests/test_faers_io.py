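from pathlib import Path

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal.errors import ConfigurationError, SchemaError
from pvsignal.faers_io import (
    CaseReport,
    DrugEntry,
    FaersDate,
    build_case_reports,
    deduplicate,
    filter_primary_suspect,
    load_quarter_reports,
    normalize_age,
    parse_quarter,
    read_deleted_caseids,
    write_quarter,
)

from conftest import write_quarter as write_test_quarter


def _report(caseid="1", version=1, primaryid=None, receipt=None, drugs=None, reactions=("PT_A",)):
    return CaseReport(
        primaryid=primaryid or f"{caseid}{version}",
        caseid=caseid,
        caseversion=version,
        receipt_date=receipt,
        drugs=tuple(drugs or [DrugEntry("SOMEDRUG", role="PS")]),
        reactions=tuple(reactions),
    )


class TestParsing:
    def test_two_record_demo_file(self, tmp_path):
        paths = write_test_quarter(
            tmp_path,
            {
                "demo": ["11$1$1$20230101$60$YR$F$55$MD$US$20230201",
                         "21$2$1$20230102$$$M$$CN$JP$20230202"],
                "drug": ["11$1$1$PS$TERIPARATIDE$TERIPARATIDE$SUBCUTANEOUS",
                         "21$2$1$PS$OTHERDRUG$$ORAL"],
                "reac": ["11$1$Back pain", "21$2$Nausea"],
            },
        )
        raw = parse_quarter(paths, quarter_label="2023Q1")
        assert len(raw.demo) == 2
        assert raw.issues.total == 0
        reports = build_case_reports(raw)
        assert len(reports) == 2
        assert reports[0].sex == "F" and reports[0].reporter_occupation == "PHYSICIAN"

    def test_all_four_role_codes_map_to_enum(self, tmp_path):
        paths = write_test_quarter(
            tmp_path,
            {
                "demo": ["11$1$1$$$$F$$$US$20230201"],
                "drug": [f"11$1${i}${role}$D{i}$$" for i, role in enumerate(["PS", "SS", "C", "I"], 1)],
                "reac": ["11$1$Nausea"],
            },
        )
        (report,) = build_case_reports(parse_quarter(paths))
        assert [d.role for d in report.drugs] == ["PS", "SS", "C", "I"]

    def test_short_row_counted_and_excluded(self, tmp_path):
        paths = write_test_quarter(
            tmp_path,
            {
                "demo": ["11$1$1$$$$F$$$US$20230201"],
                "drug": ["11$1$1$PS$GOODDRUG$$", "11$1$2$SS"],  # second row too short
                "reac": ["11$1$Nausea"],
            },
        )
        raw = parse_quarter(paths)
        assert raw.issues.counts["malformed_row"] == 1
        assert len(raw.drug) == 1

    def test_missing_mandatory_column_names_it(self, tmp_path):
        bad = tmp_path / "DEMOX.txt"
        bad.write_text("primaryid$caseid\n11$1\n")
        paths = write_test_quarter(tmp_path, {})
        paths["demo"] = bad
        with pytest.raises(SchemaError, match="caseversion"):
            parse_quarter(paths)

    def test_unknown_dialect_rejected(self, tmp_path):
        paths = write_test_quarter(tmp_path, {})
        with pytest.raises(ConfigurationError, match="laers"):
            parse_quarter(paths, schema="laers")

    def test_reaction_count_conservation(self, small_corpus):
        """Every REAC row of a surviving report becomes exactly one reaction."""
        _, paths, _ = small_corpus
        raw = parse_quarter(Path(paths["demo"]).parent)
        reports = build_case_reports(raw)
        surviving = {r.primaryid for r in reports}
        reac_rows = sum(
            1 for pid in raw.reac["primaryid"].astype(str) if pid in surviving
        )
        assert sum(len(r.reactions) for r in reports) == reac_rows

    def test_round_trip_preserves_case_reports(self, small_corpus, tmp_path):
        _, paths, _ = small_corpus
        raw = parse_quarter(Path(paths["demo"]).parent)
        first = build_case_reports(raw)
        rewritten = write_quarter(raw, tmp_path, quarter_suffix="RT")
        second = build_case_reports(parse_quarter(rewritten))
        assert first == second


class TestNormalizeAge:
    @pytest.mark.parametrize(
        "value,code,expected",
        [
            (720, "MON", 60.0),
            (7.2, "DEC", 72.0),
            (2000, "YR", None),       # out of range
            (30, "", 30.0),           # empty code treated as years
            (104, "WK", 2.0),
            (730.5, "DY", 2.0),
            (8766, "HR", 1.0),
            (-5, "YR", None),
            ("abc", "YR", None),
            ("", "YR", None),
        ],
    )
    def test_unit_conversion(self, value, code, expected):
        result = normalize_age(value, code)
        if expected is None:
            assert result is None
        else:
            assert result == pytest.approx(expected)


class TestDeduplicate:
    def test_highest_caseversion_wins(self):
        v1, v2 = _report("7", 1), _report("7", 2)
        assert deduplicate([v1, v2]) == [v2]
        assert deduplicate([v2, v1]) == [v2]

    def test_deleted_caseid_removed_entirely(self):
        assert deduplicate([_report("7", 1), _report("7", 2)], {"7"}) == []

    def test_tie_breaks_receipt_date_then_primaryid(self):
        early = _report("7", 1, primaryid="71", receipt=FaersDate(2023, 1, 1))
        late = _report("7", 1, primaryid="70", receipt=FaersDate(2023, 6, 1))
        assert deduplicate([early, late]) == [late]
        a = _report("7", 1, primaryid="71", receipt=FaersDate(2023, 1, 1))
        b = _report("7", 1, primaryid="72", receipt=FaersDate(2023, 1, 1))
        assert deduplicate([a, b]) == [b]

    def test_empty_input(self):
        assert deduplicate([]) == []

    @given(
        st.lists(
            st.tuples(st.integers(1, 20), st.integers(1, 3), st.integers(0, 1000)),
            max_size=40,
        )
    )
    def test_idempotent_and_never_grows(self, spec):
        reports = [
            _report(str(cid), ver, primaryid=str(pid * 100 + i))
            for i, (cid, ver, pid) in enumerate(spec)
        ]
        once = deduplicate(reports)
        assert len(once) <= len(reports)
        assert deduplicate(once) == once
        assert len({r.caseid for r in once}) == len(once)

    def test_manifest_duplicate_removal(self, small_corpus):
        _, paths, manifest = small_corpus
        reports, _ = load_quarter_reports(Path(paths["demo"]).parent)
        assert len(reports) == manifest.n_demo_rows
        deduped = deduplicate(reports, read_deleted_caseids(paths["deleted"]))
        assert len(deduped) == manifest.expected_survivors
        assert deduplicate(deduped, read_deleted_caseids(paths["deleted"])) == deduped


class TestPrimarySuspectFilter:
    def test_secondary_suspect_only_is_excluded(self):
        report = _report(drugs=[DrugEntry("TERIPARATIDE", role="SS")])
        assert filter_primary_suspect([report], ["TERIPARATIDE"]) == []

    def test_substring_match_on_verbatim_name(self):
        report = _report(drugs=[DrugEntry("FORTEO (TERIPARATIDE)", role="PS")])
        assert filter_primary_suspect([report], ["TERIPARATIDE"]) == [report]

    def test_match_via_active_ingredient_and_whitespace_folding(self):
        report = _report(drugs=[DrugEntry("BRANDX", active_ingredient="  Teriparatide  acetate", role="PS")])
        assert filter_primary_suspect([report], ["teriparatide"]) == [report]

    def test_exact_mode(self):
        report = _report(drugs=[DrugEntry("FORTEO (TERIPARATIDE)", role="PS")])
        assert filter_primary_suspect([report], ["TERIPARATIDE"], mode="exact") == []

    def test_empty_synonyms_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_primary_suspect([], [" "])

    def test_manifest_target_count(self, small_reports):
        reports, manifest = small_reports
        filtered = filter_primary_suspect(reports, ["TERIPARATIDE"])
        assert len(filtered) == manifest.expected_target_ps_reports


class TestFaersDate:
    @pytest.mark.parametrize(
        "raw,precision", [("20230115", "day"), ("202301", "month"), ("2023", "year")]
    )
    def test_precision(self, raw, precision):
        assert FaersDate.parse(raw).precision == precision

    def test_imprecise_dates_have_no_calendar_date(self):
        assert FaersDate.parse("202301").to_date() is None
        assert FaersDate.parse("20230115").to_date() is not None

    @pytest.mark.parametrize("raw", ["", "2023013", "ABCD0101", "202313"])
    def test_invalid(self, raw):
        assert FaersDate.parse(raw) is None
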