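import random

import pytest
from hypothesis import given, settings, strategies as st

from faersig.errors import IngestError, SchemaError
from faersig.ingest import (
    RawDemoRecord,
    assemble_cases,
    deduplicate,
    merge_quarters,
    parse_table,
)
from faersig.normalize import SynonymTable


class TestParseTable:
    def test_row_count_equals_data_lines(self, tmp_path):
        path = tmp_path / "DEMO18Q1.txt"
        path.write_text(
            "primaryid$caseid$caseversion$fda_dt\n101$1$1$20190101\n201$2$1$20190102\n"
        )
        records, log = parse_table(path, "DEMO")
        assert len(records) == 2
        assert log.parsed == 2 and log.n_skipped == 0

    def test_fields_selected_by_header_name_not_position(self, tmp_path):
        path = tmp_path / "DRUG18Q1.txt"
        # shuffled column order relative to the canonical layout
        path.write_text("role_cod$drugname$primaryid$drug_seq\nPS$SPIRIVA$101$1\n")
        records, _ = parse_table(path, "DRUG")
        (rec,) = records
        assert rec.primaryid == "101"
        assert rec.drugname == "SPIRIVA"
        assert rec.role_code == "PS"
        assert rec.drug_seq == 1

    def test_missing_required_column_is_fatal_and_named(self, tmp_path):
        path = tmp_path / "DEMO18Q1.txt"
        path.write_text("primaryid$caseversion$fda_dt\n101$1$20190101\n")
        with pytest.raises(SchemaError, match="caseid"):
            parse_table(path, "DEMO")

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(IngestError, match="missing file"):
            parse_table(tmp_path / "DEMO99Q9.txt", "DEMO")

    def test_malformed_lines_are_skipped_with_line_numbers(self, tmp_path):
        path = tmp_path / "REAC18Q1.txt"
        path.write_text(
            "primaryid$pt\n"
            "101$Dyspnoea\n"
            "102$free text with $ inside$extra\n"  # wrong field count
            "$Cough\n"  # missing primaryid
            "103$\n"  # empty pt
            "104$Cough\n"
        )
        records, log = parse_table(path, "REAC")
        assert len(records) == 2
        assert [lineno for lineno, _ in log.skipped] == [3, 4, 5]

    def test_unknown_role_code_skipped(self, tmp_path):
        path = tmp_path / "DRUG18Q1.txt"
        path.write_text("primaryid$drugname$role_cod\n101$SPIRIVA$XX\n101$SPIRIVA$ps\n")
        records, log = parse_table(path, "DRUG")
        assert len(records) == 1 and records[0].role_code == "PS"
        assert log.n_skipped == 1


class TestMergeQuarters:
    def test_record_counts_add_up(self, tmp_path):
        q1 = [RawDemoRecord(str(i), str(i), 1, None) for i in range(10)]
        q2 = [RawDemoRecord(str(100 + i), str(100 + i), 1, None) for i in range(15)]
        assert len(merge_quarters([q1, q2])) == 25

    def test_empty_quarter_list(self):
        assert merge_quarters([]) == []

    def test_same_primaryid_retained_before_dedup(self):
        rec = RawDemoRecord("101", "1", 1, None)
        assert len(merge_quarters([[rec], [rec]])) == 2


DEMO_RECORDS = [
    RawDemoRecord("71", "7", 1, "20190101"),
    RawDemoRecord("72", "7", 2, "20180601"),  # higher version wins despite older date
    RawDemoRecord("81", "8", 1, "20190101"),
    RawDemoRecord("82", "8", 1, "20200101"),  # version tie -> later date wins
    RawDemoRecord("91", "9", 1, "20190101"),
    RawDemoRecord("92", "9", 1, "20190101"),  # full tie -> greater primaryid wins
]


class TestDeduplicate:
    def test_tie_break_chain(self):
        result = deduplicate(DEMO_RECORDS)
        assert result.by_case == {"7": "72", "8": "82", "9": "92"}

    def test_single_record_retained(self):
        result = deduplicate([DEMO_RECORDS[0]])
        assert result.by_case == {"7": "71"}

    def test_missing_caseid_keyed_by_primaryid(self):
        result = deduplicate([RawDemoRecord("55", None, 1, None)])
        assert result.missing_caseid == 1
        assert result.retained["55"].primaryid == "55"

    def test_idempotence(self):
        once = deduplicate(DEMO_RECORDS)
        twice = deduplicate(list(once.retained.values()))
        assert twice.by_case == once.by_case

    def test_conservation(self):
        result = deduplicate(DEMO_RECORDS)
        assert len(result.retained) == len({r.caseid for r in DEMO_RECORDS})


@settings(derandomize=True, max_examples=50)
@given(st.randoms(use_true_random=False))
def test_dedup_order_invariance(rnd: random.Random):
    shuffled = list(DEMO_RECORDS)
    rnd.shuffle(shuffled)
    assert deduplicate(shuffled).by_case == deduplicate(DEMO_RECORDS).by_case


class TestAssembleCases:
    def test_duplicate_mentions_collapse_to_sets(self):
        dedup = deduplicate([RawDemoRecord("101", "1", 1, "20190101")])
        from faersig.ingest import RawDrugRecord, RawReacRecord

        cases, log = assemble_cases(
            dedup,
            [
                RawDrugRecord("101", 1, "SPIRIVA", "PS"),
                RawDrugRecord("101", 2, "spiriva", "PS"),
            ],
            [RawReacRecord("101", "Dyspnoea"), RawReacRecord("101", "Cough")],
        )
        (case,) = cases
        assert case.drug_names() == {"SPIRIVA"}
        assert case.reactions == {"DYSPNOEA", "COUGH"}
        assert log.dropped_drug_records == 0

    def test_superseded_version_records_dropped(self):
        dedup = deduplicate(
            [RawDemoRecord("71", "7", 1, None), RawDemoRecord("72", "7", 2, None)]
        )
        from faersig.ingest import RawDrugRecord, RawReacRecord

        cases, log = assemble_cases(
            dedup,
            [RawDrugRecord("71", 1, "OLDDRUG", "PS"), RawDrugRecord("72", 1, "NEWDRUG", "PS")],
            [RawReacRecord("71", "Cough")],
        )
        (case,) = cases
        assert case.primaryid == "72"
        assert case.drug_names() == {"NEWDRUG"}
        assert log.dropped_drug_records == 1 and log.dropped_reac_records == 1

    def test_synonyms_applied_at_assembly(self):
        dedup = deduplicate([RawDemoRecord("101", "1", 1, None)])
        from faersig.ingest import RawDrugRecord

        cases, _ = assemble_cases(
            dedup,
            [RawDrugRecord("101", 1, "Opsumit", "PS")],
            [],
            synonyms=SynonymTable.from_pairs({"OPSUMIT": "MACITENTAN"}),
        )
        assert cases[0].drug_names() == {"MACITENTAN"}

    def test_role_filter(self):
        dedup = deduplicate([RawDemoRecord("101", "1", 1, None)])
        from faersig.ingest import RawDrugRecord

        cases, _ = assemble_cases(
            dedup,
            [RawDrugRecord("101", 1, "ASPIRIN", "C"), RawDrugRecord("101", 2, "SPIRIVA", "PS")],
            [],
        )
        (case,) = cases
        assert case.drug_names() == {"SPIRIVA"}  # suspect roles only by default
        assert case.drug_names("all") == {"SPIRIVA", "ASPIRIN"}
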