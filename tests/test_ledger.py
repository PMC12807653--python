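import random

import pytest

from transqc import ledger
from transqc.ledger import (
    DuplicateKeyError,
    LedgerRecord,
    Triple,
    apply_definition_policy,
    emit_release_templates,
    format_percent,
    make_subsets,
    read_ledger,
    reconcile,
    summarize,
    write_master,
)


def rec(subject="DOID:1", predicate="label", text="night fever", **kw) -> LedgerRecord:
    defaults = dict(
        subject_id=subject,
        predicate_id=predicate,
        source_lang="en",
        source_text=text,
        target_lang="es",
        target_text="fiebre nocturna",
        status="passed",
        score=0.9,
        method="professional",
    )
    defaults.update(kw)
    return LedgerRecord(**defaults)


class TestLedgerRecord:
    def test_unknown_status(self):
        with pytest.raises(ValueError):
            rec(status="maybe")

    def test_reviewed_requires_reviewer(self):
        with pytest.raises(ValueError, match="reviewer"):
            rec(status="reviewed_accepted")
        rec(status="reviewed_accepted", reviewer="curator-1")  # fine

    def test_text_type_mapping(self):
        assert rec(predicate="label").text_type == "labels"
        assert rec(predicate="exact_synonym").text_type == "synonyms"
        assert rec(predicate="definition").text_type == "definitions"


class TestMasterFile:
    def test_sorted_output(self, tmp_path):
        records = [
            rec("DOID:3", text="c"),
            rec("DOID:1", text="a"),
            rec("DOID:2", text="b"),
        ]
        path = str(tmp_path / "master.tsv")
        write_master(records, path)
        got = read_ledger(path)
        assert [r.subject_id for r in got] == ["DOID:1", "DOID:2", "DOID:3"]

    def test_empty_is_header_only(self, tmp_path):
        path = str(tmp_path / "master.tsv")
        write_master([], path)
        content = open(path, encoding="utf-8").read()
        assert content == "\t".join(ledger.MASTER_COLUMNS) + "\n"

    def test_round_trip_with_escaped_tab(self, tmp_path):
        record = rec(text="night\tfever", target_text="fiebre\nnocturna")
        path = str(tmp_path / "master.tsv")
        write_master([record], path)
        assert read_ledger(path) == [record]

    def test_serialization_idempotent(self, tmp_path):
        records = [rec("DOID:%d" % i, text=f"t{i}") for i in (5, 2, 9)]
        p1, p2 = str(tmp_path / "a.tsv"), str(tmp_path / "b.tsv")
        write_master(records, p1)
        write_master(read_ledger(p1), p2)
        assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_duplicate_keys_rejected(self, tmp_path):
        with pytest.raises(DuplicateKeyError):
            write_master([rec(), rec()], str(tmp_path / "m.tsv"))

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        good = "\t".join(ledger.MASTER_COLUMNS)
        bad_row = "\t".join(["DOID:1", "label", "en", "x", "es", "y", "passed",
                             "not-a-number", "false", "", "", ""])
        path.write_text(good + "\n" + bad_row + "\n", encoding="utf-8")
        with pytest.raises(Exception, match="line 2"):
            read_ledger(str(path))


class TestReconcile:
    def test_all_carried(self):
        records = [rec("DOID:1", text="a"), rec("DOID:2", text="b")]
        triples = [Triple("DOID:1", "label", "a"), Triple("DOID:2", "label", "b")]
        result = reconcile(triples, records)
        assert len(result.carried) == 2
        assert not result.changed and not result.new_untranslated and not result.retired

    def test_changed_text(self):
        # same (subject, predicate), different text: current triple is
        # "changed", prior record is "retired"
        records = [rec("DOID:1", text="old wording")]
        triples = [Triple("DOID:1", "label", "new wording")]
        result = reconcile(triples, records)
        assert len(result.changed) == 1 and len(result.retired) == 1
        assert not result.carried and not result.new_untranslated

    def test_new_untranslated(self):
        result = reconcile([Triple("DOID:9", "label", "fresh")], [])
        assert len(result.new_untranslated) == 1

    def test_duplicate_triples_rejected(self):
        t = Triple("DOID:1", "label", "x")
        with pytest.raises(DuplicateKeyError):
            reconcile([t, t], [])

    @pytest.mark.parametrize("seed,n", [(0, 200), (1, 2000), (2, 10_000)])
    def test_partition_conservation_randomized(self, seed, n):
        rng = random.Random(seed)
        triples = []
        records = []
        for i in range(n):
            subject = f"DOID:{rng.randrange(n)}"
            predicate = rng.choice(ledger.PREDICATES)
            text = f"text-{rng.randrange(n // 2)}"
            roll = rng.random()
            if roll < 0.4:  # both sides, same text
                triples.append((subject, predicate, text))
                records.append((subject, predicate, text))
            elif roll < 0.6:  # text changed
                triples.append((subject, predicate, text + "-new"))
                records.append((subject, predicate, text))
            elif roll < 0.8:
                triples.append((subject, predicate, text))
            else:
                records.append((subject, predicate, text))
        triples = [Triple(*k) for k in dict.fromkeys(triples)]
        records = [rec(k[0], k[1], k[2]) for k in dict.fromkeys(records)]
        result = reconcile(triples, records)
        # every record in exactly one of carried/retired
        assert sorted(r.key for r in result.carried + result.retired) == sorted(
            r.key for r in records
        )
        # every triple in exactly one of carried/changed/new
        covered = (
            [r.key for r in result.carried]
            + [t.key for t in result.changed]
            + [t.key for t in result.new_untranslated]
        )
        assert sorted(covered) == sorted(t.key for t in triples)


class TestMakeSubsets:
    def test_one_of_each(self):
        pending = rec("DOID:1", text="a", status="pending")
        result = reconcile(
            [
                Triple("DOID:1", "label", "a"),
                Triple("DOID:2", "label", "b-new"),
                Triple("DOID:3", "label", "c"),
            ],
            [pending, rec("DOID:2", text="b")],
        )
        subsets = make_subsets(result)
        assert subsets["pending_review"] == (pending,)
        assert [t.subject_id for t in subsets["changed_text"]] == ["DOID:2"]
        assert [t.subject_id for t in subsets["needs_translation"]] == ["DOID:3"]
        # no overlap between subsets
        all_keys = [
            k for part in subsets.values() for k in (x.key for x in part)
        ]
        assert len(all_keys) == len(set(all_keys))

    def test_all_passed_no_changes(self):
        result = reconcile(
            [Triple("DOID:1", "label", "a")], [rec("DOID:1", text="a")]
        )
        subsets = make_subsets(result)
        assert subsets["pending_review"] == ()
        assert subsets["changed_text"] == ()

    def test_empty(self):
        subsets = make_subsets(reconcile([], []))
        assert all(part == () for part in subsets.values())


class TestDefinitionPolicy:
    def test_signed_off_pending_definition_promoted(self):
        r = rec(predicate="definition", status="pending", score=0.4)
        out = apply_definition_policy([r], [r.key], reviewer="curator-2")
        assert out[0].status == "pending_included"
        assert out[0].reviewer == "curator-2"

    def test_signed_off_label_ignored_with_warning(self):
        r = rec(predicate="label", status="pending")
        with pytest.warns(UserWarning):
            out = apply_definition_policy([r], [r.key])
        assert out[0] == r

    def test_passed_definition_unchanged(self):
        r = rec(predicate="definition", status="passed")
        with pytest.warns(UserWarning):
            out = apply_definition_policy([r], [r.key])
        assert out[0] == r

    def test_unrelated_records_untouched(self):
        r = rec(predicate="definition", status="pending")
        assert apply_definition_policy([r], []) == [r]


class TestReleaseTemplates:
    def test_two_eligible_rows(self):
        records = [rec("DOID:1", text="a"), rec("DOID:2", text="b", status="exact")]
        tables = emit_release_templates(records)
        header, directives, rows = tables["international_table"]
        assert len(rows) == 2
        assert all(row[2] and row[3] for row in rows)  # both language columns
        assert any("@en" in d for d in directives)
        assert any("@es" in d for d in directives)
        _, t_directives, t_rows = tables["target_language_table"]
        assert len(t_rows) == 2
        assert any("@es" in d for d in t_directives)
        assert not any("@en" in d for d in t_directives)

    def test_pending_excluded(self):
        tables = emit_release_templates([rec(status="pending")])
        assert tables["international_table"][2] == []
        assert tables["target_language_table"][2] == []

    def test_pending_included_is_eligible(self):
        tables = emit_release_templates([rec(status="pending_included")])
        assert len(tables["international_table"][2]) == 1

    def test_acronym_annotation(self):
        r = rec(predicate="exact_synonym", acronym=True)
        tables = emit_release_templates([r])
        assert tables["international_table"][2][0][-1] == "acronym"

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="empty target_text"):
            emit_release_templates([rec(target_text="")])


class TestSummarize:
    def test_percentages(self):
        records = (
            [rec(f"DOID:{i}", text=f"t{i}", status="exact") for i in range(4)]
            + [rec(f"DOID:{i+4}", text=f"t{i+4}", status="passed") for i in range(4)]
            + [rec(f"DOID:{i+8}", text=f"t{i+8}", status="pending") for i in range(2)]
        )
        report = summarize(records)
        assert report.counts["labels"] == {"exact": 4, "passed": 4, "pending": 2}
        assert report.percentages["labels"] == {"exact": 40.0, "passed": 40.0, "pending": 20.0}

    def test_percentages_sum_to_100(self, corpus500):
        records = [
            rec(su.unit.subject_id, su.unit.predicate_id, su.unit.source_text,
                status=("passed" if su.label == "faithful" else "pending"))
            for su in corpus500
        ]
        report = summarize(records)
        for tt, pcts in report.percentages.items():
            assert sum(pcts.values()) == pytest.approx(100.0, abs=0.05)
            assert sum(report.counts[tt].values()) == sum(
                1 for r in records if r.text_type == tt
            )

    def test_coverage(self):
        report = summarize(
            [rec()], totals={"labels": 11946}
        )
        assert report.coverage["labels"] == format_percent(1, 11946)

    def test_empty(self):
        report = summarize([])
        assert report.counts == {} and report.percentages == {}


def test_format_percent_coverage_value():
    assert format_percent(11078, 11946) == 92.73


def test_format_report_layout():
    text = ledger.format_report(summarize([rec()]))
    assert "labels" in text and "passed" in text
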