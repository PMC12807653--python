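"""Translation-record lifecycle: the sorted master table, reconciliation
against current ontology text, task subsets, release templates and reports.

Every translated text element is one record keyed by the triple
``(subject_id, predicate_id, source_text)``.  Reconciling prior records
against a fresh export of ontology triples partitions both sides into
carried / changed / new / retired, from which the task subsets
(needs_translation, pending_review, changed_text) are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from . import _tsv
from ._tsv import TsvFormatError

PREDICATES = (
    "label",
    "definition",
    "exact_synonym",
    "narrow_synonym",
    "broad_synonym",
    "related_synonym",
    "comment",
)

STATUSES = (
    "exact",
    "passed",
    "pending",
    "reviewed_accepted",
    "reviewed_rejected",
    "pending_included",
)

#: Statuses whose records may be emitted into release templates.
RELEASE_ELIGIBLE = frozenset({"exact", "passed", "reviewed_accepted", "pending_included"})

MASTER_COLUMNS = (
    "subject_id",
    "predicate_id",
    "source_lang",
    "source_text",
    "target_lang",
    "target_text",
    "status",
    "score",
    "acronym",
    "reviewer",
    "review_date",
    "method",
)

TRIPLE_COLUMNS = ("subject_id", "predicate_id", "text", "lang")

# Table-2-style text types; predicates not listed (comments) report under "other".
_TEXT_TYPE_OF_PREDICATE = {
    "label": "labels",
    "definition": "definitions",
    "exact_synonym": "synonyms",
    "narrow_synonym": "synonyms",
    "broad_synonym": "synonyms",
    "related_synonym": "synonyms",
}

# Score-category view of a record's status, for Table-2-style reporting.
_CATEGORY_OF_STATUS = {
    "exact": "exact",
    "passed": "passed",
    "pending": "pending",
    "pending_included": "pending",
    "reviewed_accepted": "passed",
    "reviewed_rejected": "pending",
}

CATEGORIES = ("exact", "passed", "pending")


class DuplicateKeyError(ValueError):
    pass


@dataclass(frozen=True)
class Triple:
    """One current ontology text element (source-language side)."""

    subject_id: str
    predicate_id: str
    text: str
    lang: str = "en"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.predicate_id, self.text)


@dataclass(frozen=True)
class LedgerRecord:
    subject_id: str
    predicate_id: str
    source_lang: str
    source_text: str
    target_lang: str
    target_text: str
    status: str
    score: float | None = None
    acronym: bool = False
    reviewer: str = ""
    review_date: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status.startswith("reviewed_") and not self.reviewer:
            raise ValueError(
                f"{self.subject_id}/{self.predicate_id}: status {self.status!r} "
                "requires reviewer provenance"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.predicate_id, self.source_text)

    @property
    def text_type(self) -> str:
        return _TEXT_TYPE_OF_PREDICATE.get(self.predicate_id, "other")

    @property
    def category(self) -> str:
        return _CATEGORY_OF_STATUS[self.status]


@dataclass(frozen=True)
class ReconcileResult:
    carried: tuple[LedgerRecord, ...]
    changed: tuple[Triple, ...]
    new_untranslated: tuple[Triple, ...]
    retired: tuple[LedgerRecord, ...]


def _check_unique(keys: Iterable[tuple[str, str, str]], what: str) -> None:
    seen: set[tuple[str, str, str]] = set()
    for key in keys:
        if key in seen:
            raise DuplicateKeyError(f"duplicate {what} triple key: {key}")
        seen.add(key)


def _record_to_row(r: LedgerRecord) -> list[str]:
    return [
        r.subject_id,
        r.predicate_id,
        r.source_lang,
        r.source_text,
        r.target_lang,
        r.target_text,
        r.status,
        "" if r.score is None else f"{r.score:.4f}",
        "true" if r.acronym else "false",
        r.reviewer,
        r.review_date,
        r.method,
    ]


def _row_to_record(row: Mapping[str, str], lineno: int | None = None) -> LedgerRecord:
    where = f"line {lineno}: " if lineno is not None else ""
    score_field = row.get("score", "")
    try:
        score = float(score_field) if score_field else None
    except ValueError:
        raise TsvFormatError(f"{where}invalid score {score_field!r}") from None
    try:
        return LedgerRecord(
            subject_id=row["subject_id"],
            predicate_id=row["predicate_id"],
            source_lang=row["source_lang"],
            source_text=row["source_text"],
            target_lang=row["target_lang"],
            target_text=row["target_text"],
            status=row["status"],
            score=score,
            acronym=row.get("acronym", "false").lower() in ("true", "1", "yes"),
            reviewer=row.get("reviewer", ""),
            review_date=row.get("review_date", ""),
            method=row.get("method", ""),
        )
    except ValueError as exc:
        raise TsvFormatError(f"{where}{exc}") from None


def read_ledger(path: str) -> list[LedgerRecord]:
    """Read a master-table TSV; rejects malformed rows and duplicate keys."""
    _, rows = _tsv.read_rows(path, required_columns=MASTER_COLUMNS[:7])
    records = [_row_to_record(row, lineno) for lineno, row in enumerate(rows, start=2)]
    _check_unique((r.key for r in records), "ledger")
    return records


def write_master(records: Iterable[LedgerRecord], path: str) -> None:
    """Write the sorted master table (binary code-point key order)."""
    ordered = sorted(records, key=lambda r: r.key)
    _check_unique((r.key for r in ordered), "ledger")
    _tsv.write_rows(path, MASTER_COLUMNS, [_record_to_row(r) for r in ordered])


def read_triples(path: str) -> list[Triple]:
    _, rows = _tsv.read_rows(path, required_columns=TRIPLE_COLUMNS[:3])
    triples = [
        Triple(
            subject_id=row["subject_id"],
            predicate_id=row["predicate_id"],
            text=row["text"],
            lang=row.get("lang", "en"),
        )
        for row in rows
    ]
    _check_unique((t.key for t in triples), "triple")
    return triples


def write_triples(triples: Iterable[Triple], path: str) -> None:
    _tsv.write_rows(
        path,
        TRIPLE_COLUMNS,
        [[t.subject_id, t.predicate_id, t.text, t.lang] for t in sorted(triples, key=lambda t: t.key)],
    )


def reconcile(
    current_triples: Sequence[Triple], prior_records: Sequence[LedgerRecord]
) -> ReconcileResult:
    """Partition current triples and prior records by triple-key comparison.

    A current triple whose full key matches a record is *carried* (with that
    record); one whose (subject, predicate) pair is known but whose text
    differs is *changed*; an unknown pair is *new_untranslated*.  Prior
    records without a current full-key match are *retired*.
    """
    _check_unique((t.key for t in current_triples), "triple")
    _check_unique((r.key for r in prior_records), "ledger")
    records_by_key = {r.key: r for r in prior_records}
    record_pairs = {(r.subject_id, r.predicate_id) for r in prior_records}
    triple_keys = {t.key for t in current_triples}

    carried: list[LedgerRecord] = []
    changed: list[Triple] = []
    new_untranslated: list[Triple] = []
    for t in current_triples:
        if t.key in records_by_key:
            carried.append(records_by_key[t.key])
        elif (t.subject_id, t.predicate_id) in record_pairs:
            changed.append(t)
        else:
            new_untranslated.append(t)
    retired = [r for r in prior_records if r.key not in triple_keys]
    return ReconcileResult(
        carried=tuple(carried),
        changed=tuple(changed),
        new_untranslated=tuple(new_untranslated),
        retired=tuple(retired),
    )


def make_subsets(
    result: ReconcileResult,
) -> dict[str, tuple]:
    """Task subsets: untranslated triples, carried-but-pending records, changed text."""
    return {
        "needs_translation": result.new_untranslated,
        "pending_review": tuple(
            r for r in result.carried if r.category == "pending" and r.status != "pending_included"
        ),
        "changed_text": result.changed,
    }


def apply_definition_policy(
    records: Iterable[LedgerRecord],
    signed_off: Iterable[tuple[str, str, str]],
    reviewer: str = "",
    review_date: str = "",
) -> list[LedgerRecord]:
    """Promote signed-off pending definitions to release-eligible status.

    ``signed_off`` lists triple keys whose translations a fluent reviewer
    found free of obvious errors in a glancing review.  Only definition
    records with status ``pending`` are promoted (to ``pending_included``);
    sign-offs pointing at any other record are ignored with a warning.
    """
    signed = set(signed_off)
    out: list[LedgerRecord] = []
    for r in records:
        if r.key in signed:
            signed.discard(r.key)
            if r.predicate_id == "definition" and r.status == "pending":
                out.append(
                    replace(
                        r,
                        status="pending_included",
                        reviewer=reviewer or r.reviewer,
                        review_date=review_date or r.review_date,
                    )
                )
                continue
            warnings.warn(
                f"sign-off ignored for non-pending-definition record {r.key}",
                stacklevel=2,
            )
        out.append(r)
    return out


def emit_release_templates(
    records: Sequence[LedgerRecord],
) -> dict[str, tuple[list[str], list[str], list[list[str]]]]:
    """Build the two release-template tables from release-eligible records.

    Returns ``{name: (header, directive_row, data_rows)}`` where the
    directive row carries language-tagged annotation directives consumed by
    ontology template tooling.  The international table holds source and
    target text; the target-language table holds target text only.
    """
    eligible = sorted(
        (r for r in records if r.status in RELEASE_ELIGIBLE), key=lambda r: r.key
    )
    for r in eligible:
        if not r.target_text:
            raise ValueError(
                f"release-eligible record {r.key} has empty target_text"
            )
    _check_unique((r.key for r in eligible), "release")

    def acr(r: LedgerRecord) -> str:
        return "acronym" if r.acronym else ""

    international_rows = [
        [r.subject_id, r.predicate_id, r.source_text, r.target_text, acr(r)]
        for r in eligible
    ]
    target_rows = [
        [r.subject_id, r.predicate_id, r.target_text, acr(r)] for r in eligible
    ]
    src_tag = eligible[0].source_lang if eligible else "en"
    tgt_tag = eligible[0].target_lang if eligible else "es"
    return {
        "international_table": (
            ["subject_id", "predicate_id", "source_text", "target_text", "synonym_type"],
            ["ID", "", f"A %predicate%@{src_tag}", f"A %predicate%@{tgt_tag}", "AT synonym_type"],
            international_rows,
        ),
        "target_language_table": (
            ["subject_id", "predicate_id", "target_text", "synonym_type"],
            ["ID", "", f"A %predicate%@{tgt_tag}", "AT synonym_type"],
            target_rows,
        ),
    }


def write_template(path: str, table: tuple[list[str], list[str], list[list[str]]]) -> None:
    header, directives, rows = table
    _tsv.write_rows(path, header, [directives] + rows)


def format_percent(numerator: int, denominator: int) -> float:
    """Percentage to two decimals, e.g. 11078/11946 -> 92.73."""
    return round(100.0 * numerator / denominator, 2)


@dataclass(frozen=True)
class Report:
    """Counts and percentages per text type and category, plus coverage."""

    counts: dict[str, dict[str, int]]
    percentages: dict[str, dict[str, float]]
    coverage: dict[str, float]

    def total(self, text_type: str) -> int:
        return sum(self.counts.get(text_type, {}).values())


def summarize(
    records: Iterable[LedgerRecord],
    totals: Mapping[str, int] | None = None,
) -> Report:
    """Per-text-type category counts/percentages; coverage when totals given."""
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        by_cat = counts.setdefault(r.text_type, {c: 0 for c in CATEGORIES})
        by_cat[r.category] += 1
    percentages = {
        tt: {
            cat: format_percent(n, sum(by_cat.values()))
            for cat, n in by_cat.items()
            if sum(by_cat.values())
        }
        for tt, by_cat in counts.items()
    }
    coverage: dict[str, float] = {}
    if totals:
        for tt, total in totals.items():
            translated = sum(counts.get(tt, {}).values())
            coverage[tt] = format_percent(translated, total) if total else 0.0
    return Report(counts=counts, percentages=percentages, coverage=coverage)


def format_report(report: Report) -> str:
    """Pretty text table: text type x category x count x percent."""
    lines = [f"{'Text type':<14}{'Category':<10}{'Total':>8}{'Percent':>9}"]
    for tt in sorted(report.counts):
        for cat in CATEGORIES:
            n = report.counts[tt].get(cat, 0)
            pct = report.percentages.get(tt, {}).get(cat, 0.0)
            lines.append(f"{tt:<14}{cat:<10}{n:>8}{pct:>9.2f}")
    for tt in sorted(report.coverage):
        lines.append(f"{tt:<14}{'coverage':<10}{'':>8}{report.coverage[tt]:>9.2f}")
    return "\n".join(lines) + "\n"


def report_rows(report: Report) -> tuple[list[str], list[list[str]]]:
    header = ["text_type", "category", "count", "percent"]
    rows = [
        [tt, cat, str(report.counts[tt].get(cat, 0)), f"{report.percentages.get(tt, {}).get(cat, 0.0):.2f}"]
        for tt in sorted(report.counts)
        for cat in CATEGORIES
    ]
    for tt in sorted(report.coverage):
        rows.append([tt, "coverage", "", f"{report.coverage[tt]:.2f}"])
    return header, rows
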