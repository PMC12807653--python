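"""Minimal escaped-TSV codec shared by the unit and ledger tables.

Dialect: UTF-8, header row mandatory, no quoting; literal backslash, tab and
newline inside a field are escaped as ``\\\\``, ``\\t`` and ``\\n``.
"""

from __future__ import annotations

from typing import Iterable, Sequence


class TsvFormatError(ValueError):
    """Malformed TSV input; message carries the 1-based line number."""


def escape_field(value: str) -> str:
    return (
        value.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n").replace("\r", "\\r")
    )


def unescape_field(value: str) -> str:
    out: list[str] = []
    it = iter(range(len(value)))
    i = 0
    while i < len(value):
        c = value[i]
        if c == "\\" and i + 1 < len(value):
            nxt = value[i + 1]
            mapped = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}.get(nxt)
            if mapped is not None:
                out.append(mapped)
                i += 2
                continue
        out.append(c)
        i += 1
    return "".join(out)


def format_rows(header: Sequence[str], rows: Iterable[Sequence[str]]) -> str:
    lines = ["\t".join(header)]
    for row in rows:
        if len(row) != len(header):
            raise TsvFormatError(
                f"row has {len(row)} fields, expected {len(header)}: {row!r}"
            )
        lines.append("\t".join(escape_field(str(f)) for f in row))
    return "\n".join(lines) + "\n"


def write_rows(path: str, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(format_rows(header, rows))


def parse(text: str, required_columns: Sequence[str] | None = None) -> tuple[list[str], list[dict[str, str]]]:
    """Parse TSV text into (header, row dicts); validates required columns."""
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise TsvFormatError("line 1: empty file, header row required")
    header = lines[0].split("\t")
    if required_columns is not None:
        missing = [c for c in required_columns if c not in header]
        if missing:
            raise TsvFormatError(f"line 1: missing required column(s): {', '.join(missing)}")
    records: list[dict[str, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise TsvFormatError(
                f"line {lineno}: expected {len(header)} fields, found {len(fields)}"
            )
        records.append(
            {col: unescape_field(val) for col, val in zip(header, fields)}
        )
    return header, records


def read_rows(path: str, required_columns: Sequence[str] | None = None) -> tuple[list[str], list[dict[str, str]]]:
    with open(path, encoding="utf-8") as fh:
        return parse(fh.read(), required_columns)
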