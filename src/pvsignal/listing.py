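"""Line-listing CSV dialects shared by the generator and the reader.

Two dialects are supported, both UTF-8 CSV with ISO-8601 dates:

``long``
    One row per (report, drug, event) combination:
    ``report_id,date,drug_code,event_term,med_error``.  A report with two
    drugs and three events occupies six rows sharing one report id; a
    report with no drugs (or no events) keeps the corresponding cell
    empty so that nothing is lost on round trip.

``wide``
    One row per report:
    ``report_id,date,med_error,drug_codes,event_terms`` with the mention
    sets as semicolon-delimited, sorted lists.

``read_line_listing(write_line_listing(R)) == R`` for collections of
normalized reports.
"""

from __future__ import annotations

import csv
import datetime as dt
from itertools import product

from .errors import IntegrityError, LineListingError

DIALECTS = ("long", "wide")

_LONG_HEADER = ["report_id", "date", "drug_code", "event_term", "med_error"]
_WIDE_HEADER = ["report_id", "date", "med_error", "drug_codes", "event_terms"]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _fmt_bool(flag: bool) -> str:
    return "true" if flag else "false"


def write_line_listing(reports, path, dialect: str = "long") -> None:
    """Write a report collection to ``path`` in the given dialect.

    Mentions are written in sorted order so identical collections produce
    byte-identical files.
    """
    _check_dialect(dialect)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        if dialect == "long":
            w.writerow(_LONG_HEADER)
            for r in reports:
                drugs = sorted(r.drugs) or [""]
                events = sorted(r.events) or [""]
                for d, e in product(drugs, events):
                    w.writerow([r.report_id, r.date.isoformat(), d, e, _fmt_bool(r.med_error)])
        else:
            w.writerow(_WIDE_HEADER)
            for r in reports:
                w.writerow(
                    [
                        r.report_id,
                        r.date.isoformat(),
                        _fmt_bool(r.med_error),
                        ";".join(sorted(r.drugs)),
                        ";".join(sorted(r.events)),
                    ]
                )


def _parse_date(value: str, lineno: int) -> dt.date:
    try:
        return dt.date.fromisoformat(value.strip())
    except ValueError:
        raise LineListingError(f"line {lineno}: unparseable date {value!r}") from None


def _parse_bool(value: str, lineno: int) -> bool:
    try:
        return _BOOL[value.strip().lower()]
    except KeyError:
        raise LineListingError(f"line {lineno}: unparseable boolean {value!r}") from None


def read_line_listing(path, dialect: str = "long"):
    """Read a line listing; see :func:`pvsignal.ingest.read_line_listing`."""
    from .ingest import IcsrReport, normalize_drug_code, normalize_event_term

    _check_dialect(dialect)
    header = _LONG_HEADER if dialect == "long" else _WIDE_HEADER

    # report_id -> [date, med_error, drug set, event set]
    merged: dict[str, list] = {}

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            first = next(reader)
        except StopIteration:
            raise LineListingError("line 1: empty file, expected a header row") from None
        if [c.strip().lower() for c in first] != header:
            raise LineListingError(
                f"line 1: expected header {','.join(header)!r}, got {','.join(first)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise LineListingError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rid = row[0].strip()
            if not rid:
                raise LineListingError(f"line {lineno}: empty report_id")
            date = _parse_date(row[1], lineno)
            if dialect == "long":
                med = _parse_bool(row[4], lineno)
                drugs = [row[2]] if row[2].strip() else []
                events = [row[3]] if row[3].strip() else []
            else:
                med = _parse_bool(row[2], lineno)
                drugs = [p for p in row[3].split(";") if p.strip()]
                events = [p for p in row[4].split(";") if p.strip()]
            drugs = [normalize_drug_code(d) for d in drugs]
            events = [normalize_event_term(e) for e in events]
            entry = merged.get(rid)
            if entry is None:
                merged[rid] = [date, med, set(drugs), set(events)]
            else:
                if entry[0] != date or entry[1] != med:
                    raise IntegrityError(
                        f"line {lineno}: report {rid!r} repeated with conflicting "
                        f"date or med_error flag"
                    )
                entry[2].update(drugs)
                entry[3].update(events)

    return [
        IcsrReport(rid, e[0], frozenset(e[2]), frozenset(e[3]), e[1])
        for rid, e in sorted(merged.items())
    ]
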