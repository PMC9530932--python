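"""Reading and filtering of ICSR line listings.

An Individual Case Safety Report (ICSR) is one spontaneous report for one
patient; it may mention several suspected drugs and several adverse-event
terms.  This module turns delimited line listings into :class:`IcsrReport`
collections and applies the inclusion rules of a case/non-case
disproportionality study: a calendar window, an ATC-class prefix, and the
exclusion of medication-error notifications.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, replace

from .errors import ConfigurationError

__all__ = [
    "IcsrReport",
    "FilterSpec",
    "normalize_drug_code",
    "normalize_event_term",
    "read_line_listing",
    "apply_filters",
    "vocabulary",
]


def normalize_drug_code(code: str) -> str:
    """Canonical drug-code form: trimmed, uppercased."""
    return code.strip().upper()


def normalize_event_term(term: str) -> str:
    """Canonical event-term form: casefolded, internal whitespace collapsed.

    Deliberately deterministic and auditable; no fuzzy matching.
    """
    return " ".join(term.split()).casefold()


@dataclass(frozen=True)
class IcsrReport:
    """One spontaneous report.

    Drug and event mentions are deduplicated sets: the counting unit of
    the downstream 2x2 tables is the report, so repeating a mention within
    a report carries no information.
    """

    report_id: str
    date: dt.date
    drugs: frozenset[str]
    events: frozenset[str]
    med_error: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        object.__setattr__(self, "events", frozenset(self.events))


_PREFIX_RE = re.compile(r"^[A-Z0-9]+$")


@dataclass(frozen=True)
class FilterSpec:
    """Inclusion rules defining the analysis universe.

    Parameters
    ----------
    atc_prefix
        Retained reports must mention at least one drug whose ATC code
        starts with this prefix (e.g. ``"J01"``, systemic antibacterials).
    date_start, date_end
        Inclusive calendar window on the report date.
    exclude_med_errors
        Drop reports flagged as medication errors.
    keep_nonmatching_drugs
        Universe policy switch.  By default (False) drug mentions outside
        the ATC class are dropped from retained reports, so "other drugs"
        in the 2x2 denominator means other drugs *of the class*.  Set True
        to keep class-external comparator mentions for sensitivity
        analyses.
    """

    atc_prefix: str
    date_start: dt.date
    date_end: dt.date
    exclude_med_errors: bool = True
    keep_nonmatching_drugs: bool = False

    def __post_init__(self) -> None:
        prefix = normalize_drug_code(self.atc_prefix)
        if not prefix or not _PREFIX_RE.match(prefix):
            raise ConfigurationError(
                f"atc_prefix must be non-empty uppercase alphanumeric, got {self.atc_prefix!r}"
            )
        object.__setattr__(self, "atc_prefix", prefix)
        if self.date_start > self.date_end:
            raise ConfigurationError(
                f"date_start {self.date_start} is after date_end {self.date_end}"
            )


def read_line_listing(path, dialect: str = "long") -> list[IcsrReport]:
    """Read a line listing into a report collection.

    Rows sharing a ``report_id`` are merged into one report; drug codes and
    event terms are normalized and deduplicated.  The returned collection is
    sorted by report id, so row order in the file is irrelevant.

    Raises
    ------
    LineListingError
        On an unparseable row (with its line number).
    IntegrityError
        When rows with the same report id disagree on date or
        medication-error flag.
    """
    from . import listing as _listing

    return _listing.read_line_listing(path, dialect)


def apply_filters(reports, spec: FilterSpec) -> list[IcsrReport]:
    """Apply the study inclusion rules; returns the analysis universe.

    A report is retained iff its date lies in the inclusive window, it
    mentions at least one drug matching ``atc_prefix``, and (when
    ``exclude_med_errors``) it is not a medication-error notification.
    Idempotent, and never increases the report count.
    """
    out: list[IcsrReport] = []
    for r in reports:
        if not (spec.date_start <= r.date <= spec.date_end):
            continue
        if spec.exclude_med_errors and r.med_error:
            continue
        matching = frozenset(d for d in r.drugs if d.startswith(spec.atc_prefix))
        if not matching:
            continue
        if spec.keep_nonmatching_drugs:
            out.append(r)
        else:
            out.append(replace(r, drugs=matching))
    return out


def vocabulary(reports) -> tuple[set[str], set[str]]:
    """Union of drug codes and event terms mentioned in the collection."""
    drugs: set[str] = set()
    events: set[str] = set()
    for r in reports:
        drugs.update(r.drugs)
        events.update(r.events)
    return drugs, events
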