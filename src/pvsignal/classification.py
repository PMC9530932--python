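"""ATC level-5 validation and WHO AWaRe grouping.

The WHO AWaRe scheme sorts antibiotics into three stewardship groups:
Access (first/second-line, lower resistance potential), Watch (higher
resistance potential, monitoring priority) and Reserve (last resort).
A small table covering the systemic antibacterials (ATC class J01) most
often seen in spontaneous-report screening ships with the package; users
can load their own table, since WHO revises the list.

Grouping is an annotation, never a gate: unknown codes map to
``"unclassified"`` rather than raising, so a screen never halts on a
vocabulary gap.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources

from .errors import ConfigurationError
from .ingest import normalize_drug_code

__all__ = [
    "AWARE_GROUPS",
    "UNCLASSIFIED",
    "AwareTable",
    "validate_atc5",
    "aware_group",
    "load_aware_table",
    "save_aware_table",
    "load_atc_names",
]

AWARE_GROUPS = frozenset({"Access", "Watch", "Reserve"})
UNCLASSIFIED = "unclassified"

# letter, 2 digits, 2 letters, 2 digits — a substance-level (level 5) code
_ATC5_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


def validate_atc5(code: str) -> bool:
    """True iff ``code`` is a lexically valid level-5 ATC code
    (after canonical uppercasing), e.g. ``J01DD52``."""
    return bool(_ATC5_RE.match(normalize_drug_code(code)))


@dataclass(frozen=True)
class AwareTable:
    """Mapping from level-5 ATC code to AWaRe group label."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, group in self.mapping.items():
            if not validate_atc5(code):
                raise ConfigurationError(f"malformed ATC level-5 code {code!r}")
            if group not in AWARE_GROUPS:
                raise ConfigurationError(
                    f"unknown AWaRe group {group!r} for {code}; "
                    f"expected one of {sorted(AWARE_GROUPS)}"
                )

    def group(self, code: str) -> str:
        return self.mapping.get(normalize_drug_code(code), UNCLASSIFIED)


def aware_group(code: str, table: AwareTable) -> str:
    """AWaRe group of ``code``, or ``"unclassified"`` when absent.  Total
    and deterministic."""
    return table.group(code)


def _packaged(name: str):
    return resources.files("pvsignal.data").joinpath(name)


def load_aware_table(path=None) -> AwareTable:
    """Load an AWaRe table from a two-column CSV ``atc_code,group``.

    With ``path=None`` the packaged default is used.  Rows with malformed
    codes or labels outside {Access, Watch, Reserve} are rejected with
    their row number.
    """
    source = _packaged("aware_atc.csv") if path is None else path
    mapping: dict[str, str] = {}
    with (source.open() if path is None else open(source, newline="", encoding="utf-8")) as fh:
        reader = csv.reader(fh)
        for rowno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if rowno == 1 and [c.strip().lower() for c in row[:2]] == ["atc_code", "group"]:
                continue
            if len(row) < 2:
                raise ConfigurationError(f"row {rowno}: expected atc_code,group, got {row!r}")
            code = normalize_drug_code(row[0])
            group = row[1].strip()
            if not validate_atc5(code):
                raise ConfigurationError(f"row {rowno}: malformed ATC code {row[0]!r}")
            if group not in AWARE_GROUPS:
                raise ConfigurationError(f"row {rowno}: unknown group {row[1]!r}")
            mapping[code] = group
    return AwareTable(mapping)


def save_aware_table(table: AwareTable, path) -> None:
    """Write a table back to CSV; ``load_aware_table`` round-trips it."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["atc_code", "group"])
        for code in sorted(table.mapping):
            w.writerow([code, table.mapping[code]])


def load_atc_names(path=None) -> dict[str, str]:
    """Display names for ATC codes (``atc_code,name`` CSV); packaged
    default covers the same J01 substances as the AWaRe table."""
    source = _packaged("atc_names.csv") if path is None else path
    names: dict[str, str] = {}
    with (source.open() if path is None else open(source, newline="", encoding="utf-8")) as fh:
        reader = csv.reader(fh)
        for rowno, row in enumerate(reader, start=1):
            if not row or (rowno == 1 and row[0].strip().lower() == "atc_code"):
                continue
            if len(row) >= 2:
                names[normalize_drug_code(row[0])] = row[1].strip()
    return names
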