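"""Reporting odds ratio (ROR) disproportionality screening.

The case/non-case design compares, within a spontaneous-reporting
database, the odds of exposure to a target drug P among reports of a
target event R ("cases") against the same odds among all other reports.
Each report contributes exactly once to one cell of the 2x2 table

    ========  =========  =============
              event R    not event R
    ========  =========  =============
    drug P       a            b
    not P        c            d
    ========  =========  =============

and the reporting odds ratio is ROR = (a*d)/(c*b), with a Woolf
(log-normal) 95% confidence interval
``exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d))``, z = 1.96.

A drug-event pair is a signal of disproportionate reporting (SDR) when
the lower CI bound exceeds 1 and the pair has at least ``min_a`` case
reports (default 3, the conventional minimum-case screen).  When c = 0
— every report of the event also lists the drug — the ratio is a
division by zero; the conventional sentinel value 99.9 is assigned and
flagged with an explicit status so numeric summaries can exclude it:
99.9 is a marker, not an estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import defaultdict

__all__ = [
    "SENTINEL_ROR",
    "INTENSITY_LOW",
    "INTENSITY_HIGH",
    "INTENSITY_SENTINEL",
    "INTENSITY_EXCLUDED",
    "ContingencyTable",
    "RorResult",
    "SignalRecord",
    "build_contingency",
    "compute_ror",
    "classify_sdr",
    "screen_all",
]

SENTINEL_ROR = 99.9

# intensity strata: screened pairs are stratified by case count
INTENSITY_LOW = "3<=a<5"
INTENSITY_HIGH = "a>=5"
INTENSITY_SENTINEL = "a>=3_c=0"
INTENSITY_EXCLUDED = "excluded_a<3"


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one drug-event pair.

    Realized tables carry non-negative integers; expected tables from the
    generative model (see :func:`pvsignal.synthetic.expected_contingency`)
    carry non-negative reals.  ``n`` is always a + b + c + d, the size of
    the report universe.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"cell {name} must be a finite non-negative count, got {v!r}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    """ROR point estimate with CI and status.

    status:
        ``"ok"``              all cells positive; estimate and CI valid.
        ``"sentinel_c_zero"`` c = 0 with a > 0; ror is the 99.9 marker,
                              CI undefined (None).
        ``"undefined"``       a = 0, or a zero in b or d; no estimate.
    """

    ror: float | None
    ci_low: float | None
    ci_high: float | None
    status: str
    table: ContingencyTable


def build_contingency(reports, drug_code: str, event_term: str) -> ContingencyTable:
    """Count the 2x2 table for (drug_code, event_term) over a report universe.

    Membership is by set containment, so duplicated mentions within a
    report count once; each report lands in exactly one cell.
    """
    a = b = c = d = 0
    for r in reports:
        has_d = drug_code in r.drugs
        has_e = event_term in r.events
        if has_d and has_e:
            a += 1
        elif has_d:
            b += 1
        elif has_e:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_ror(table: ContingencyTable, z: float = 1.96, haldane: bool = False) -> RorResult:
    """ROR and Woolf CI for a 2x2 table.

    Parameters
    ----------
    z
        Normal quantile for the CI (1.96 for 95%).
    haldane
        Apply the Haldane–Anscombe continuity correction (+0.5 to every
        cell) when any cell is zero, instead of the sentinel/undefined
        statuses.  Off by default: zero cells are surfaced, not patched.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane and min(a, b, c, d) == 0:
        table = ContingencyTable(a + 0.5, b + 0.5, c + 0.5, d + 0.5)
        a, b, c, d = table.a, table.b, table.c, table.d
    if a == 0:
        return RorResult(None, None, None, "undefined", table)
    if c == 0:
        return RorResult(SENTINEL_ROR, None, None, "sentinel_c_zero", table)
    if b == 0 or d == 0:
        return RorResult(None, None, None, "undefined", table)
    ror = (a * d) / (c * b)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = z * se
    log_ror = math.log(ror)
    return RorResult(ror, math.exp(log_ror - half), math.exp(log_ror + half), "ok", table)


def classify_sdr(result: RorResult, min_a: int = 3) -> tuple[bool, str]:
    """SDR decision and case-count intensity stratum.

    Pairs with fewer than ``min_a`` case reports are excluded outright.
    The c = 0 sentinel with enough cases is treated as a possible SDR.
    Otherwise the pair is an SDR iff the CI lower bound exceeds 1, and
    falls in the ``3<=a<5`` or ``a>=5`` stratum.  Undefined results are
    never SDRs; their status field carries the annotation.
    """
    a = result.table.a
    if a < min_a:
        return False, INTENSITY_EXCLUDED
    if result.status == "sentinel_c_zero":
        return True, INTENSITY_SENTINEL
    stratum = INTENSITY_LOW if a < 5 else INTENSITY_HIGH
    if result.status != "ok":
        return False, stratum
    return result.ci_low > 1.0, stratum


@dataclass(frozen=True)
class SignalRecord:
    """One screened drug-event pair with its statistics and annotations.

    ``labelled`` is tri-state: True (event on the drug's label), False
    (drug curated, event absent), None (drug not in the knowledge table).
    """

    drug_code: str
    event_term: str
    result: RorResult
    is_sdr: bool
    intensity: str
    aware_group: str = "unclassified"
    labelled: bool | None = None


def screen_all(
    reports,
    aware_table=None,
    min_a: int = 3,
    z: float = 1.96,
    haldane: bool = False,
) -> list[SignalRecord]:
    """Screen every drug-event pair of the universe with at least ``min_a``
    case reports.

    Returns records sorted by (drug code, event term) for reproducible
    output.  Pairs with a = 0 are never emitted — they carry no
    information.
    """
    reports = list(reports)
    n = len(reports)
    drug_idx: dict[str, set[int]] = defaultdict(set)
    event_idx: dict[str, set[int]] = defaultdict(set)
    for i, r in enumerate(reports):
        for dcode in r.drugs:
            drug_idx[dcode].add(i)
        for term in r.events:
            event_idx[term].add(i)

    min_a = max(min_a, 1)
    records: list[SignalRecord] = []
    for dcode in sorted(drug_idx):
        d_set = drug_idx[dcode]
        for term in sorted(event_idx):
            e_set = event_idx[term]
            a = len(d_set & e_set)
            if a < min_a:
                continue
            b = len(d_set) - a
            c = len(e_set) - a
            table = ContingencyTable(a, b, c, n - a - b - c)
            result = compute_ror(table, z=z, haldane=haldane)
            is_sdr, intensity = classify_sdr(result, min_a=min_a)
            group = aware_table.group(dcode) if aware_table is not None else "unclassified"
            records.append(SignalRecord(dcode, term, result, is_sdr, intensity, group))
    return records
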