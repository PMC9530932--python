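"""Label-knowledge annotation, per-drug summaries and the end-to-end pipeline.

A detected disproportionality signal is only *new* if the event is not
already described in the drug's summary of product characteristics (SPC).
Label knowledge is supplied as data — a CSV of (drug, event) pairs the
label describes — because SPCs are unversioned documents; annotation is
tri-state so an uncurated drug is never mistaken for an unlabelled event.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import os
import warnings
from dataclasses import dataclass

import pandas as pd
import yaml

from .classification import AwareTable, load_atc_names, load_aware_table
from .disproportionality import SignalRecord, screen_all
from .errors import ConfigurationError, IntegrityError, PvSignalError
from .ingest import (
    FilterSpec,
    apply_filters,
    normalize_drug_code,
    normalize_event_term,
    read_line_listing,
    vocabulary,
)

__all__ = [
    "LabelKnowledgeTable",
    "DrugSummary",
    "PipelineConfig",
    "PipelineResult",
    "PipelineError",
    "load_label_table",
    "annotate_labelled",
    "summarize_by_drug",
    "signals_to_frame",
    "run_pipeline",
]


# drug_code -> set of normalized event terms the label describes
LabelKnowledgeTable = dict[str, frozenset[str]]


def load_label_table(path) -> LabelKnowledgeTable:
    """Read a label-knowledge CSV ``atc_code,event_term``; terms are
    normalized like ingest does, so matching is consistent."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in frame.columns]
    if cols[:2] != ["atc_code", "event_term"]:
        raise ConfigurationError(
            f"label table must have columns atc_code,event_term; got {list(frame.columns)}"
        )
    table: dict[str, set[str]] = {}
    for code, term in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        table.setdefault(normalize_drug_code(code), set()).add(normalize_event_term(term))
    return {code: frozenset(terms) for code, terms in table.items()}


def annotate_labelled(signals, table: LabelKnowledgeTable) -> list[SignalRecord]:
    """Flag each signal as labelled / unlabelled / unknown.

    ``labelled=True`` iff the (drug, event) pair is in the table;
    drugs absent from the table yield ``None`` (unknown), never False.
    Never alters SDR flags, ROR values or the record count.
    """
    out = []
    for s in signals:
        known = table.get(s.drug_code)
        flag = None if known is None else (s.event_term in known)
        out.append(dataclasses.replace(s, labelled=flag))
    return out


@dataclass(frozen=True)
class DrugSummary:
    """Per-drug report and signal counts over one universe."""

    drug_code: str
    n_reports: int
    n_signals: int
    aware_group: str = "unclassified"


def summarize_by_drug(reports, signals, aware_table: AwareTable | None = None) -> list[DrugSummary]:
    """Per-drug counts: reports mentioning the drug, and SDRs for the drug.

    A report mentioning two target drugs contributes one to each drug's
    ``n_reports`` (the distinct-report total is smaller; the pipeline run
    log records it alongside).  Sorted by n_reports descending, then code.

    Raises :class:`IntegrityError` when the signals were computed against
    a different universe (detected via the table totals).
    """
    reports = list(reports)
    n = len(reports)
    for s in signals:
        if s.result.table.n != n:
            raise IntegrityError(
                f"signal ({s.drug_code}, {s.event_term}) was computed over a universe "
                f"of {s.result.table.n} reports, but {n} reports were supplied"
            )
    report_counts: dict[str, int] = {}
    for r in reports:
        for code in r.drugs:
            report_counts[code] = report_counts.get(code, 0) + 1
    signal_counts: dict[str, int] = {}
    for s in signals:
        if s.is_sdr:
            signal_counts[s.drug_code] = signal_counts.get(s.drug_code, 0) + 1
    summaries = [
        DrugSummary(
            code,
            count,
            signal_counts.get(code, 0),
            aware_table.group(code) if aware_table is not None else "unclassified",
        )
        for code, count in report_counts.items()
    ]
    summaries.sort(key=lambda s: (-s.n_reports, s.drug_code))
    return summaries


def signals_to_frame(signals, names: dict[str, str] | None = None) -> pd.DataFrame:
    """Signal table with audit counts, one row per screened pair."""
    names = names or {}
    rows = []
    for s in signals:
        t = s.result.table
        rows.append(
            {
                "atc_code": s.drug_code,
                "drug": names.get(s.drug_code, ""),
                "event_term": s.event_term,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "ror": s.result.ror,
                "ci_low": s.result.ci_low,
                "ci_high": s.result.ci_high,
                "status": s.result.status,
                "is_sdr": s.is_sdr,
                "intensity": s.intensity,
                "aware_group": s.aware_group,
                "labelled": {True: "true", False: "false", None: "unknown"}[s.labelled],
            }
        )
    columns = [
        "atc_code", "drug", "event_term", "a", "b", "c", "d",
        "ror", "ci_low", "ci_high", "status", "is_sdr", "intensity",
        "aware_group", "labelled",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration (mirrors the YAML schema)."""

    input: str
    out_dir: str
    dialect: str = "long"
    atc_prefix: str = "J01"
    date_start: dt.date = dt.date(2018, 12, 1)
    date_end: dt.date = dt.date(2021, 12, 31)
    exclude_med_errors: bool = True
    keep_nonmatching_drugs: bool = False
    aware_table: str | None = None  # None -> packaged default
    label_table: str | None = None
    min_a: int = 3
    z: float = 1.96
    haldane: bool = False
    plot: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        for key in ("date_start", "date_end"):
            if key in data and isinstance(data[key], str):
                data[key] = dt.date.fromisoformat(data[key])
        return cls(**data)


@dataclass(frozen=True)
class PipelineResult:
    signals: list
    summaries: list
    run_log: dict


class PipelineError(PvSignalError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r}: {cause}")
        self.stage = stage


def _candidate_pairs(reports) -> set[tuple[str, str]]:
    """All (drug, event) pairs co-occurring in at least one report (a >= 1)."""
    pairs: set[tuple[str, str]] = set()
    for r in reports:
        for code in r.drugs:
            for term in r.events:
                pairs.add((code, term))
    return pairs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read → filter → screen → annotate → summarize → write the bundle.

    Writes ``signals.csv``, ``drug_summary.csv`` and ``run_log.json`` to
    ``config.out_dir``; deterministic given identical inputs (fixed row
    order and float formatting).  On any stage failure, partial outputs
    are removed before the error propagates with the stage name.
    """
    stage = "read"
    written: list[str] = []
    try:
        reports = read_line_listing(config.input, config.dialect)
        log: dict = {"config": _config_to_jsonable(config)}
        log["reports_read"] = len(reports)

        stage = "filter"
        spec = FilterSpec(
            atc_prefix=config.atc_prefix,
            date_start=config.date_start,
            date_end=config.date_end,
            exclude_med_errors=config.exclude_med_errors,
            keep_nonmatching_drugs=config.keep_nonmatching_drugs,
        )
        in_window = [r for r in reports if config.date_start <= r.date <= config.date_end]
        log["reports_in_date_window"] = len(in_window)
        no_med = [r for r in in_window if not (config.exclude_med_errors and r.med_error)]
        log["reports_after_med_error_exclusion"] = len(no_med)
        universe = apply_filters(reports, spec)
        log["reports_in_universe"] = len(universe)
        if not universe:
            warnings.warn("empty universe after filtering; signal table will be empty")
            log["warnings"] = ["empty universe after filtering"]

        stage = "screen"
        aware = load_aware_table(config.aware_table)
        drugs, events = vocabulary(universe)
        log["n_drugs"], log["n_events"] = len(drugs), len(events)
        candidates = _candidate_pairs(universe)
        signals = screen_all(
            universe, aware_table=aware, min_a=config.min_a, z=config.z, haldane=config.haldane
        )
        log["pairs_evaluated"] = len(candidates)
        log["pairs_excluded_min_a"] = len(candidates) - len(signals)
        log["pairs_reported"] = len(signals)

        stage = "annotate"
        if config.label_table is not None:
            signals = annotate_labelled(signals, load_label_table(config.label_table))
        log["sdrs_found"] = sum(s.is_sdr for s in signals)

        stage = "summarize"
        summaries = summarize_by_drug(universe, signals, aware_table=aware)

        stage = "write"
        os.makedirs(config.out_dir, exist_ok=True)
        signal_path = os.path.join(config.out_dir, "signals.csv")
        summary_path = os.path.join(config.out_dir, "drug_summary.csv")
        log_path = os.path.join(config.out_dir, "run_log.json")

        frame = signals_to_frame(signals, names=load_atc_names())
        written.append(signal_path)
        frame.to_csv(signal_path, index=False, float_format="%.6g")
        summary_frame = pd.DataFrame(
            [dataclasses.asdict(s) for s in summaries],
            columns=["drug_code", "n_reports", "n_signals", "aware_group"],
        )
        written.append(summary_path)
        summary_frame.to_csv(summary_path, index=False)
        written.append(log_path)
        with open(log_path, "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
            fh.write("\n")

        if config.plot:
            written.append(os.path.join(config.out_dir, "drug_summary.png"))
            _plot_summaries(summaries, written[-1])

        return PipelineResult(signals, summaries, log)
    except Exception as exc:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise PipelineError(stage, exc) from exc


def _config_to_jsonable(config: PipelineConfig) -> dict:
    out = {}
    for key, value in dataclasses.asdict(config).items():
        out[key] = value.isoformat() if isinstance(value, dt.date) else value
    return out


def _plot_summaries(summaries, path) -> None:
    # optional extra behind the plot flag; CSVs are the contract
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = summaries[:20]
    fig, ax = plt.subplots(figsize=(7, max(2, 0.35 * len(top))))
    codes = [s.drug_code for s in top][::-1]
    ax.barh(codes, [s.n_reports for s in top][::-1], color="#86b4d4", label="reports")
    ax.barh(codes, [s.n_signals for s in top][::-1], color="#c44e52", label="SDRs")
    ax.set_xlabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
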