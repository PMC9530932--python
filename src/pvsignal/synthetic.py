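"""Synthetic spontaneous-report databases with known association structure.

Emulates a VigiFlow-style line listing — multi-drug, multi-event reports
with ATC-coded drugs, MedDRA-Preferred-Term-like event strings, report
dates and a medication-error flag — under a fully specified generative
model, so every downstream screening stage can be tested against ground
truth without access to a national pharmacovigilance extract.

Generative model, per report (drawn independently for ``n_reports``):

* each drug is mentioned with its marginal probability, independently;
* each event is mentioned with its baseline probability, modified on the
  *odds* scale by the ``odds_multiplier`` of every injected signal whose
  drug is present: with baseline p and combined multiplier M the mention
  probability becomes ``M*p / (M*p + 1 - p)``.  With a single injecting
  drug the population odds ratio of the drug-event 2x2 table equals M
  exactly, so injected multipliers are the true ORs that recovery tests
  target;
* the report date is uniform over the inclusive date range, and the
  medication-error flag is Bernoulli(``med_error_prob``).

One :class:`numpy.random.Generator` seeded from ``config.seed`` drives a
single documented draw order (drug matrix, event matrix, dates, flags),
so an identical config reproduces the identical collection bit-for-bit.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import yaml

from .disproportionality import ContingencyTable
from .errors import ConfigurationError
from .ingest import IcsrReport, normalize_drug_code, normalize_event_term
from .listing import write_line_listing  # re-exported: the generator's output format

__all__ = ["SynthConfig", "generate_reports", "expected_contingency", "write_line_listing"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic reporting database.

    drugs / events are ``(name, marginal_prob)`` pairs; injected_signals
    are ``(drug_code, event_term, odds_multiplier)`` triples referring to
    entries of those vocabularies.  Names are normalized (drug codes
    uppercased, event terms casefolded) so generated collections are in
    the same canonical form the ingest reader produces.
    """

    n_reports: int
    drugs: tuple[tuple[str, float], ...]
    events: tuple[tuple[str, float], ...]
    injected_signals: tuple[tuple[str, str, float], ...] = ()
    med_error_prob: float = 0.0
    date_start: dt.date = dt.date(2018, 12, 1)
    date_end: dt.date = dt.date(2021, 12, 31)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ConfigurationError(f"n_reports must be >= 0, got {self.n_reports}")
        drugs = tuple((normalize_drug_code(c), float(p)) for c, p in self.drugs)
        events = tuple((normalize_event_term(t), float(p)) for t, p in self.events)
        object.__setattr__(self, "drugs", drugs)
        object.__setattr__(self, "events", events)
        for name, p in (*drugs, *events):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"marginal_prob for {name!r} must be in [0,1], got {p}")
        if not 0.0 <= self.med_error_prob <= 1.0:
            raise ConfigurationError(f"med_error_prob must be in [0,1], got {self.med_error_prob}")
        if self.date_start > self.date_end:
            raise ConfigurationError(
                f"date_start {self.date_start} is after date_end {self.date_end}"
            )
        drug_names = {c for c, _ in drugs}
        event_names = {t for t, _ in events}
        signals = []
        for code, term, mult in self.injected_signals:
            code = normalize_drug_code(code)
            term = normalize_event_term(term)
            if code not in drug_names:
                raise ConfigurationError(f"injected signal refers to unknown drug {code!r}")
            if term not in event_names:
                raise ConfigurationError(f"injected signal refers to unknown event {term!r}")
            mult = float(mult)
            if not (np.isfinite(mult) and mult >= 0):
                raise ConfigurationError(
                    f"odds_multiplier for ({code}, {term}) must be >= 0, got {mult}"
                )
            signals.append((code, term, mult))
        object.__setattr__(self, "injected_signals", tuple(signals))

    @classmethod
    def from_mapping(cls, data: dict) -> "SynthConfig":
        """Build from a plain mapping (parsed YAML/JSON mirroring field names)."""
        kw = dict(data)
        for key in ("date_start", "date_end"):
            if key in kw and isinstance(kw[key], str):
                kw[key] = dt.date.fromisoformat(kw[key])
        kw["drugs"] = tuple((d["code"], d["marginal_prob"]) if isinstance(d, dict) else tuple(d)
                            for d in kw["drugs"])
        kw["events"] = tuple((e["term"], e["marginal_prob"]) if isinstance(e, dict) else tuple(e)
                             for e in kw["events"])
        if "injected_signals" in kw:
            kw["injected_signals"] = tuple(
                (s["drug_code"], s["event_term"], s["odds_multiplier"])
                if isinstance(s, dict) else tuple(s)
                for s in kw["injected_signals"]
            )
        return cls(**kw)

    @classmethod
    def from_file(cls, path) -> "SynthConfig":
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_mapping(data)


def _modified_prob(p: np.ndarray, mult: np.ndarray) -> np.ndarray:
    """Apply an odds-scale multiplier: p' = M p / (M p + 1 - p)."""
    num = mult * p
    den = num + (1.0 - p)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def generate_reports(config: SynthConfig) -> list[IcsrReport]:
    """Draw the synthetic report collection defined by ``config``."""
    n = config.n_reports
    rng = np.random.default_rng(config.seed)
    drug_codes = [c for c, _ in config.drugs]
    event_terms = [t for t, _ in config.events]
    p_drug = np.array([p for _, p in config.drugs], dtype=float)
    p_event = np.array([p for _, p in config.events], dtype=float)

    drug_mat = rng.random((n, len(drug_codes))) < p_drug

    # combined odds multiplier per (report, event) from injected signals
    mult = np.ones((n, len(event_terms)))
    d_pos = {c: j for j, c in enumerate(drug_codes)}
    e_pos = {t: j for j, t in enumerate(event_terms)}
    for code, term, m in config.injected_signals:
        j = e_pos[term]
        mult[:, j] *= np.where(drug_mat[:, d_pos[code]], m, 1.0)
    event_mat = rng.random((n, len(event_terms))) < _modified_prob(p_event, mult)

    span = (config.date_end - config.date_start).days
    day_offsets = rng.integers(0, span + 1, size=n)
    med_flags = rng.random(n) < config.med_error_prob

    width = max(6, len(str(max(n, 1))))
    reports = []
    for i in range(n):
        reports.append(
            IcsrReport(
                report_id=f"R{i + 1:0{width}d}",
                date=config.date_start + dt.timedelta(days=int(day_offsets[i])),
                drugs=frozenset(drug_codes[j] for j in np.flatnonzero(drug_mat[i])),
                events=frozenset(event_terms[j] for j in np.flatnonzero(event_mat[i])),
                med_error=bool(med_flags[i]),
            )
        )
    return reports


def expected_contingency(config: SynthConfig, drug_code: str, event_term: str) -> ContingencyTable:
    """Expected (non-integer) 2x2 counts for a pair under the generative model.

    Analytic oracle for parameter-recovery tests: enumerates the joint
    presence/absence of every drug that injects into the target event
    (plus the target drug) and accumulates the four joint probabilities
    exactly.  ``a+b+c+d`` equals ``n_reports`` by construction.
    """
    drug_code = normalize_drug_code(drug_code)
    event_term = normalize_event_term(event_term)
    p_by_drug = dict(config.drugs)
    p_by_event = dict(config.events)
    if drug_code not in p_by_drug:
        raise KeyError(f"unknown drug code {drug_code!r}")
    if event_term not in p_by_event:
        raise KeyError(f"unknown event term {event_term!r}")

    injectors: dict[str, float] = {}
    for code, term, m in config.injected_signals:
        if term == event_term:
            injectors[code] = injectors.get(code, 1.0) * m
    relevant = sorted(set(injectors) | {drug_code})

    p_e = p_by_event[event_term]
    p_de = p_d_only = 0.0  # P(drug & event), P(drug & not event)
    p_e_only = 0.0
    for present in product((False, True), repeat=len(relevant)):
        prob = 1.0
        m = 1.0
        target_present = False
        for code, here in zip(relevant, present):
            pd = p_by_drug[code]
            prob *= pd if here else (1.0 - pd)
            if here:
                m *= injectors.get(code, 1.0)
                if code == drug_code:
                    target_present = True
        if prob == 0.0:
            continue
        num = m * p_e
        den = num + (1.0 - p_e)
        pe = num / den if den > 0 else 0.0
        if target_present:
            p_de += prob * pe
            p_d_only += prob * (1.0 - pe)
        else:
            p_e_only += prob * pe

    n = config.n_reports
    a = n * p_de
    b = n * p_d_only
    c = n * p_e_only
    return ContingencyTable(a, b, c, n - a - b - c)
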