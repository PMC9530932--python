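# Methods

## Design and counting unit

The screen implements the case/non-case design over a spontaneous-report
database: for each target drug P and event term R, reports of R are the
cases and all other reports the non-cases, and disproportionality
compares drug exposure between them via the reporting odds ratio
ROR = (a·d)/(c·b). The counting unit is the *report* (ICSR), not the
drug–event mention: a report mentioning a drug or event several times
contributes once, and each report falls in exactly one cell of each 2×2
table. Mentions are therefore stored as deduplicated sets on the report.

The analysis universe is produced by three inclusion rules applied to
the raw listing: an inclusive calendar window on the report date, the
requirement that a report mention at least one drug of the target ATC
class (prefix match, e.g. `J01`), and the exclusion of reports flagged
as medication errors. The medication-error flag is report-level, since
whole notifications are excluded, not individual events.

**Universe policy.** After filtering, drug mentions outside the ATC
class are dropped by default, so the denominator "reports without P"
means other reports *of the class* — consistent with screening a
class-restricted database pull. `FilterSpec(keep_nonmatching_drugs=True)`
keeps class-external comparator mentions for sensitivity analyses. No
suspect-vs-concomitant role filter is applied: the line-listing formats
carry no role field, so none is invented.

## Estimation and decision rules

* **CI method.** Woolf (log-normal): `exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`
  with z = 1.96 by default; `z` is exposed so other levels (or the exact
  normal quantile) can be used.
* **SDR rule.** A pair is a signal of disproportionate reporting when the
  CI lower bound exceeds 1 and a ≥ `min_a` (default 3, the conventional
  minimum-case screen; exposed). This is a one-sided test at the 2.5%
  level — the calibration target of the validation suite.
* **Intensity strata.** Screened pairs are labelled `3<=a<5` or `a>=5`;
  sentinel pairs `a>=3_c=0`; pairs below the case minimum
  `excluded_a<3` (never SDRs).
* **Zero cells.** c = 0 with a > 0 yields the conventional sentinel
  ROR = 99.9 with status `sentinel_c_zero` and no CI: the value is a
  marker of a possible signal, not an estimate, and the explicit status
  lets numeric summaries exclude it. A zero in b or d (or a = 0) yields
  status `undefined`; nothing is silently corrected. A Haldane–Anscombe
  +0.5 correction is available (`haldane=True`) but off by default:
  zero cells are surfaced, not patched. Pairs with a = 0 are never
  emitted — they carry no information.
* **Ordering.** Output is sorted by (drug code, event term) and floats
  are written with fixed formatting, so identical inputs give
  byte-identical bundles.
* **Term normalization.** Drug codes are trimmed and uppercased; event
  terms casefolded with internal whitespace collapsed. Deterministic and
  auditable; no fuzzy matching, no MedDRA hierarchy traversal.

## Annotation

AWaRe grouping (Access / Watch / Reserve) is a total, deterministic
lookup against a packaged CSV of level-5 ATC codes covering the systemic
antibacterials most often seen in screening; unknown codes map to
`unclassified` rather than erroring, because classification is an
annotation, not a gate, and WHO revises the list (users can supply their
own table). Label knowledge is likewise user-supplied data
(`atc_code,event_term` CSV) rather than scraped from regulator websites:
SPCs are unversioned documents. The labelled flag is tri-state — True
(on label), False (drug curated, event absent), None (drug not curated) —
so incomplete curation can never masquerade as a new signal.

## Synthetic reporting databases

The generator emulates a VigiFlow-like line listing with a fully
specified generative model. Per report, independently: each drug is
mentioned with its marginal probability; each event with its baseline
probability modified *on the odds scale* by the product of the
`odds_multiplier`s of injected signals whose drug is present
(`p' = M·p / (M·p + 1 − p)`); the date is uniform over the configured
range and the medication-error flag Bernoulli. Injection on the odds
scale means that with a single injecting drug the population odds ratio
of the report-level 2×2 table equals the multiplier exactly, so the
injected value is the true OR that recovery tests target.
`expected_contingency` provides the analytic expectation of any pair's
table by enumerating the joint presence of the (few) drugs that modify
the event. A single `numpy` generator seeded from `config.seed` drives a
fixed draw order (drugs, events, dates, flags), so identical configs
reproduce identical collections bit-for-bit.

What the generator deliberately does **not** model: reporting biases
(notoriety, stimulated reporting), duplicate reports, under-reporting
dynamics, event-term hierarchies, or correlated co-prescription. Passing
calibration and recovery tests therefore demonstrates that the
*statistics* are implemented correctly under independent reporting; it
does not certify performance on real spontaneous data, where those
biases dominate the error budget.

## Validation conditions and numerical choices

* **Null calibration.** 200 replicates of 20,000 reports, 10 drugs and
  20 events with no injected association; marginal probabilities spread
  geometrically over 0.10–0.30 (drugs) and 0.05–0.15 (events), giving
  expected case counts of roughly 100–900 per pair, where the one-sided
  2.5% level of the Woolf-based screen is near its asymptote. The
  fraction of eligible pairs (a ≥ 3, all cells positive) flagged SDR is
  compared to 0.025 within 3 Monte-Carlo standard errors (empirical SE
  across replicates, which absorbs the within-replicate correlation from
  shared reports).
* **Recovery.** One drug (p = 0.15), one event (baseline p = 0.02),
  injected OR 5, 2,200 reports → expected a ≈ 30.6; 500 replicates.
  95% CI coverage of the true OR and the mean of ln ROR are checked at
  3 Monte-Carlo standard errors (the log-OR estimator's small-sample
  bias at a ≈ 30 is well inside that band).
* **Exhaustive invariants.** All positive-cell tables with n ≤ 40 are
  enumerated: role-swap symmetry (b ↔ c), CI bracketing, and strict
  monotonicity of the ROR in a at fixed margins.
* **Oracle equivalence.** The ROR is compared bit-for-bit against an
  odds ratio recomputed from raw report sets in exact rational
  arithmetic, and the Woolf CI against statsmodels' independent
  implementation.

These problem sizes keep the whole suite around a minute on one CPU
while leaving Monte-Carlo tolerances tight enough to be meaningful.

## Degenerate inputs and errors

Empty universes screen to an empty signal table with an explicit
warning; header-only listings are valid and round-trip. Conflicting
duplicate report ids (same id, different date or flag) are hard
integrity errors, never last-wins merges. Configuration objects validate
eagerly (probabilities in [0,1], odds multipliers ≥ 0, vocabulary
membership of injected signals, ordered date ranges) and name the
offending entry. Pipeline failures carry the stage name and remove any
partially written outputs.

## Known limitations

Only the ROR is implemented — no PRR, IC/BCPNN or Bayesian shrinkage,
and no multiple-comparison correction: with hundreds of pairs screened
at the 2.5% one-sided level, a corresponding share of null pairs will be
flagged by construction, which is the accepted trade-off of frequentist
first-pass screening. Signal *detection* is the scope; validation,
causality assessment and literature corroboration are downstream manual
steps. Free-text drug-name → ATC mapping and duplicate-report detection
are out of scope; inputs are assumed ATC-coded and deduplicated.
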