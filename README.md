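# pvsignal

Disproportionality screening of spontaneous adverse-drug-event reports:
from an Individual Case Safety Report (ICSR) line listing to a table of
signals of disproportionate reporting (SDRs), with WHO AWaRe / ATC
annotation for antibacterials and a synthetic report generator for
validation.

It is written for pharmacovigilance analysts and pharmacoepidemiologists
who work with national spontaneous-reporting extracts (VigiFlow-style
line listings) and want a reproducible, auditable screen rather than a
spreadsheet: every count, estimate and decision in the output can be
traced back to the report universe that produced it.

## The statistic

Screening uses the case/non-case design. For a target drug P and target
event R, each report in the universe falls in exactly one cell of a 2×2
table:

|          | event R | not R |
|----------|---------|-------|
| drug P   | a       | b     |
| not P    | c       | d     |

The reporting odds ratio is

    ROR = (a·d) / (c·b)

with a Woolf (log-normal) 95% confidence interval

    exp( ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) ).

A drug–event pair is an **SDR** when the CI lower bound exceeds 1 and the
pair has at least 3 case reports; screened pairs are stratified by case
count (`3<=a<5` vs `a>=5`). When **c = 0** — every report of the event
also lists the drug — the ratio is a division by zero and the
conventional sentinel value **99.9** is assigned, flagged with an
explicit `sentinel_c_zero` status so summaries never mistake the marker
for an estimate. Pairs with a zero in b or d are reported as `undefined`
rather than silently corrected (a Haldane–Anscombe +0.5 option exists but
is off by default).

Antibacterial drug codes (ATC class J01) are annotated with their WHO
AWaRe stewardship group (Access / Watch / Reserve) from a packaged,
user-overridable table, and signals can be annotated against a label
knowledge table (drug → events described in its SPC) to separate known
reactions from candidate new signals.

## Worked example

```python
from pvsignal import ContingencyTable, classify_sdr, compute_ror

result = compute_ror(ContingencyTable(a=5, b=10, c=20, d=1000))
is_sdr, stratum = classify_sdr(result)
```

Running `python examples/ror_basics.py` prints:

```
  disproportionate: a=  5  ROR=25.00  CI=(7.83, 79.84)  status=ok  SDR=True  stratum=a>=5
        equal odds: a= 10  ROR=1.00  CI=(0.40, 2.51)  status=ok  SDR=False  stratum=a>=5
    c = 0 sentinel: a=  5  ROR=99.90  CI=undefined  status=sentinel_c_zero  SDR=True  stratum=a>=3_c=0
```

The first pair is reported 25 times more often with the drug than the
equal-odds expectation and its CI excludes 1, so it is an SDR in the
`a>=5` stratum; the second sits exactly at unity; the third has no
event reports outside the drug, so the 99.9 sentinel marks a possible
SDR without pretending to estimate a ratio.

`examples/simulate_and_screen.py` plants one association (true odds
ratio 8 between azithromycin and gait disturbance) in a 10,000-report
synthetic database and screens it — the planted pair surfaces at
ROR 6.76 with CI lower bound 5.23, while null pairs hover around 1.
`examples/pipeline_from_files.py` runs the full file-to-bundle pipeline
including medication-error exclusion, the J01 universe filter and label
annotation.

The command line mirrors the library:

```
pvsignal simulate --config synth.yaml --out listing.csv
pvsignal ingest --input listing.csv --from 2018-12-01 --to 2021-12-31
pvsignal run --config pipeline.yaml
```

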