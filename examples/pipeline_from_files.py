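"""The end-to-end pipeline: line listing in, signal bundle out.

Writes a synthetic VigiFlow-like line listing to disk, plus a small label
knowledge table saying the planted event is NOT on the drug's label, then
runs the full pipeline (read -> filter -> screen -> annotate -> summarize)
from a config object.  The run log records the report counts at each
filter stage; `labelled=false` rows are the candidate *new* signals a
reviewer would take to the literature.
"""

import datetime as dt
import tempfile
from pathlib import Path

from pvsignal import (
    PipelineConfig,
    SynthConfig,
    generate_reports,
    run_pipeline,
    write_line_listing,
)

workdir = Path(tempfile.mkdtemp(prefix="pvsignal_example_"))

synth = SynthConfig(
    n_reports=8_000,
    drugs=[("J01FA10", 0.10), ("J01DD04", 0.15), ("J01CA04", 0.08)],
    events=[("rash", 0.05), ("nausea", 0.06), ("gait disturbance", 0.02)],
    injected_signals=[("J01FA10", "gait disturbance", 8.0)],
    med_error_prob=0.05,
    seed=7,
)
listing = workdir / "listing.csv"
write_line_listing(generate_reports(synth), listing, "long")

labels = workdir / "labels.csv"
labels.write_text(
    "atc_code,event_term\n"
    "J01FA10,rash\nJ01FA10,nausea\n"      # azithromycin label: no gait disturbance
    "J01DD04,rash\nJ01DD04,nausea\n"
)

result = run_pipeline(
    PipelineConfig(
        input=str(listing),
        out_dir=str(workdir / "out"),
        atc_prefix="J01",
        date_start=dt.date(2018, 12, 1),
        date_end=dt.date(2021, 12, 31),
        label_table=str(labels),
    )
)

log = result.run_log
print(f"reports read:              {log['reports_read']}")
print(f"in date window:            {log['reports_in_date_window']}")
print(f"after med-error exclusion: {log['reports_after_med_error_exclusion']}")
print(f"analysis universe:         {log['reports_in_universe']}")
print(f"pairs evaluated (a>=1):    {log['pairs_evaluated']}")
print(f"pairs reported (a>=3):     {log['pairs_reported']}")
print(f"SDRs found:                {log['sdrs_found']}\n")

print("unlabelled or uncurated SDRs (candidate new signals):")
for s in result.signals:
    if s.is_sdr and s.labelled is not True:
        tag = "not on label" if s.labelled is False else "drug not curated"
        print(f"  {s.drug_code}  {s.event_term:18} ROR={s.result.ror:6.2f}  [{tag}]")
print(f"\noutputs written to {workdir / 'out'}")
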