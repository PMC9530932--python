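"""Generate a synthetic reporting database and screen it.

Simulates 10,000 spontaneous reports over five antibacterials and six
event terms with one planted association — azithromycin (J01FA10) and
gait disturbance at a true odds ratio of 8 — then screens every
drug-event pair with at least 3 case reports.  The planted pair should
surface as the clear SDR; a few null pairs may cross the threshold by
chance, which is exactly the false-positive behaviour the screen's
one-sided 2.5% level implies.
"""

from pvsignal import SynthConfig, generate_reports, load_aware_table, screen_all

config = SynthConfig(
    n_reports=10_000,
    drugs=[
        ("J01FA10", 0.10),  # azithromycin
        ("J01DD04", 0.15),  # ceftriaxone
        ("J01CA04", 0.08),  # amoxicillin
        ("J01XB02", 0.03),  # polymyxin B
        ("J01MA02", 0.12),  # ciprofloxacin
    ],
    events=[
        ("rash", 0.06),
        ("nausea", 0.05),
        ("gait disturbance", 0.015),
        ("phlebitis", 0.04),
        ("pyrexia", 0.05),
        ("dyspnoea", 0.02),
    ],
    injected_signals=[("J01FA10", "gait disturbance", 8.0)],
    med_error_prob=0.04,
    seed=42,
)

reports = generate_reports(config)
records = screen_all(reports, aware_table=load_aware_table())

print(f"universe: {len(reports)} reports, {len(records)} screened pairs\n")
print(f"{'drug':8} {'event':18} {'a':>4} {'ROR':>6} {'CI low':>7} {'SDR':>5}  AWaRe")
for r in sorted(records, key=lambda r: -(r.result.ror or 0))[:8]:
    lo = f"{r.result.ci_low:.2f}" if r.result.ci_low is not None else "--"
    print(
        f"{r.drug_code:8} {r.event_term:18} {r.result.table.a:4.0f} "
        f"{r.result.ror:6.2f} {lo:>7} {str(r.is_sdr):>5}  {r.aware_group}"
    )
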