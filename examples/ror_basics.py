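"""Reporting odds ratio on hand-built 2x2 tables.

Builds three contingency tables — a clear disproportionality, an equal-odds
pair, and a zero-denominator (c = 0) pair — and prints the ROR, its Woolf
95% CI and the signal decision for each.  A pair is a signal of
disproportionate reporting (SDR) when the CI lower bound exceeds 1 and at
least 3 case reports exist; with c = 0 the ROR is undefined by division and
the conventional 99.9 marker flags a possible SDR instead.
"""

from pvsignal import ContingencyTable, classify_sdr, compute_ror

tables = {
    "disproportionate": ContingencyTable(a=5, b=10, c=20, d=1000),
    "equal odds": ContingencyTable(a=10, b=10, c=100, d=100),
    "c = 0 sentinel": ContingencyTable(a=5, b=100, c=0, d=1000),
}

for label, table in tables.items():
    result = compute_ror(table)
    is_sdr, intensity = classify_sdr(result)
    ci = (
        f"({result.ci_low:.2f}, {result.ci_high:.2f})"
        if result.status == "ok"
        else "undefined"
    )
    print(
        f"{label:>18}: a={table.a:>3.0f}  ROR={result.ror:.2f}  CI={ci}  "
        f"status={result.status}  SDR={is_sdr}  stratum={intensity}"
    )
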