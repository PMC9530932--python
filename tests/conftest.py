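import datetime as dt

import pytest

from pvsignal import IcsrReport


def report(rid, drugs=(), events=(), date=dt.date(2020, 6, 1), med_error=False):
    return IcsrReport(rid, date, frozenset(drugs), frozenset(events), med_error)


@pytest.fixture
def six_report_universe():
    """2 reports with (P, R), 1 with P only, 2 with R only, 1 with neither
    -> (a, b, c, d) = (2, 1, 2, 1) for the pair (J01FA10, gait disturbance)."""
    P, R = "J01FA10", "gait disturbance"
    other_d, other_e = "J01DD04", "nausea"
    return [
        report("R1", [P], [R]),
        report("R2", [P, other_d], [R, other_e]),
        report("R3", [P], [other_e]),
        report("R4", [other_d], [R]),
        report("R5", [other_d], [R]),
        report("R6", [other_d], [other_e]),
    ]
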