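import datetime as dt
import math

import numpy as np
import pytest

from pvsignal import (
    ConfigurationError,
    SynthConfig,
    build_contingency,
    expected_contingency,
    generate_reports,
    read_line_listing,
    write_line_listing,
)

from conftest import report

ONE_PAIR = dict(drugs=[("J01FA10", 0.5)], events=[("gait disturbance", 0.5)])


class TestConfigValidation:
    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError, match="marginal_prob"):
            SynthConfig(n_reports=10, drugs=[("J01FA10", 1.5)], events=[("rash", 0.1)])

    def test_injection_naming_unknown_entry_rejected(self):
        with pytest.raises(ConfigurationError, match="J01XX99"):
            SynthConfig(
                n_reports=10,
                drugs=[("J01FA10", 0.1)],
                events=[("rash", 0.1)],
                injected_signals=[("J01XX99", "rash", 2.0)],
            )
        with pytest.raises(ConfigurationError, match="headache"):
            SynthConfig(
                n_reports=10,
                drugs=[("J01FA10", 0.1)],
                events=[("rash", 0.1)],
                injected_signals=[("J01FA10", "headache", 2.0)],
            )

    def test_negative_odds_multiplier_rejected(self):
        with pytest.raises(ConfigurationError, match="odds_multiplier"):
            SynthConfig(n_reports=10, drugs=[("J01FA10", 0.1)], events=[("rash", 0.1)],
                        injected_signals=[("J01FA10", "rash", -1.0)])

    def test_from_mapping_mirrors_field_names(self):
        cfg = SynthConfig.from_mapping({
            "n_reports": 5,
            "drugs": [["J01FA10", 0.2]],
            "events": [{"term": "rash", "marginal_prob": 0.1}],
            "injected_signals": [["J01FA10", "rash", 3.0]],
            "date_start": "2019-01-01",
            "date_end": "2019-12-31",
            "seed": 42,
        })
        assert cfg.injected_signals == (("J01FA10", "rash", 3.0),)
        assert cfg.date_start == dt.date(2019, 1, 1)


class TestGenerateReports:
    def test_zero_reports_yields_empty_collection(self):
        assert generate_reports(SynthConfig(n_reports=0, **ONE_PAIR)) == []

    def test_identical_config_reproduces_identical_collection(self):
        cfg = SynthConfig(n_reports=500, med_error_prob=0.2, seed=11, **ONE_PAIR)
        assert generate_reports(cfg) == generate_reports(cfg)

    def test_different_seed_changes_the_draw(self):
        a = generate_reports(SynthConfig(n_reports=500, seed=1, **ONE_PAIR))
        b = generate_reports(SynthConfig(n_reports=500, seed=2, **ONE_PAIR))
        assert a != b

    def test_independent_pair_joint_frequency_matches_binomial(self):
        # p(drug & event) = 0.25; binomial SE = sqrt(p(1-p)/n)
        n = 20000
        cfg = SynthConfig(n_reports=n, seed=3, **ONE_PAIR)
        t = build_contingency(generate_reports(cfg), "J01FA10", "gait disturbance")
        se = math.sqrt(0.25 * 0.75 / n)
        assert abs(t.a / n - 0.25) <= 3 * se

    def test_injected_odds_multiplier_is_recovered_on_log_odds_scale(self):
        # Woolf SE on the realized table bounds the sampling error of ln(OR)
        n = 20000
        cfg = SynthConfig(
            n_reports=n,
            drugs=[("J01FA10", 0.2)],
            events=[("gait disturbance", 0.1)],
            injected_signals=[("J01FA10", "gait disturbance", 5.0)],
            seed=4,
        )
        t = build_contingency(generate_reports(cfg), "J01FA10", "gait disturbance")
        ln_or = math.log((t.a * t.d) / (t.b * t.c))
        woolf_se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        assert abs(ln_or - math.log(5.0)) <= 3 * woolf_se

    def test_dates_within_range_and_flags_match_probability(self):
        cfg = SynthConfig(
            n_reports=5000,
            med_error_prob=0.3,
            date_start=dt.date(2019, 1, 1),
            date_end=dt.date(2019, 1, 31),
            seed=5,
            **ONE_PAIR,
        )
        reports = generate_reports(cfg)
        assert all(cfg.date_start <= r.date <= cfg.date_end for r in reports)
        frac = np.mean([r.med_error for r in reports])
        assert abs(frac - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / 5000)


class TestExpectedContingency:
    def test_independence_splits_evenly(self):
        cfg = SynthConfig(n_reports=1000, **ONE_PAIR)
        t = expected_contingency(cfg, "J01FA10", "gait disturbance")
        assert (t.a, t.b, t.c, t.d) == (250, 250, 250, 250)

    def test_identity_multiplier_equals_no_injection(self):
        base = SynthConfig(n_reports=1000, **ONE_PAIR)
        injected = SynthConfig(
            n_reports=1000,
            injected_signals=[("J01FA10", "gait disturbance", 1.0)],
            **ONE_PAIR,
        )
        t0 = expected_contingency(base, "J01FA10", "gait disturbance")
        t1 = expected_contingency(injected, "J01FA10", "gait disturbance")
        assert (t0.a, t0.b, t0.c, t0.d) == pytest.approx((t1.a, t1.b, t1.c, t1.d))

    def test_injected_pair_matches_direct_probability_arithmetic(self):
        # p_drug=0.2, baseline p_event=0.1, multiplier 5, n=10000:
        # P(event|drug) = 0.5/1.4; hand-computed joint probabilities
        cfg = SynthConfig(
            n_reports=10000,
            drugs=[("J01FA10", 0.2)],
            events=[("gait disturbance", 0.1)],
            injected_signals=[("J01FA10", "gait disturbance", 5.0)],
        )
        t = expected_contingency(cfg, "J01FA10", "gait disturbance")
        pe_given_d = 0.5 / 1.4
        assert t.a == pytest.approx(10000 * 0.2 * pe_given_d)
        assert t.b == pytest.approx(10000 * 0.2 * (1 - pe_given_d))
        assert t.c == pytest.approx(10000 * 0.8 * 0.1)
        assert t.d == pytest.approx(10000 * 0.8 * 0.9)
        assert t.n == 10000

    def test_unknown_pair_is_a_lookup_error(self):
        cfg = SynthConfig(n_reports=10, **ONE_PAIR)
        with pytest.raises(KeyError):
            expected_contingency(cfg, "J01XX99", "gait disturbance")
        with pytest.raises(KeyError):
            expected_contingency(cfg, "J01FA10", "headache")

    def test_realized_counts_converge_to_expected(self):
        # consistency of the generator with its own analytic oracle
        cfg = SynthConfig(
            n_reports=30000,
            drugs=[("J01FA10", 0.15), ("J01DD04", 0.25)],
            events=[("rash", 0.05), ("nausea", 0.12)],
            injected_signals=[("J01FA10", "rash", 4.0), ("J01DD04", "rash", 2.0)],
            seed=6,
        )
        reports = generate_reports(cfg)
        for code, term in [("J01FA10", "rash"), ("J01DD04", "rash"), ("J01FA10", "nausea")]:
            exp = expected_contingency(cfg, code, term)
            got = build_contingency(reports, code, term)
            for cell in "abcd":
                e, g = getattr(exp, cell), getattr(got, cell)
                se = math.sqrt(max(e * (1 - e / exp.n), 1.0))
                assert abs(g - e) <= 3 * se, (code, term, cell, g, e)


class TestLineListingRoundTrip:
    FIXTURE = [
        report("R001", ["J01FA10", "J01CA04"], ["rash", "nausea", "vomiting"]),
        report("R002", ["J01DD04"], ["rash"], med_error=True),
        report("R003", [], ["dizziness"]),
    ]

    @pytest.mark.parametrize("dialect", ["long", "wide"])
    def test_three_report_fixture_round_trips(self, tmp_path, dialect):
        path = tmp_path / "listing.csv"
        write_line_listing(self.FIXTURE, path, dialect)
        assert read_line_listing(path, dialect) == self.FIXTURE

    def test_long_dialect_emits_cartesian_rows(self, tmp_path):
        path = tmp_path / "listing.csv"
        write_line_listing([self.FIXTURE[0]], path, "long")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + 2 * 3
        assert all(line.startswith("R001,") for line in lines[1:])

    @pytest.mark.parametrize("dialect", ["long", "wide"])
    def test_empty_collection_writes_header_only(self, tmp_path, dialect):
        path = tmp_path / "empty.csv"
        write_line_listing([], path, dialect)
        assert len(path.read_text().strip().splitlines()) == 1
        assert read_line_listing(path, dialect) == []

    def test_generated_collection_round_trips(self, tmp_path):
        cfg = SynthConfig(n_reports=200, med_error_prob=0.1, seed=9, **ONE_PAIR)
        reports = generate_reports(cfg)
        path = tmp_path / "gen.csv"
        write_line_listing(reports, path, "long")
        assert read_line_listing(path, "long") == reports
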