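"""Disproportionality statistics, signal criteria, SOC aggregation, descriptives."""

import math
from decimal import Decimal, getcontext
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxsig.reports import MedDRADict, ReportSet
from toxsig.signals import (
    ContingencyTable, SignalCriteria, SOCSummary, aggregate_by_soc,
    build_contingency, chi_square, compute_statistics, descriptive_distribution,
    detect_all_signals, evaluate_signal, percentage, prr, ror_with_ci,
    select_key_socs,
)
from conftest import make_report

cells = st.integers(min_value=1, max_value=500)


def oracle_ror_ci(a, b, c, d, digits=40):
    """High-precision CI recomputation with the decimal module (independent path)."""
    getcontext().prec = digits
    da, db, dc, dd = (Decimal(x) for x in (a, b, c, d))
    ror = da * dd / (db * dc)
    se = (1 / da + 1 / db + 1 / dc + 1 / dd).sqrt()
    half = Decimal("1.96") * se
    return float(ror), float((ror.ln() - half).exp()), float((ror.ln() + half).exp())


def oracle_chi2_oe(a, b, c, d):
    """Sum of (O-E)^2/E over the four cells."""
    n = a + b + c + d
    obs = [a, b, c, d]
    exp = [(a + b) * (a + c) / n, (a + b) * (b + d) / n,
           (c + d) * (a + c) / n, (c + d) * (b + d) / n]
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


class TestContingency:
    def test_one_report_per_cell(self, toy_reports):
        t = build_contingency(toy_reports, "drug_x", "headache")
        assert t.cells() == (1, 1, 1, 1)

    def test_duplicate_pt_counts_once(self):
        rs = ReportSet([make_report("r1", pts=("rash", "Rash", " rash ")),
                        make_report("r2", drug="other", pts=("fever",))])
        t = build_contingency(rs, "selumetinib", "rash")
        assert t.a == 1 and t.n == 2

    def test_absent_drug_is_legal(self, toy_reports):
        t = build_contingency(toy_reports, "no_such_drug", "headache")
        assert (t.a, t.b) == (0, 0) and t.n == 4

    def test_empty_pt_rejected(self, toy_reports):
        with pytest.raises(ValueError):
            build_contingency(toy_reports, "drug_x", "  ")

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestRor:
    def test_worked_example(self):
        t = ContingencyTable(3, 7, 30, 960)
        ror, lo, hi = ror_with_ci(t)
        assert ror == pytest.approx(float(Fraction(3 * 960, 7 * 30)), rel=1e-12)
        o_ror, o_lo, o_hi = oracle_ror_ci(3, 7, 30, 960)
        assert (ror, lo, hi) == pytest.approx((o_ror, o_lo, o_hi), rel=1e-12)
        assert lo == pytest.approx(3.380, abs=5e-4)
        assert hi == pytest.approx(55.64, abs=5e-2)

    def test_symmetric_table(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(10, 10, 10, 10))
        assert ror == pytest.approx(1.0) and lo < 1.0 < hi

    def test_scaling_preserves_ror_and_narrows_ci(self):
        r1, lo1, hi1 = ror_with_ci(ContingencyTable(3, 7, 30, 960))
        r2, lo2, hi2 = ror_with_ci(ContingencyTable(30, 70, 300, 9600))
        assert r2 == pytest.approx(r1, rel=1e-12)
        assert hi2 - lo2 < hi1 - lo1

    def test_zero_cell_policies(self):
        t = ContingencyTable(3, 0, 30, 960)
        assert ror_with_ci(t) is None
        ror, lo, hi = ror_with_ci(t, zero_cell="haldane")
        assert ror == pytest.approx((3.5 * 960.5) / (0.5 * 30.5), rel=1e-12)
        stats = compute_statistics(t, zero_cell="haldane")
        assert stats.continuity_corrected

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, derandomize=True)
    def test_ror_times_bc_equals_ad(self, a, b, c, d):
        ror, _, _ = ror_with_ci(ContingencyTable(a, b, c, d))
        assert ror * b * c == pytest.approx(a * d, rel=1e-9)

    @given(a=st.integers(1, 200), b=cells, c=cells, d=cells)
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_a(self, a, b, c, d):
        r1, _, _ = ror_with_ci(ContingencyTable(a, b, c, d))
        r2, _, _ = ror_with_ci(ContingencyTable(a + 1, b, c, d))
        assert r2 > r1
        assert prr(ContingencyTable(a + 1, b, c, d)) > prr(ContingencyTable(a, b, c, d))


class TestPrr:
    def test_worked_example(self):
        assert prr(ContingencyTable(3, 7, 30, 960)) == pytest.approx(
            float(Fraction(3, 10) / Fraction(30, 990)), rel=1e-12)

    def test_symmetric_table(self):
        assert prr(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_undefined_when_no_comparator(self):
        assert prr(ContingencyTable(3, 7, 0, 960)) is None

    def test_rare_event_agreement_with_ror(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = int(rng.integers(1, 10))
            b = int(rng.integers(500, 2000))
            c = int(rng.integers(1, 30))
            d = int(rng.integers(20000, 80000))
            t = ContingencyTable(a, b, c, d)
            ror, _, _ = ror_with_ci(t)
            assert abs(prr(t) - ror) / ror < 0.05


class TestChiSquare:
    def test_independence_gives_zero(self):
        t = ContingencyTable(10, 10, 10, 10)
        assert chi_square(t, "plain") == 0.0
        assert chi_square(t, "yates") == 0.0

    def test_worked_example(self):
        t = ContingencyTable(3, 7, 30, 960)
        assert chi_square(t, "plain") == pytest.approx(oracle_chi2_oe(3, 7, 30, 960),
                                                       rel=1e-12)
        assert chi_square(t, "plain") == pytest.approx(22.566, abs=1e-3)
        assert chi_square(t, "yates") == pytest.approx(14.905, abs=1e-3)

    def test_yates_floored_at_zero(self):
        # |ad - bc| = 1 <= n/2 for this table
        assert chi_square(ContingencyTable(2, 1, 1, 1), "yates") == 0.0

    def test_zero_margin_undefined(self):
        assert chi_square(ContingencyTable(0, 0, 5, 5), "plain") is None

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=300, derandomize=True)
    def test_plain_equals_observed_expected_form(self, a, b, c, d):
        assert chi_square(ContingencyTable(a, b, c, d), "plain") == pytest.approx(
            oracle_chi2_oe(a, b, c, d), rel=1e-9)


class TestEvaluateSignal:
    def test_worked_example_positive(self):
        r = evaluate_signal("rash", ContingencyTable(3, 7, 30, 960))
        assert r.positive
        assert all(r.criteria_trace.values())

    def test_low_count_gate_dominates(self):
        # a = 2 with an enormous odds ratio is still negative
        r = evaluate_signal("x", ContingencyTable(2, 1, 1, 10000))
        assert not r.positive and not r.criteria_trace["min_reports"]
        assert r.criteria_trace["ror_ci_lower"]

    def test_symmetric_table_fails_three_gates(self):
        r = evaluate_signal("x", ContingencyTable(10, 10, 10, 10))
        assert not r.positive
        assert r.criteria_trace["min_reports"]
        assert not r.criteria_trace["ror_ci_lower"]
        assert not r.criteria_trace["prr"]
        assert not r.criteria_trace["chi2"]

    def test_undefined_statistics_fail_their_gates(self):
        r = evaluate_signal("x", ContingencyTable(5, 0, 3, 100))
        assert not r.criteria_trace["ror_ci_lower"] and not r.positive

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, derandomize=True)
    def test_positive_is_conjunction_of_independent_gates(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        crit = SignalCriteria()
        r = evaluate_signal("x", t)
        res = ror_with_ci(t)
        expected = (a >= crit.min_reports
                    and res is not None and res[1] > crit.ror_ci_lower_gt
                    and prr(t) is not None and prr(t) >= crit.prr_min
                    and chi_square(t, "yates") >= crit.chi2_min)
        assert r.positive == expected


class TestDetectAll:
    def test_tables_match_per_pair_construction(self, power_config):
        from toxsig.simulate import generate_reports
        rs = generate_reports(power_config)
        results = detect_all_signals(rs, "DRUG_A")
        assert results, "the drug must co-occur with at least one PT"
        for r in results[:10]:
            assert r.table == build_contingency(rs, "DRUG_A", r.pt)
        counts = [r.table.a for r in results]
        assert counts == sorted(counts, reverse=True)

    def test_unknown_drug_gives_empty_list(self, toy_reports):
        assert detect_all_signals(toy_reports, "no_such_drug") == []

    def test_empty_set_gives_empty_list(self):
        assert detect_all_signals(ReportSet([]), "selumetinib") == []


class TestSocAggregation:
    @staticmethod
    def _positive(pt, a):
        # a synthetic clearly-positive table with the requested a-cell
        return evaluate_signal(pt, ContingencyTable(a, 10, 10, 10000))

    def test_report_count_sums_a_cells(self):
        meddra = MedDRADict({"rash": "skin", "alopecia": "skin"})
        out = aggregate_by_soc([self._positive("rash", 5), self._positive("alopecia", 7)],
                               meddra)
        assert out == [SOCSummary("skin", 2, 12, ("alopecia", "rash"))]

    def test_pt_count_conserved_across_socs(self):
        meddra = MedDRADict({f"pt{i}": f"soc{i % 3}" for i in range(9)})
        signals = [self._positive(f"pt{i}", 3 + i) for i in range(9)]
        out = aggregate_by_soc(signals, meddra)
        assert sum(s.pt_count for s in out) == 9

    def test_negatives_are_ignored(self):
        meddra = MedDRADict({"rash": "skin"})
        neg = evaluate_signal("rash", ContingencyTable(1, 10, 10, 10))
        assert aggregate_by_soc([neg], meddra) == []

    def test_unmapped_pt_policies(self):
        meddra = MedDRADict({"rash": "skin"})
        sig = [self._positive("rash", 5), self._positive("mystery", 4)]
        with pytest.raises(KeyError):
            aggregate_by_soc(sig, meddra)
        out = aggregate_by_soc(sig, meddra, on_missing="unmapped")
        assert {s.soc for s in out} == {"skin", "unmapped"}

    def test_empty_input(self):
        assert aggregate_by_soc([], MedDRADict({"x": "y"})) == []


class TestKeySocSelection:
    def test_strict_inequalities(self):
        at_threshold = SOCSummary("cardiac disorders", 3, 50, ())
        above = SOCSummary("eye disorders", 4, 11, ())
        assert select_key_socs([at_threshold, above]) == [above]

    def test_boundary_reports(self):
        assert select_key_socs([SOCSummary("eye disorders", 4, 10, ())]) == []

    def test_non_organ_socs_excluded(self):
        skin = SOCSummary("skin and subcutaneous tissue disorders", 13, 162, ())
        invest = SOCSummary("Investigations", 4, 77, ())
        infect = SOCSummary("infections and infestations", 4, 31, ())
        assert select_key_socs([skin, invest, infect]) == [skin]


class TestDescriptives:
    def test_half_up_rounding(self):
        # 1/800 = 0.125% -> 0.13 under half-up (0.12 under banker's rounding)
        assert percentage(1, 800) == 0.13

    def test_single_report_is_100_percent(self):
        rs = ReportSet([make_report("r1", sex="male")])
        table = descriptive_distribution(rs, "sex")
        assert table.bins == ("male",) and table.percentages == (100.0,)

    def test_counts_and_denominators(self, mixed_reports):
        table = descriptive_distribution(mixed_reports, "sex")
        assert dict(zip(table.bins, table.counts)) == {"male": 2, "female": 1}
        assert table.denominator == 3
        known = descriptive_distribution(mixed_reports, "country",
                                         denominator="known_only")
        assert known.denominator == 3  # all three countries known

    def test_year_binning_uses_received_date(self, mixed_reports):
        table = descriptive_distribution(mixed_reports, "year", bins=["2022", "2023"])
        assert table.counts == (1, 2)

    def test_age_bins_inclusive_and_known_only(self, mixed_reports):
        table = descriptive_distribution(mixed_reports, "age_bins",
                                         bins=[(0, 12), (13, 17)],
                                         denominator="known_only")
        assert table.counts == (1, 1) and table.denominator == 2

    def test_overlapping_age_bins_rejected(self, mixed_reports):
        with pytest.raises(ValueError, match="overlap"):
            descriptive_distribution(mixed_reports, "age_bins",
                                     bins=[(0, 12), (12, 17)])

    def test_sum_of_counts_bounded_by_denominator(self, mixed_reports):
        for field in ("sex", "outcome", "country", "year"):
            table = descriptive_distribution(mixed_reports, field)
            assert sum(table.counts) <= table.denominator
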