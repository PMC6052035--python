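"""ROR computation, contingency construction, and signal classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rorsignal import (
    AnalysisConfig,
    ContingencyTable,
    EventDefinition,
    ExposureDefinition,
    analyze,
    build_contingency,
    classify_signal,
    compute_ror,
    is_case,
    is_exposed,
)

from conftest import make_report

TIN = EventDefinition("tin", frozenset({"tubulointerstitial nephritis"}))
FXA = ExposureDefinition(
    "fxa inhibitors", frozenset({"edoxaban", "rivaroxaban", "apixaban"})
)
HALDANE = AnalysisConfig(zero_cell_policy="haldane")

cells = st.integers(min_value=1, max_value=100_000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


def _normalized(report):
    """Mark every mention as already normalized to its case-folded name."""
    for m in report.drugs:
        m.normalized_name = m.verbatim_name.strip().casefold()
    return report


class TestCaseAndExposure:
    def test_direct_term_membership(self):
        r = make_report(1, events=["Tubulointerstitial nephritis"])
        assert is_case(r, TIN)

    def test_empty_events_never_case(self):
        assert not is_case(make_report(1), TIN)

    def test_case_fold_and_trim_terms(self):
        r = make_report(1, events=["Nausea", "TUBULOINTERSTITIAL NEPHRITIS "])
        assert is_case(r, TIN)

    def test_exposure_any_class_member(self):
        r = _normalized(make_report(1, drugs=["edoxaban", "aspirin"]))
        assert is_exposed(r, FXA)

    def test_non_member_not_exposed(self):
        r = _normalized(make_report(1, drugs=["warfarin"]))
        assert not is_exposed(r, FXA)

    def test_two_class_drugs_count_once(self):
        r = _normalized(make_report(1, drugs=["rivaroxaban", "apixaban"]))
        t = build_contingency([r], FXA, TIN)
        assert (t.a, t.b, t.c, t.d) == (0, 1, 0, 0)


class TestBuildContingency:
    def test_toy_fixture(self, toy_reports):
        edox = ExposureDefinition("edoxaban", frozenset({"edoxaban"}))
        t = build_contingency([_normalized(r) for r in toy_reports], edox, TIN)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)
        assert t.n == 6

    def test_empty_reports(self):
        t = build_contingency([], FXA, TIN)
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)

    @given(st.data())
    def test_matches_bruteforce_enumeration(self, data):
        """Counting must agree with naive per-report set arithmetic."""
        drugs = ["edoxaban", "rivaroxaban", "warfarin", "aspirin"]
        terms = ["tin", "rash", "nausea"]
        reports = data.draw(
            st.lists(
                st.builds(
                    make_report,
                    report_id=st.integers(0, 10**6),
                    drugs=st.lists(st.sampled_from(drugs), max_size=3),
                    events=st.lists(st.sampled_from(terms), max_size=3),
                ),
                max_size=40,
            )
        )
        reports = [_normalized(r) for r in reports]
        exposure = ExposureDefinition("x", frozenset({"edoxaban", "rivaroxaban"}))
        event = EventDefinition("e", frozenset({"tin"}))
        t = build_contingency(reports, exposure, event)
        exp_sets = [{m.normalized_name for m in r.drugs} for r in reports]
        ev_sets = [set(r.events) for r in reports]
        a = sum(1 for es, vs in zip(exp_sets, ev_sets)
                if es & exposure.generics and vs & event.terms)
        b = sum(1 for es, vs in zip(exp_sets, ev_sets)
                if es & exposure.generics and not vs & event.terms)
        c = sum(1 for es, vs in zip(exp_sets, ev_sets)
                if not es & exposure.generics and vs & event.terms)
        d = len(reports) - a - b - c
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)


class TestComputeRor:
    def test_fxa_inhibitor_table(self):
        r = compute_ror(ContingencyTable(52, 132_539, 4_895, 8_144_431))
        assert round(r.ror, 2) == 0.65
        assert r.ci_upper < 1
        assert r.signal == "inverse_signal"

    def test_warfarin_table(self):
        r = compute_ror(ContingencyTable(85, 150_455, 4_862, 8_126_515))
        assert round(r.ror, 2) == 0.94
        assert round(r.ci_lower, 2) == 0.76
        assert r.ci_lower < 1 < r.ci_upper
        assert r.signal == "none"

    def test_balanced_table_is_exactly_one(self):
        r = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert r.ror == 1.0
        assert r.ci_lower < 1 < r.ci_upper

    def test_proportional_rows_are_one(self):
        assert compute_ror(ContingencyTable(1, 9, 10, 90)).ror == 1.0

    def test_zero_cell_policies(self):
        t = ContingencyTable(0, 10, 5, 85)
        undef = compute_ror(t)
        assert undef.ror is None and undef.signal == "undefined"
        hald = compute_ror(t, HALDANE)
        # +0.5 on every cell, worked through by hand
        assert hald.corrected
        assert hald.ror == pytest.approx(0.7402597402597403)
        assert hald.ci_lower == pytest.approx(0.038162203193, rel=1e-9)
        assert hald.ci_upper == pytest.approx(14.35935132660577, rel=1e-9)

    def test_negative_cell_fatal(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    def test_matches_statsmodels_log_normal_interval(self):
        """Independent cross-check of the Woolf CI."""
        sm = pytest.importorskip("statsmodels.api")
        t = ContingencyTable(52, 132_539, 4_895, 8_144_431)
        ref = sm.stats.Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        mine = compute_ror(t)
        assert mine.ror == pytest.approx(ref.oddsratio, rel=1e-12)
        lo, hi = ref.oddsratio_confint(alpha=0.05)
        assert mine.ci_lower == pytest.approx(lo, rel=1e-6)
        assert mine.ci_upper == pytest.approx(hi, rel=1e-6)

    @given(tables)
    def test_exchange_symmetry(self, t):
        """Swapping exposed/unexposed rows inverts the ROR and flips the CI."""
        r = compute_ror(t)
        s = compute_ror(ContingencyTable(t.c, t.d, t.a, t.b))
        assert s.ror == pytest.approx(1 / r.ror, rel=1e-9)
        assert s.ci_lower == pytest.approx(1 / r.ci_upper, rel=1e-9)
        assert s.ci_upper == pytest.approx(1 / r.ci_lower, rel=1e-9)

    @given(tables)
    def test_transpose_symmetry(self, t):
        """Swapping case/non-case columns also inverts the ROR."""
        r = compute_ror(t)
        s = compute_ror(ContingencyTable(t.b, t.a, t.d, t.c))
        assert s.ror == pytest.approx(1 / r.ror, rel=1e-9)

    @given(tables, st.integers(min_value=2, max_value=50))
    def test_scaling_preserves_ror_and_narrows_ci(self, t, k):
        r = compute_ror(t)
        s = compute_ror(ContingencyTable(k * t.a, k * t.b, k * t.c, k * t.d))
        assert s.ror == pytest.approx(r.ror, rel=1e-9)
        assert s.ci_upper / s.ci_lower < r.ci_upper / r.ci_lower


class TestClassifySignal:
    @pytest.mark.parametrize(
        "lo,hi,label",
        [
            (0.49, 0.85, "inverse_signal"),
            (0.76, 1.16, "none"),
            (1.20, 2.50, "signal"),
            (None, None, "undefined"),
        ],
    )
    def test_thresholds(self, lo, hi, label):
        r = compute_ror(ContingencyTable(10, 10, 10, 10))
        r = type(r)(r.exposure_name, r.event_name, r.table, r.ror, lo, hi, "")
        assert classify_signal(r) == label


class TestAnalyze:
    @pytest.fixture
    def config(self):
        return AnalysisConfig(
            exposures=[
                ExposureDefinition("edoxaban", frozenset({"edoxaban"})),
                ExposureDefinition("warfarin", frozenset({"warfarin"})),
            ],
            events=[TIN],
            zero_cell_policy="haldane",
        )

    def test_one_result_per_pair_sorted(self, toy_reports, config):
        reports = [_normalized(r) for r in toy_reports]
        results = analyze(reports, config)
        assert [(r.exposure_name, r.event_name) for r in results] == [
            ("edoxaban", "tin"),
            ("warfarin", "tin"),
        ]

    def test_shared_case_marginal(self, toy_reports, config):
        reports = [_normalized(r) for r in toy_reports]
        res = analyze(reports, config)
        assert res[0].table.a + res[0].table.c == res[1].table.a + res[1].table.c
        assert all(r.table.n == len(reports) for r in res)

    def test_equals_manual_composition(self, toy_reports, config):
        reports = [_normalized(r) for r in toy_reports]
        auto = analyze(reports, config)[0]
        table = build_contingency(reports, config.exposures[0], TIN)
        manual = compute_ror(table, config, exposure_name="edoxaban", event_name="tin")
        assert auto == manual
        assert classify_signal(manual) == auto.signal
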