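import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mortlink import (
    ContingencyTable,
    contingency,
    date_agreement,
    metrics,
    per_practice_sensitivity,
    reconstruct_contingency,
)
from mortlink.benchmark import CoverageError, Proportion


def _composite(pairs):
    return pd.DataFrame({
        "patient_id": [p for p, _ in pairs],
        "death_date": pd.to_datetime([d for _, d in pairs]),
    })


def _calls(triples):
    return pd.DataFrame({
        "patient_id": [p for p, _, _ in triples],
        "status": [s for _, s, _ in triples],
        "gold_death_date": pd.to_datetime([d for _, _, d in triples]),
    })


class TestContingency:
    def test_hand_built_six_patient_fixture(self):
        """One of each disagreement type, counts enumerated by hand."""
        comp = _composite([
            ("P1", "2015-01-01"),   # A: dead in both
            ("P2", "2015-02-01"),   # A: dead in both, date off
            ("P3", "2015-03-01"),   # B: composite only
            ("P4", None),           # C: gold only
            ("P5", None),           # D: neither
            ("P6", None),           # D: neither (likely-false in gold)
        ])
        calls = _calls([
            ("P1", "dead", "2015-01-01"),
            ("P2", "dead", "2015-02-10"),
            ("P3", "alive", None),
            ("P4", "dead", "2015-04-01"),
            ("P5", "alive", None),
            ("P6", "alive", None),
        ])
        t = contingency(comp, calls)
        assert (t.A, t.B, t.C, t.D) == (2, 1, 1, 2)
        assert t.n == 6

    def test_all_dead_in_both(self):
        comp = _composite([("P1", "2015-01-01"), ("P2", "2015-01-02")])
        calls = _calls([("P1", "dead", "2015-01-01"),
                        ("P2", "dead", "2015-01-02")])
        assert contingency(comp, calls) == ContingencyTable(2, 0, 0, 0)

    def test_empty_composite_with_k_gold_deaths(self):
        comp = _composite([("P1", None), ("P2", None), ("P3", None)])
        calls = _calls([("P1", "dead", "2015-01-01"),
                        ("P2", "alive", None), ("P3", "alive", None)])
        assert contingency(comp, calls) == ContingencyTable(0, 0, 1, 2)

    def test_mismatched_coverage_rejected(self):
        comp = _composite([("P1", None)])
        calls = _calls([("P1", "alive", None), ("P2", "alive", None)])
        with pytest.raises(CoverageError):
            contingency(comp, calls)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 1)


class TestMetrics:
    def test_symmetric_table_gives_080_everywhere(self):
        m = metrics(ContingencyTable(8, 2, 2, 8))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert m[name].point == pytest.approx(0.80)

    def test_perfect_tiny_table_truncates_ci_at_one(self):
        m = metrics(ContingencyTable(1, 0, 0, 1))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert m[name].point == 1.0
            assert m[name].upper == 1.0
            assert m[name].lower <= 1.0

    def test_wald_halfwidth_closed_form(self):
        # p = 0.5, m = 100: half-width 1.96 * sqrt(0.25/100) = 0.098
        p = Proportion.wald(50, 100)
        assert p.upper - p.point == pytest.approx(0.098, abs=2e-4)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = metrics(ContingencyTable(0, 0, 3, 5))
        assert math.isnan(m["ppv"].point)
        assert m["npv"].point == pytest.approx(5 / 8)

    def test_definitional_identities(self, calibrated_study):
        for r in calibrated_study.reports:
            t = r.table
            assert r.sensitivity.point * (t.A + t.C) == pytest.approx(t.A)
            assert r.specificity.point * (t.B + t.D) == pytest.approx(t.D)
            assert r.ppv.point * (t.A + t.B) == pytest.approx(t.A)
            assert r.npv.point * (t.C + t.D) == pytest.approx(t.D)
            for prop in (r.sensitivity, r.specificity, r.ppv, r.npv):
                assert prop.lower <= prop.point <= prop.upper


class TestDateAgreement:
    comp = _composite([(f"P{i}", f"2015-01-{i:02d}") for i in range(1, 11)]
                      + [("P11", None)])

    def test_perfect_agreement(self):
        calls = _calls([(f"P{i}", "dead", f"2015-01-{i:02d}")
                        for i in range(1, 11)] + [("P11", "alive", None)])
        assert date_agreement(self.comp, calls, 0).point == 1.0

    def test_false_positive_counts_as_disagreement(self):
        # 9 exact matches + 1 composite-only death -> 0.90
        calls = _calls([(f"P{i}", "dead", f"2015-01-{i:02d}")
                        for i in range(1, 10)]
                       + [("P10", "alive", None), ("P11", "alive", None)])
        assert date_agreement(self.comp, calls, 0).point == pytest.approx(0.9)

    @pytest.mark.parametrize("window,agrees", [(0, False), (15, True),
                                               (30, True)])
    def test_window_boundaries_inclusive(self, window, agrees):
        comp = _composite([("P1", "2015-01-14")])
        calls = _calls([("P1", "dead", "2015-01-01")])
        expected = 1.0 if agrees else 0.0
        assert date_agreement(comp, calls, window).point == expected

    def test_exactly_at_window_edge_agrees(self):
        comp = _composite([("P1", "2015-01-16")])
        calls = _calls([("P1", "dead", "2015-01-01")])
        assert date_agreement(comp, calls, 15).point == 1.0

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_agreement_nests_across_windows(self, data):
        n = data.draw(st.integers(2, 25))
        offsets = data.draw(st.lists(
            st.integers(-400, 400), min_size=n, max_size=n))
        gold_dead = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        base = pd.Timestamp("2015-06-01")
        comp = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "death_date": [base + pd.Timedelta(days=o) for o in offsets]})
        calls = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "status": ["dead" if g else "alive" for g in gold_dead],
            "gold_death_date": [base if g else pd.NaT for g in gold_dead]})
        a0 = date_agreement(comp, calls, 0).point
        a15 = date_agreement(comp, calls, 15).point
        a30 = date_agreement(comp, calls, 30).point
        assert a0 <= a15 <= a30


class TestPerPracticeSensitivity:
    @staticmethod
    def _study(practices, dead_mask, comp_dead_mask):
        n = len(practices)
        cohort = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "practice_id": practices})
        comp = pd.DataFrame({
            "patient_id": cohort["patient_id"],
            "death_date": [pd.Timestamp("2015-01-01") if c else pd.NaT
                           for c in comp_dead_mask]})
        calls = pd.DataFrame({
            "patient_id": cohort["patient_id"],
            "status": ["dead" if d else "alive" for d in dead_mask],
            "gold_death_date": [pd.Timestamp("2015-01-01") if d else pd.NaT
                                for d in dead_mask]})
        return comp, calls, cohort

    def test_single_perfect_practice(self):
        comp, calls, cohort = self._study(
            ["A"] * 120, [True] * 120, [True] * 120)
        s = per_practice_sensitivity(comp, calls, cohort, min_patients=100)
        assert s.median == 1.0
        assert s.q3 - s.q1 == 0.0

    def test_undersized_practice_excluded(self):
        comp, calls, cohort = self._study(
            ["A"] * 120 + ["B"] * 99,
            [True] * 219, [True] * 120 + [False] * 99)
        s = per_practice_sensitivity(comp, calls, cohort, min_patients=100)
        assert list(s.sensitivities.index) == ["A"]

    def test_no_qualifying_practice_warns(self):
        comp, calls, cohort = self._study(["A"] * 10, [True] * 10,
                                          [True] * 10)
        with pytest.warns(UserWarning, match="size threshold"):
            s = per_practice_sensitivity(comp, calls, cohort)
        assert s.sensitivities.empty

    def test_recovers_per_practice_capture_probabilities(self):
        rng = np.random.default_rng(5)
        practices = ["LO"] * 1000 + ["HI"] * 1000
        dead = [True] * 2000
        comp_dead = list(rng.random(1000) < 0.5) + list(
            rng.random(1000) < 0.9)
        comp, calls, cohort = self._study(practices, dead, comp_dead)
        s = per_practice_sensitivity(comp, calls, cohort)
        for pid, p in (("LO", 0.5), ("HI", 0.9)):
            se = math.sqrt(p * (1 - p) / 1000)
            assert abs(s.sensitivities[pid] - p) < 3 * se


class TestReconstruction:
    def test_round_trip_exact_metrics(self):
        t = ContingencyTable(80, 20, 20, 80)
        m = metrics(t)
        got = reconstruct_contingency(
            100 * m["specificity"].point, 100 * m["ppv"].point,
            100 * m["npv"].point, t.n)
        assert got == t

    def test_round_trip_guided_search_large_n(self):
        t = ContingencyTable(600, 25, 75, 300)
        m = metrics(t)
        got = reconstruct_contingency(
            100 * m["specificity"].point, 100 * m["ppv"].point,
            100 * m["npv"].point, t.n)
        assert got == t

    def test_all_dead_degenerate(self):
        got = reconstruct_contingency(math.nan, 100.0, math.nan, 4,
                                      sensitivity=100.0)
        assert got == ContingencyTable(4, 0, 0, 0)

    def test_infeasible_inputs_reported(self):
        with pytest.raises(ValueError, match="no contingency table"):
            reconstruct_contingency(50.0, 99.0, 1.0, 10)

    def test_out_of_range_metric_rejected(self):
        with pytest.raises(ValueError, match="specificity"):
            reconstruct_contingency(101.0, 50.0, 50.0, 100)
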