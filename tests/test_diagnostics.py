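"""Tiered tallies, metrics, Wilson intervals, cross-lab summaries."""

import pytest

from saaconcord import (ConfusionTally, InputError, ParameterError, SampleCall,
                        UsageError, abeta_map, calls_by_lab, cross_lab_summary,
                        metrics, round_half_up, stratified_sensitivity, tally,
                        tiered_reports, truth_map, wilson_interval)
from saaconcord.diagnostics import report_frame


def _call(sid, cat, lab="X"):
    n_pos = {"positive": 2, "negative": 0, "inconclusive": 1}[cat]
    return SampleCall(sid, lab, "initial", cat, n_pos, 3)


def _mini(pat, ctl):
    """Build calls+truth from category sequences for patients then controls."""
    calls, truth = {}, {}
    for i, cat in enumerate(pat):
        sid = f"p{i}"
        calls[sid], truth[sid] = _call(sid, cat), "DLB"
    for i, cat in enumerate(ctl):
        sid = f"c{i}"
        calls[sid], truth[sid] = _call(sid, cat), "control"
    return calls, truth


class TestTally:
    def test_lab_b_actual_counts(self, records, results):
        truth = truth_map(records)
        calls = calls_by_lab(results, "initial")["B"]
        t = tally(calls, truth, "actual")
        assert (t.patients_pos, t.patients_neg, t.patients_inconclusive) == (15, 3, 2)
        assert (t.controls_pos, t.controls_neg, t.controls_inconclusive) == (0, 5, 5)

    def test_lab_a_final_counts(self, records, results):
        truth = truth_map(records)
        calls = calls_by_lab(results, "final")["A"]
        t = tally(calls, truth, "final")
        assert (t.patients_pos, t.patients_neg, t.patients_inconclusive) == (20, 0, 0)
        assert (t.controls_pos, t.controls_neg, t.controls_inconclusive) == (0, 10, 0)

    def test_all_inconclusive_initial_tier_empty(self):
        calls, truth = _mini(["inconclusive"] * 3, ["inconclusive"] * 2)
        t = tally(calls, truth, "initial")
        assert t.patient_denominator == 0 and t.control_denominator == 0

    def test_missing_call_names_participant(self):
        calls, truth = _mini(["positive"], [])
        truth["ghost"] = "control"
        with pytest.raises(InputError, match="ghost"):
            tally(calls, truth, "actual")


class TestMetrics:
    def test_lab_c_actual(self, records, results):
        truth = truth_map(records)
        calls = calls_by_lab(results, "initial")["C"]
        r = metrics(tally(calls, truth, "actual"))
        assert (r.sensitivity.k, r.sensitivity.n, r.sensitivity.pct) == (11, 20, 55)
        assert (r.specificity.k, r.specificity.n, r.specificity.pct) == (6, 10, 60)
        assert (r.accuracy.k, r.accuracy.n, r.accuracy.pct) == (17, 30, 57)

    def test_lab_b_initial_sensitivity(self, records, results):
        truth = truth_map(records)
        calls = calls_by_lab(results, "initial")["B"]
        r = metrics(tally(calls, truth, "initial"))
        assert (r.sensitivity.k, r.sensitivity.n, r.sensitivity.pct) == (15, 18, 83)

    def test_zero_denominator_is_undefined_marker(self):
        t = ConfusionTally("X", "actual", 0, 0, 0, 1, 4, 0)
        r = metrics(t)
        assert r.sensitivity is None and r.npv is not None

    def test_accuracy_numerator_identity_and_tier_monotonicity(self, records, results):
        reports = tiered_reports(records, results)
        for lab, by_tier in reports.items():
            for r in by_tier.values():
                assert r.accuracy.k == r.sensitivity.k + r.specificity.k
            assert by_tier["initial"].sensitivity.n <= by_tier["actual"].sensitivity.n
            assert by_tier["final"].accuracy.k >= by_tier["actual"].accuracy.k

    def test_no_repeat_labs_final_equals_actual(self, records, results):
        reports = tiered_reports(records, results)
        for lab in ("C", "D"):
            final, actual = reports[lab]["final"], reports[lab]["actual"]
            for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
                assert getattr(final, name) == getattr(actual, name)


class TestWilson:
    @pytest.mark.parametrize("k,n,lo,hi", [
        (20, 20, 84, 100),
        (17, 20, 64, 95),
        (10, 10, 72, 100),
        (11, 15, 48, 89),
    ])
    def test_printed_percent_examples(self, k, n, lo, hi):
        low, high = wilson_interval(k, n)
        assert (round_half_up(100 * low), round_half_up(100 * high)) == (lo, hi)

    def test_boundary_clip(self):
        low, high = wilson_interval(0, 7)
        assert low == 0.0
        low, high = wilson_interval(7, 7)
        assert high == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ParameterError):
            wilson_interval(5, 4)
        with pytest.raises(ParameterError):
            wilson_interval(0, 0)


class TestStratifiedSensitivity:
    def test_published_abeta_rows(self, records, results):
        truth = truth_map(records)
        strata = abeta_map(records)
        final = calls_by_lab(results, "final")
        d = stratified_sensitivity(final["D"], truth, strata, "final")
        assert (d["negative"].k, d["negative"].n, d["negative"].pct) == (9, 10, 90)
        c = stratified_sensitivity(final["C"], truth, strata, "final")
        assert (c["positive"].k, c["positive"].n, c["positive"].pct) == (5, 10, 50)
        a = stratified_sensitivity(final["A"], truth, strata, "final")
        assert a["negative"].k == a["positive"].k == 10


class TestCrossLab:
    def _reports(self, pcts, metric="sensitivity"):
        out = []
        for lab, pct in zip("ABCD", pcts):
            calls, truth = _mini(["positive"] * round(pct / 5) +
                                 ["negative"] * (20 - round(pct / 5)), ["negative"])
            out.append(metrics(tally(calls, truth, "final", lab_label=lab)))
        return out

    def test_printed_integer_rounding_rule(self):
        reports = self._reports([100, 85, 55, 75])
        mean, lo, hi = cross_lab_summary(reports, "sensitivity")
        assert (mean, lo, hi) == (78.8, 55, 100)

    def test_identical_reports_collapse(self):
        reports = self._reports([60, 60, 60, 60])
        mean, lo, hi = cross_lab_summary(reports, "sensitivity")
        assert mean == lo == hi == 60

    def test_mixed_tiers_rejected(self, records, results):
        truth = truth_map(records)
        initial = calls_by_lab(results, "initial")
        a = metrics(tally(initial["A"], truth, "initial"))
        b = metrics(tally(initial["B"], truth, "actual"))
        with pytest.raises(UsageError):
            cross_lab_summary([a, b], "sensitivity")

    def test_needs_two_labs(self, records, results):
        truth = truth_map(records)
        calls = calls_by_lab(results, "final")["A"]
        r = metrics(tally(calls, truth, "final"))
        with pytest.raises(UsageError):
            cross_lab_summary([r], "sensitivity")


def test_round_half_up():
    assert round_half_up(78.75, 1) == 78.8
    assert round_half_up(86.5) == 87
    assert round_half_up(85.71) == 86


def test_report_frame_layout(records, results):
    reports = tiered_reports(records, results)
    frame = report_frame(reports[lab][tier] for lab in "ABCD"
                         for tier in ("initial", "actual", "final"))
    assert len(frame) == 4 * 3 * 5
    assert set(frame.columns) == {"lab", "tier", "metric", "k", "n",
                                  "estimate_pct", "ci_low_pct", "ci_high_pct"}
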