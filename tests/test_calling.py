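"""Threshold derivation, replicate and sample calls, repeat pooling."""

import itertools

import numpy as np
import pytest

from saaconcord import (ConfigurationError, InputError, KineticTrace,
                        LabRuleSet, SampleCall, ThresholdRule, UsageError,
                        call_replicate, call_sample, call_sample_counts,
                        derive_threshold, final_call, initial_call,
                        median_trace, merge_runs, repeat_call)

GRID = np.arange(0.0, 100.5, 0.5)


def flat(level, well="w"):
    return KineticTrace("s", well, "p", GRID, np.full_like(GRID, float(level)))


def sigmoid(tmid, well="w", f0=100.0, fmax=5000.0, rate=0.5):
    rfu = f0 + (fmax - f0) / (1.0 + np.exp(-rate * (GRID - tmid)))
    return KineticTrace("s", well, "p", GRID, rfu)


COUNT_RULES = LabRuleSet("X", n_replicates=3)


class TestDeriveThreshold:
    def test_zero_variance_equals_baseline(self):
        assert derive_threshold([flat(100)], ThresholdRule()) == pytest.approx(100.0)

    def test_hand_computed_sample_sd(self):
        # baseline readings {90, 100, 110}: mean 100, sample SD 10 -> 100 + 30*10
        tr = KineticTrace("s", "w", "p", np.array([0.0, 4.0, 8.0]),
                          np.array([90.0, 100.0, 110.0]))
        rule = ThresholdRule(baseline_window_h=10.0, k_sd=30.0)
        assert derive_threshold([tr], rule) == pytest.approx(400.0)

    def test_scale_equivariance(self):
        rule = ThresholdRule()
        t1 = derive_threshold([flat(90, "a"), flat(110, "b")], rule)
        t2 = derive_threshold([flat(180, "a"), flat(220, "b")], rule)
        assert t2 == pytest.approx(2 * t1)

    def test_insufficient_baseline(self):
        tr = KineticTrace("s", "w", "p", np.array([50.0, 60.0]), np.array([1.0, 1.0]))
        with pytest.raises(InputError):
            derive_threshold([tr], ThresholdRule())


class TestCallReplicate:
    def test_below_threshold(self):
        rc = call_replicate(flat(100), 400.0, COUNT_RULES)
        assert not rc.crossed and rc.time_to_threshold is None

    def test_early_crossing_flagged(self):
        rules = LabRuleSet("D", 3, aggregation="median_trace", min_valid_crossing_h=48.0)
        rc = call_replicate(sigmoid(40.0), 2500.0, rules)
        assert rc.crossed and rc.early and rc.time_to_threshold == pytest.approx(40.0)

    def test_valid_late_crossing(self):
        rules = LabRuleSet("D", 3, aggregation="median_trace", min_valid_crossing_h=48.0)
        rc = call_replicate(sigmoid(60.0), 2500.0, rules)
        assert rc.crossed and not rc.early

    def test_crossing_after_assay_cap_ignored(self):
        rules = LabRuleSet("B", 3, max_assay_h=90.0)
        rc = call_replicate(sigmoid(99.0), 2500.0, rules)
        assert not rc.crossed


@pytest.mark.parametrize("n_pos,n_total,expected", [
    (4, 4, "positive"),
    (2, 3, "positive"),
    (2, 6, "positive"),
    (1, 3, "inconclusive"),
    (1, 4, "inconclusive"),
    (0, 3, "negative"),
])
def test_count_rule(n_pos, n_total, expected):
    assert call_sample_counts(n_pos, n_total, COUNT_RULES) == expected


def test_count_rule_without_inconclusive_category():
    rules = LabRuleSet("X", 3, inconclusive_on_exactly_one=False)
    assert call_sample_counts(1, 3, rules) == "negative"


class TestMedianTrace:
    def test_identity_and_constants(self):
        tr = sigmoid(60.0)
        med = median_trace([tr, tr, tr])
        np.testing.assert_array_equal(med.rfu, tr.rfu)
        med = median_trace([flat(100, "a"), flat(200, "b"), flat(900, "c")])
        assert np.all(med.rfu == 200.0)

    def test_median_dominated_by_flats(self):
        med = median_trace([flat(100, "a"), flat(100, "b"), sigmoid(50.0, "c")])
        assert med.rfu.max() <= 100.0

    def test_rejects_even_count_and_mismatched_grids(self):
        with pytest.raises(InputError):
            median_trace([flat(1), flat(2)])
        other = KineticTrace("s", "w", "p", GRID[:-1], np.full(len(GRID) - 1, 1.0))
        with pytest.raises(InputError):
            median_trace([flat(1, "a"), flat(2, "b"), other])


class TestCallSample:
    def test_two_of_three_positive(self):
        traces = [sigmoid(60, "a"), sigmoid(62, "b"), flat(100, "c")]
        calls = [call_replicate(t, 2500.0, COUNT_RULES) for t in traces]
        sc = call_sample(calls, traces, 2500.0, COUNT_RULES)
        assert sc.category == "positive" and (sc.n_pos, sc.n_total) == (2, 3)

    def test_no_crossing_negative_in_both_modes(self):
        traces = [flat(100, w) for w in "abc"]
        for rules in (COUNT_RULES,
                      LabRuleSet("D", 3, aggregation="median_trace")):
            calls = [call_replicate(t, 400.0, rules) for t in traces]
            assert call_sample(calls, traces, 400.0, rules).category == "negative"

    def test_early_crossing_overrides_to_inconclusive(self):
        # median crosses, but one replicate crossed before the 48 h minimum
        rules = LabRuleSet("D", 3, aggregation="median_trace",
                           min_valid_crossing_h=48.0)
        traces = [sigmoid(40.0, "a"), sigmoid(60.0, "b"), flat(100, "c")]
        calls = [call_replicate(t, 2500.0, rules) for t in traces]
        sc = call_sample(calls, traces, 2500.0, rules)
        assert sc.category == "inconclusive" and sc.n_pos == 2

    def test_permutation_invariance(self):
        traces = [sigmoid(55, "a"), flat(100, "b"), sigmoid(70, "c")]
        cats = set()
        for perm in itertools.permutations(traces):
            calls = [call_replicate(t, 2500.0, COUNT_RULES) for t in perm]
            cats.add(call_sample(calls, list(perm), 2500.0, COUNT_RULES).category)
        assert len(cats) == 1

    def test_median_mode_requires_odd_replicates(self):
        rules = LabRuleSet("D", 3, aggregation="median_trace")
        traces = [flat(100, w) for w in "abcd"]
        calls = [call_replicate(t, 400.0, rules) for t in traces]
        with pytest.raises(ConfigurationError):
            call_sample(calls, traces, 400.0, rules)


class TestMergeRuns:
    @pytest.mark.parametrize("ini,rep,n_pos,n_total,category", [
        ((1, 3), (3, 3), 4, 6, "positive"),
        ((1, 4), (0, 4), 1, 8, "negative"),
        ((1, 3), (1, 3), 2, 6, "positive"),
        ((1, 3), (0, 3), 1, 6, "negative"),
    ])
    def test_pooling(self, ini, rep, n_pos, n_total, category):
        rules = LabRuleSet("A", 4)
        initial = SampleCall("s", "A", "initial", "inconclusive", *ini)
        repeat = SampleCall("s", "A", "repeat",
                            call_sample_counts(rep[0], rep[1], rules), *rep)
        final = merge_runs(initial, repeat, rules)
        assert (final.n_pos, final.n_total, final.category) == (n_pos, n_total, category)
        assert final.run_level == "final"

    def test_never_converts_a_conclusive_initial(self):
        initial = SampleCall("s", "A", "initial", "positive", 4, 4)
        final = merge_runs(initial, None, LabRuleSet("A", 4))
        assert final.category == "positive" and final.run_level == "final"
        repeat = SampleCall("s", "A", "repeat", "negative", 0, 4)
        with pytest.raises(UsageError):
            merge_runs(initial, repeat, LabRuleSet("A", 4))


def test_count_rules_reproduce_published_calls(results, rulesets):
    """Labs A-C: the replicate-count rules reproduce every printed call.

    Lab D is excluded: its published calls come from a continuous
    median-fluorescence criterion that is not a function of the counts.
    """
    for r in results:
        if r.lab == "D":
            continue
        rules = rulesets[r.lab]
        if r.was_repeated:
            merged = merge_runs(initial_call(r), repeat_call(r), rules)
            assert merged.category == r.printed_call
            assert (merged.n_pos, merged.n_total) == (r.n_pos, r.n_total)
        else:
            assert call_sample_counts(r.n_pos, r.n_total, rules) == r.printed_call
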