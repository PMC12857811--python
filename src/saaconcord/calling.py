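"""Qualitative SAA positivity calling.

Implements the decision procedures the four laboratories applied to raw ThT
kinetics: a cutoff fluorescence derived from the early-assay baseline (mean
of all readings in the first 10 h plus 30 standard deviations), well-level
threshold-crossing calls, sample-level aggregation either by counting
crossing replicates (>= 2 of N positive, exactly 1 inconclusive, 0 negative)
or by testing whether the pointwise median trace of the replicates crosses,
an early-aggregation time rule (a crossing before a minimum valid time makes
the sample inconclusive), and pooling of repeat runs for initially
inconclusive samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, ParameterError, UsageError
from .kinetics import KineticTrace, traces_from_frame

__all__ = [
    "POSITIVE", "NEGATIVE", "INCONCLUSIVE",
    "ThresholdRule", "ReplicateCall", "LabRuleSet", "SampleCall",
    "derive_threshold", "call_replicate", "call_sample_counts",
    "median_trace", "call_sample", "merge_runs",
    "reference_rulesets", "call_dataset",
]

POSITIVE = "positive"
NEGATIVE = "negative"
INCONCLUSIVE = "inconclusive"
CATEGORIES = (POSITIVE, NEGATIVE, INCONCLUSIVE)


@dataclass(frozen=True)
class ThresholdRule:
    """How the cutoff fluorescence is derived from baseline readings.

    threshold = mean(readings with time < baseline_window_h) + k_sd * SD,
    pooled over all wells in scope (per plate by default).  ``sd_kind``
    selects the sample (n-1) or population (n) standard deviation.
    """

    baseline_window_h: float = 10.0
    k_sd: float = 30.0
    scope: str = "per_plate"  # or "per_experiment"
    sd_kind: str = "sample"   # or "population"

    def __post_init__(self):
        if self.baseline_window_h <= 0 or self.k_sd <= 0:
            raise ParameterError("baseline_window_h and k_sd must be positive")
        if self.scope not in ("per_plate", "per_experiment"):
            raise ParameterError(f"unknown scope {self.scope!r}")
        if self.sd_kind not in ("sample", "population"):
            raise ParameterError(f"unknown sd_kind {self.sd_kind!r}")


@dataclass(frozen=True)
class ReplicateCall:
    """Well-level outcome against the cutoff fluorescence."""

    well_id: str
    crossed: bool
    time_to_threshold: float | None
    early: bool = False

    def __post_init__(self):
        if self.crossed != (self.time_to_threshold is not None):
            raise ParameterError("time_to_threshold present iff crossed")
        if self.early and not self.crossed:
            raise ParameterError("early implies crossed")


@dataclass(frozen=True)
class LabRuleSet:
    """A laboratory's complete sample-calling procedure."""

    lab_label: str
    n_replicates: int
    aggregation: str = "count_based"  # or "median_trace"
    min_pos_for_positive: int = 2
    inconclusive_on_exactly_one: bool = True
    min_valid_crossing_h: float | None = None
    max_assay_h: float | None = None
    repeat_policy: str = "pool_replicates"  # or "no_repeat"

    def __post_init__(self):
        if self.aggregation not in ("count_based", "median_trace"):
            raise ConfigurationError(f"unknown aggregation {self.aggregation!r}")
        if self.repeat_policy not in ("pool_replicates", "no_repeat"):
            raise ConfigurationError(f"unknown repeat_policy {self.repeat_policy!r}")
        if not 1 <= self.min_pos_for_positive <= self.n_replicates:
            raise ConfigurationError("require 1 <= min_pos_for_positive <= n_replicates")
        if self.aggregation == "median_trace" and self.n_replicates % 2 == 0:
            raise ConfigurationError("median_trace requires an odd replicate count")

    @classmethod
    def from_json(cls, path) -> "LabRuleSet":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass(frozen=True)
class SampleCall:
    """Qualitative SAA result for one sample in one laboratory run."""

    sample_id: str
    lab_label: str
    run_level: str  # initial, repeat, final
    category: str   # positive, negative, inconclusive
    n_pos: int
    n_total: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ParameterError(f"unknown category {self.category!r}")
        if self.run_level not in ("initial", "repeat", "final"):
            raise ParameterError(f"unknown run_level {self.run_level!r}")
        if not 0 <= self.n_pos <= self.n_total:
            raise ParameterError("require 0 <= n_pos <= n_total")


def reference_rulesets() -> dict[str, LabRuleSet]:
    """The four packaged laboratory rule sets, keyed by lab label."""
    out = {}
    base = resources.files("saaconcord").joinpath("data/rulesets")
    for lab in "ABCD":
        with resources.as_file(base.joinpath(f"lab_{lab}.json")) as path:
            out[lab] = LabRuleSet.from_json(path)
    return out


def derive_threshold(traces: Iterable[KineticTrace], rule: ThresholdRule) -> float:
    """Cutoff fluorescence: baseline mean + k_sd * baseline SD.

    Baseline readings are all readings with time < ``baseline_window_h``,
    pooled across the given traces (the caller groups traces according to
    the rule's scope: one plate or the whole experiment).
    """
    readings = []
    for tr in traces:
        window = tr.rfu[tr.times < rule.baseline_window_h]
        if len(window) < 2:
            raise InputError(
                f"well {tr.well_id!r} has fewer than 2 readings before "
                f"{rule.baseline_window_h} h")
        readings.append(window)
    if not readings:
        raise InputError("no traces supplied")
    pooled = np.concatenate(readings)
    ddof = 1 if rule.sd_kind == "sample" else 0
    return float(pooled.mean() + rule.k_sd * pooled.std(ddof=ddof))


def call_replicate(trace: KineticTrace, threshold: float,
                   ruleset: LabRuleSet) -> ReplicateCall:
    """Well-level call: did this replicate cross the cutoff fluorescence?

    The crossing time is the first grid time with rfu >= threshold (no
    interpolation).  Crossings after ``max_assay_h`` do not count; a crossing
    before ``min_valid_crossing_h`` is flagged ``early``.
    """
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    if len(trace.rfu) == 0:
        raise InputError("empty trace")
    times, rfu = trace.times, trace.rfu
    if ruleset.max_assay_h is not None:
        mask = times <= ruleset.max_assay_h
        times, rfu = times[mask], rfu[mask]
    idx = np.nonzero(rfu >= threshold)[0]
    if len(idx) == 0:
        return ReplicateCall(trace.well_id, crossed=False, time_to_threshold=None)
    ttt = float(times[idx[0]])
    early = (ruleset.min_valid_crossing_h is not None
             and ttt < ruleset.min_valid_crossing_h)
    return ReplicateCall(trace.well_id, crossed=True, time_to_threshold=ttt, early=early)


def call_sample_counts(n_pos: int, n_total: int, ruleset: LabRuleSet) -> str:
    """Sample category from replicate counts.

    >= ``min_pos_for_positive`` crossings -> positive; zero -> negative;
    exactly one -> inconclusive when the rule set says so, else negative.
    """
    if not 0 <= n_pos <= n_total:
        raise ParameterError("require 0 <= n_pos <= n_total")
    if n_pos >= ruleset.min_pos_for_positive:
        return POSITIVE
    if n_pos == 1 and ruleset.inconclusive_on_exactly_one:
        return INCONCLUSIVE
    return NEGATIVE


def median_trace(traces: Sequence[KineticTrace]) -> KineticTrace:
    """Pointwise median fluorescence of an odd number of replicate traces."""
    if len(traces) % 2 == 0 or len(traces) == 0:
        raise InputError("median_trace requires an odd number of traces")
    grid = traces[0].times
    for tr in traces[1:]:
        if len(tr.times) != len(grid) or not np.allclose(tr.times, grid):
            raise InputError("traces must share a common time grid")
    med = np.median(np.vstack([tr.rfu for tr in traces]), axis=0)
    first = traces[0]
    return KineticTrace(sample_id=first.sample_id, well_id=f"{first.sample_id}-median",
                        plate_id=first.plate_id, times=grid, rfu=med)


def call_sample(
    replicate_calls: Sequence[ReplicateCall],
    traces: Sequence[KineticTrace] | None,
    threshold: float,
    ruleset: LabRuleSet,
    *,
    sample_id: str | None = None,
    run_level: str = "initial",
) -> SampleCall:
    """Sample-level call from well-level calls.

    ``count_based`` mode applies the replicate-count rule; ``median_trace``
    mode computes the pointwise median trace and calls the sample positive
    iff that median crosses the cutoff (``traces`` required).  In either
    mode, any early crossing among the replicates (or of the median itself)
    overrides the category to inconclusive.  ``n_pos`` always reports the
    number of crossing replicates.
    """
    if not replicate_calls:
        raise InputError("no replicate calls supplied")
    if sample_id is None:
        sample_id = traces[0].sample_id if traces else "?"
    n_total = len(replicate_calls)
    n_pos = sum(rc.crossed for rc in replicate_calls)
    any_early = any(rc.early for rc in replicate_calls)

    if ruleset.aggregation == "median_trace":
        if traces is None:
            raise InputError("median_trace aggregation requires the traces")
        if len(traces) % 2 == 0:
            raise ConfigurationError("median_trace aggregation requires an odd replicate count")
        med_call = call_replicate(median_trace(list(traces)), threshold, ruleset)
        category = POSITIVE if med_call.crossed else NEGATIVE
        if med_call.early:
            any_early = True
    else:
        category = call_sample_counts(n_pos, n_total, ruleset)

    if any_early:
        category = INCONCLUSIVE
    return SampleCall(sample_id=str(sample_id), lab_label=ruleset.lab_label,
                      run_level=run_level, category=category,
                      n_pos=n_pos, n_total=n_total)


def merge_runs(initial: SampleCall, repeat: SampleCall | None,
               ruleset: LabRuleSet) -> SampleCall:
    """Final call after an optional repeat run on an inconclusive sample.

    Counts are pooled across the two runs and the >= ``min_pos_for_positive``
    rule applied to the pooled counts.  Because the repeat exhausts the
    repeat policy, a pooled count below the positivity minimum resolves to
    negative (a final call is always conclusive when a repeat was run).
    Without a repeat, the final call equals the initial one.
    """
    if repeat is None:
        return SampleCall(initial.sample_id, initial.lab_label, "final",
                          initial.category, initial.n_pos, initial.n_total)
    if initial.category != INCONCLUSIVE:
        raise UsageError("repeat supplied for a conclusive initial call")
    if ruleset.repeat_policy != "pool_replicates":
        raise UsageError(f"rule set for lab {ruleset.lab_label} does not repeat")
    if repeat.sample_id != initial.sample_id:
        raise UsageError("initial and repeat calls refer to different samples")
    n_pos = initial.n_pos + repeat.n_pos
    n_total = initial.n_total + repeat.n_total
    category = POSITIVE if n_pos >= ruleset.min_pos_for_positive else NEGATIVE
    return SampleCall(initial.sample_id, initial.lab_label, "final",
                      category, n_pos, n_total)


def call_dataset(
    kinetics: pd.DataFrame,
    rulesets: Mapping[str, LabRuleSet],
    threshold_rule: ThresholdRule | None = None,
) -> pd.DataFrame:
    """Initial-run sample calls for a long-format kinetics table.

    The cutoff fluorescence is derived per plate (or per lab experiment,
    depending on the threshold rule's scope) from all wells in scope, then
    each sample's replicates are called and aggregated under that
    laboratory's rule set.  Returns one row per (lab, sample) with columns
    ``sample_id, lab, run_level, category, n_pos, n_total, threshold``.
    """
    if threshold_rule is None:
        threshold_rule = ThresholdRule()
    required = {"sample_id", "lab", "plate_id", "well_id", "time_h", "rfu"}
    missing = required - set(kinetics.columns)
    if missing:
        raise InputError(f"kinetics table missing columns {sorted(missing)}")

    rows = []
    for lab, lab_frame in kinetics.groupby("lab", sort=True):
        if lab not in rulesets:
            raise InputError(f"no rule set for lab {lab!r}")
        ruleset = rulesets[lab]
        group_key = "plate_id" if threshold_rule.scope == "per_plate" else "lab"
        for _, scope_frame in lab_frame.groupby(group_key, sort=True):
            traces = traces_from_frame(scope_frame)
            threshold = derive_threshold(traces, threshold_rule)
            by_sample: dict[str, list[KineticTrace]] = {}
            for tr in traces:
                by_sample.setdefault(tr.sample_id, []).append(tr)
            for sid, sample_traces in by_sample.items():
                calls = [call_replicate(tr, threshold, ruleset) for tr in sample_traces]
                sc = call_sample(calls, sample_traces, threshold, ruleset,
                                 sample_id=sid)
                rows.append({"sample_id": sc.sample_id, "lab": lab,
                             "run_level": sc.run_level, "category": sc.category,
                             "n_pos": sc.n_pos, "n_total": sc.n_total,
                             "threshold": threshold})
    return pd.DataFrame(rows)
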