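"""Tiered diagnostic-performance metrics with Wilson score intervals.

SAA results are evaluated against the clinical reference standard (DLB =
condition-positive) at three accounting tiers:

* ``initial`` — first-run calls only, inconclusive samples excluded from the
  denominators;
* ``actual`` — first-run calls with inconclusive samples kept in the
  denominators and counted as failures (neither a correct positive nor a
  correct negative);
* ``final`` — calls after repeat runs resolved inconclusives (identical to
  ``actual`` for laboratories that could not repeat).

Sensitivity uses patients only, specificity controls only, accuracy both;
PPV/NPV use the standard definitions TP/(TP+FP) and TN/(TN+FN) over
conclusive calls (inconclusives are neither positive nor negative calls).
Every proportion is wrapped in a 95% Wilson score interval.  Metrics with a
zero denominator are reported as ``None`` (an explicit undefined marker)
rather than raising, so degenerate simulated designs don't crash summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .calling import INCONCLUSIVE, NEGATIVE, POSITIVE, SampleCall
from .errors import InputError, ParameterError, UsageError

__all__ = [
    "TIERS", "ConfusionTally", "ProportionEstimate", "PerformanceReport",
    "tally", "metrics", "wilson_interval", "stratified_sensitivity",
    "cross_lab_summary", "round_half_up", "report_frame",
]

TIERS = ("initial", "actual", "final")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 rounds away from zero), as in the tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTally:
    """Per-tier counts of calls for patients and controls."""

    lab_label: str
    tier: str
    patients_pos: int
    patients_neg: int
    patients_inconclusive: int
    controls_pos: int
    controls_neg: int
    controls_inconclusive: int

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ParameterError(f"unknown tier {self.tier!r}")

    @property
    def patient_denominator(self) -> int:
        n = self.patients_pos + self.patients_neg
        return n if self.tier == "initial" else n + self.patients_inconclusive

    @property
    def control_denominator(self) -> int:
        n = self.controls_pos + self.controls_neg
        return n if self.tier == "initial" else n + self.controls_inconclusive


@dataclass(frozen=True)
class ProportionEstimate:
    """k/n with a Wilson score confidence interval."""

    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95

    def __post_init__(self):
        if not 0 <= self.ci_low <= self.estimate + 1e-12 or self.estimate > self.ci_high + 1e-12:
            raise ParameterError("require ci_low <= estimate <= ci_high")

    @property
    def pct(self) -> float:
        """Estimate as the printed integer percentage (half-up)."""
        return round_half_up(100.0 * self.estimate)

    @property
    def ci_pct(self) -> tuple[float, float]:
        return (round_half_up(100.0 * self.ci_low), round_half_up(100.0 * self.ci_high))


@dataclass(frozen=True)
class PerformanceReport:
    """One lab x tier row: all five metrics (None where undefined)."""

    lab_label: str
    tier: str
    sensitivity: ProportionEstimate | None
    specificity: ProportionEstimate | None
    accuracy: ProportionEstimate | None
    ppv: ProportionEstimate | None
    npv: ProportionEstimate | None


def wilson_interval(k: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if n < 1 or not 0 <= k <= n:
        raise ParameterError(f"invalid counts k={k}, n={n}")
    if not 0.0 < conf_level < 1.0:
        raise ParameterError("conf_level must be in (0, 1)")
    low, high = proportion_confint(k, n, alpha=1.0 - conf_level, method="wilson")
    low = 0.0 if k == 0 else max(0.0, float(low))
    high = 1.0 if k == n else min(1.0, float(high))
    return (low, high)


def _estimate(k: int, n: int, conf_level: float = 0.95) -> ProportionEstimate | None:
    if n == 0:
        return None
    low, high = wilson_interval(k, n, conf_level)
    return ProportionEstimate(k=k, n=n, estimate=k / n, ci_low=low, ci_high=high,
                              conf_level=conf_level)


def tally(calls: Mapping[str, SampleCall] | Iterable[SampleCall],
          truth: Mapping[str, str], tier: str,
          lab_label: str | None = None) -> ConfusionTally:
    """Cross-tabulate one laboratory's calls against the clinical groups.

    ``calls`` holds one call per participant at the run level the tier reads
    (initial-run calls for the initial and actual tiers, merged calls for the
    final tier); ``truth`` maps sample id to group (``DLB`` or ``control``).
    """
    if tier not in TIERS:
        raise ParameterError(f"unknown tier {tier!r}")
    if not isinstance(calls, Mapping):
        calls = {c.sample_id: c for c in calls}
    counts = {("DLB", c): 0 for c in (POSITIVE, NEGATIVE, INCONCLUSIVE)}
    counts.update({("control", c): 0 for c in (POSITIVE, NEGATIVE, INCONCLUSIVE)})
    label = lab_label
    for sid, group in truth.items():
        if sid not in calls:
            raise InputError(f"participant {sid} has no call")
        call = calls[sid]
        if label is None:
            label = call.lab_label
        counts[(group, call.category)] += 1
    return ConfusionTally(
        lab_label=label or "?", tier=tier,
        patients_pos=counts[("DLB", POSITIVE)],
        patients_neg=counts[("DLB", NEGATIVE)],
        patients_inconclusive=counts[("DLB", INCONCLUSIVE)],
        controls_pos=counts[("control", POSITIVE)],
        controls_neg=counts[("control", NEGATIVE)],
        controls_inconclusive=counts[("control", INCONCLUSIVE)])


def metrics(t: ConfusionTally, conf_level: float = 0.95) -> PerformanceReport:
    """Sensitivity, specificity, accuracy, PPV, NPV for one tally."""
    pat_n = t.patient_denominator
    ctl_n = t.control_denominator
    return PerformanceReport(
        lab_label=t.lab_label, tier=t.tier,
        sensitivity=_estimate(t.patients_pos, pat_n, conf_level),
        specificity=_estimate(t.controls_neg, ctl_n, conf_level),
        accuracy=_estimate(t.patients_pos + t.controls_neg, pat_n + ctl_n, conf_level),
        ppv=_estimate(t.patients_pos, t.patients_pos + t.controls_pos, conf_level),
        npv=_estimate(t.controls_neg, t.controls_neg + t.patients_neg, conf_level))


def stratified_sensitivity(
    calls: Mapping[str, SampleCall] | Iterable[SampleCall],
    truth: Mapping[str, str],
    strata: Mapping[str, str],
    tier: str,
    conf_level: float = 0.95,
) -> dict[str, ProportionEstimate | None]:
    """Sensitivity per patient stratum (e.g. Abeta status), same tier rules.

    ``strata`` maps patient sample ids to stratum labels; only samples whose
    group is DLB and which appear in ``strata`` enter the computation.
    """
    if not isinstance(calls, Mapping):
        calls = {c.sample_id: c for c in calls}
    out: dict[str, ProportionEstimate | None] = {}
    for stratum in sorted(set(strata.values())):
        ids = [sid for sid, s in strata.items()
               if s == stratum and truth.get(sid) == "DLB"]
        sub_truth = {sid: "DLB" for sid in ids}
        t = tally(calls, sub_truth, tier)
        out[stratum] = _estimate(t.patients_pos, t.patient_denominator, conf_level)
    return out


def cross_lab_summary(
    reports: Sequence[PerformanceReport],
    metric: str,
    rounding: str = "printed_integer",
) -> tuple[float, float, float]:
    """(mean, min, max) of one metric across laboratories.

    With ``rounding='printed_integer'`` each laboratory's percentage is first
    rounded half-up to an integer and the mean of the rounded values is then
    rounded half-up to one decimal — the convention the summary statistics in
    the reference tables follow.  With ``rounding='none'`` raw percentages
    are averaged.
    """
    if len(reports) < 2:
        raise UsageError("cross-lab summary needs at least 2 laboratories")
    tiers = {r.tier for r in reports}
    if len(tiers) != 1:
        raise UsageError(f"mixed tiers {sorted(tiers)} in cross-lab summary")
    if rounding not in ("printed_integer", "none"):
        raise ParameterError(f"unknown rounding {rounding!r}")
    values = []
    for r in reports:
        est = getattr(r, metric)
        if est is None:
            raise UsageError(f"metric {metric!r} undefined for lab {r.lab_label}")
        pct = 100.0 * est.estimate
        values.append(round_half_up(pct) if rounding == "printed_integer" else pct)
    mean = sum(values) / len(values)
    if rounding == "printed_integer":
        mean = round_half_up(mean, 1)
    return (mean, min(values), max(values))


def report_frame(reports: Iterable[PerformanceReport]) -> pd.DataFrame:
    """Long table: one row per lab x tier x metric (export surface)."""
    rows = []
    for r in reports:
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            est = getattr(r, name)
            row = {"lab": r.lab_label, "tier": r.tier, "metric": name}
            if est is None:
                row.update({"k": None, "n": None, "estimate_pct": None,
                            "ci_low_pct": None, "ci_high_pct": None})
            else:
                lo, hi = est.ci_pct
                row.update({"k": est.k, "n": est.n, "estimate_pct": est.pct,
                            "ci_low_pct": lo, "ci_high_pct": hi})
            rows.append(row)
    return pd.DataFrame(rows)
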