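"""Report assembly: tiered per-lab metrics, cross-lab summaries, agreement.

This is the surface the command-line interface renders.  ``reproduce_paper``
recomputes the whole published evaluation from the packaged per-sample call
table: per-laboratory initial/actual/final sensitivity, specificity and
accuracy with Wilson intervals, amyloid-stratified sensitivities, cross-lab
means, and the pairwise Cohen's kappa matrix.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import cohort as co
from .agreement import KappaResult, agreement_frame, pairwise_kappa
from .diagnostics import (PerformanceReport, ProportionEstimate, cross_lab_summary,
                          metrics, report_frame, round_half_up,
                          stratified_sensitivity, tally)

__all__ = [
    "tiered_reports", "abeta_sensitivity", "cross_lab_table",
    "agreement_summary", "reproduce_paper",
]


def _calls_for_tier(calls_initial, calls_final, tier: str):
    return calls_final if tier == "final" else calls_initial


def tiered_reports(
    records=None, results=None, conf_level: float = 0.95,
) -> dict[str, dict[str, PerformanceReport]]:
    """Per-lab initial/actual/final performance from the packaged calls."""
    if records is None or results is None:
        records, results = co.load_reference_cohort()
    truth = co.truth_map(records)
    initial = co.calls_by_lab(results, "initial")
    final = co.calls_by_lab(results, "final")
    out: dict[str, dict[str, PerformanceReport]] = {}
    for lab in co.LABS:
        out[lab] = {}
        for tier in ("initial", "actual", "final"):
            calls = _calls_for_tier(initial[lab], final[lab], tier)
            out[lab][tier] = metrics(tally(calls, truth, tier, lab_label=lab),
                                     conf_level)
    return out


def abeta_sensitivity(
    records=None, results=None, conf_level: float = 0.95,
) -> dict[str, dict[str, dict[str, ProportionEstimate | None]]]:
    """Amyloid-stratified sensitivity per lab and tier: [lab][tier][stratum]."""
    if records is None or results is None:
        records, results = co.load_reference_cohort()
    truth = co.truth_map(records)
    strata = co.abeta_map(records)
    initial = co.calls_by_lab(results, "initial")
    final = co.calls_by_lab(results, "final")
    out: dict[str, dict[str, dict[str, ProportionEstimate | None]]] = {}
    for lab in co.LABS:
        out[lab] = {}
        for tier in ("initial", "actual", "final"):
            calls = _calls_for_tier(initial[lab], final[lab], tier)
            out[lab][tier] = stratified_sensitivity(calls, truth, strata, tier,
                                                    conf_level)
    return out


def cross_lab_table(reports_by_lab: Mapping[str, Mapping[str, PerformanceReport]],
                    tier: str = "final") -> dict[str, dict[str, float]]:
    """Mean/min/max of each metric across the four laboratories at one tier."""
    reports = [reports_by_lab[lab][tier] for lab in sorted(reports_by_lab)]
    out = {}
    for metric in ("sensitivity", "specificity", "accuracy"):
        mean, lo, hi = cross_lab_summary(reports, metric)
        out[metric] = {"mean": mean, "min": lo, "max": hi}
    return out


def agreement_summary(
    records=None, results=None, inconclusive_mode: str = "category",
) -> tuple[dict[tuple[str, str], KappaResult], float]:
    """Pairwise Cohen's kappa on final calls plus the average."""
    if records is None or results is None:
        records, results = co.load_reference_cohort()
    final = co.calls_by_lab(results, "final")
    categories = {lab: {sid: call.category for sid, call in calls.items()}
                  for lab, calls in final.items()}
    return pairwise_kappa(categories, inconclusive_mode=inconclusive_mode)


def _abeta_cross_lab(strat, tier: str) -> dict[str, float]:
    out = {}
    for stratum in ("negative", "positive"):
        pcts = [round_half_up(100.0 * strat[lab][tier][stratum].estimate)
                for lab in co.LABS]
        out[stratum] = round_half_up(sum(pcts) / len(pcts), 1)
    return out


def reproduce_paper(out_dir: str | Path | None = None) -> dict:
    """Recompute the full published evaluation from the packaged call table.

    Returns a bundle with per-lab tiered metrics, amyloid-stratified
    sensitivities, cross-lab summaries and the agreement matrix; when
    ``out_dir`` is given, also writes ``performance.csv``,
    ``abeta_sensitivity.csv``, ``cross_lab.json``, ``agreement.csv`` and
    ``agreement.json`` there (byte-stable across runs).
    """
    records, results = co.load_reference_cohort()
    reports = tiered_reports(records, results)
    strat = abeta_sensitivity(records, results)
    kappas, avg_kappa = agreement_summary(records, results)

    cross = {tier: cross_lab_table(reports, tier) for tier in ("initial", "actual", "final")}
    abeta_means = {tier: _abeta_cross_lab(strat, tier)
                   for tier in ("initial", "actual", "final")}

    perf = report_frame(reports[lab][tier] for lab in co.LABS
                        for tier in ("initial", "actual", "final"))

    strat_rows = []
    for lab in co.LABS:
        for tier in ("initial", "actual", "final"):
            for stratum, est in strat[lab][tier].items():
                lo, hi = est.ci_pct
                strat_rows.append({"lab": lab, "tier": tier, "abeta": stratum,
                                   "k": est.k, "n": est.n, "estimate_pct": est.pct,
                                   "ci_low_pct": lo, "ci_high_pct": hi})
    strat_frame = pd.DataFrame(strat_rows)
    agree_frame = agreement_frame(kappas)

    bundle = {
        "reports": reports,
        "performance": perf,
        "abeta_sensitivity": strat_frame,
        "cross_lab": cross,
        "abeta_cross_lab": abeta_means,
        "kappa": kappas,
        "average_kappa": avg_kappa,
        "agreement": agree_frame,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        perf.to_csv(out_dir / "performance.csv", index=False)
        strat_frame.to_csv(out_dir / "abeta_sensitivity.csv", index=False)
        agree_frame.to_csv(out_dir / "agreement.csv", index=False)
        with open(out_dir / "cross_lab.json", "w") as fh:
            json.dump({"tiers": cross, "abeta_sensitivity_means": abeta_means},
                      fh, indent=2, sort_keys=True)
        with open(out_dir / "agreement.json", "w") as fh:
            json.dump({"pairs": {f"{a}-{b}": round(r.kappa, 6)
                                 for (a, b), r in kappas.items()},
                       "average_kappa": round(avg_kappa, 6)},
                      fh, indent=2, sort_keys=True)
    return bundle
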