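"""Reference cohort and per-sample published SAA calls.

The study cohort — 20 DLB patients (10 amyloid-positive, 10 amyloid-negative)
and 10 age- and sex-matched controls — and the per-sample qualitative SAA
results of the four laboratories are packaged as validated tab-separated
data.  The published calls are authoritative: the rule engine in
:mod:`saaconcord.calling` is never used to overwrite them (Lab D's calls are
not a pure function of replicate counts, because its criterion is a
continuous median-fluorescence rule applied to raw traces that are not
published).

Initial-run calls are reconstructed from the published final counts: a
repeated sample (replicate total 6 or 8) was by construction inconclusive on
its first run with exactly one crossing replicate, so the initial run had
``n_pos = 1`` of half the final total and the repeat run supplied the rest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .calling import (INCONCLUSIVE, NEGATIVE, POSITIVE, LabRuleSet, SampleCall,
                      call_sample_counts, merge_runs, reference_rulesets)
from .errors import IntegrityError, SchemaError, ValidationError

__all__ = [
    "CohortRecord", "PrintedLabResult",
    "load_reference_cohort", "validate_cohort",
    "read_cohort_table", "write_cohort_table",
    "read_lab_results", "write_lab_results",
    "initial_call", "repeat_call", "final_call", "calls_by_lab",
    "truth_map", "abeta_map",
    "LABS",
]

LABS = ("A", "B", "C", "D")
GROUPS = ("DLB", "control")
ABETA = ("positive", "negative", "not_applicable")
NEUROPATH = ("none", "LBD", "LBD_with_AD")
FEATURE = ("present", "absent", "unknown")
DAT = ("positive", "not_applicable")
CALLS = (POSITIVE, NEGATIVE, INCONCLUSIVE)


@dataclass(frozen=True)
class CohortRecord:
    """One participant: group, amyloid status, and core clinical features."""

    participant_id: int
    group: str
    abeta_status: str
    neuropathology: str = "none"
    parkinsonism: str = "unknown"
    cognitive_fluctuations: str = "unknown"
    visual_hallucinations: str = "unknown"
    probable_RBD: str = "unknown"
    dat_scan: str = "not_applicable"

    def __post_init__(self):
        checks = [("group", GROUPS), ("abeta_status", ABETA),
                  ("neuropathology", NEUROPATH), ("dat_scan", DAT),
                  ("parkinsonism", FEATURE), ("cognitive_fluctuations", FEATURE),
                  ("visual_hallucinations", FEATURE), ("probable_RBD", FEATURE)]
        for name, allowed in checks:
            if getattr(self, name) not in allowed:
                raise ValidationError(
                    f"participant {self.participant_id}: {name}="
                    f"{getattr(self, name)!r} not in {allowed}")


@dataclass(frozen=True)
class PrintedLabResult:
    """One published per-sample SAA outcome from one laboratory.

    ``n_pos``/``n_total`` are the published replicate counts (totals of 6 or
    8 indicate a pooled repeat run); ``printed_call`` is the published final
    qualitative result; ``early_aggregation_flag`` marks samples whose
    replicate crossed before 48 h and were therefore called inconclusive.
    """

    participant_id: int
    lab: str
    n_pos: int
    n_total: int
    printed_call: str
    early_aggregation_flag: bool = False
    was_repeated: bool = False

    def __post_init__(self):
        if self.lab not in LABS:
            raise ValidationError(f"unknown lab {self.lab!r}")
        if self.printed_call not in CALLS:
            raise ValidationError(
                f"participant {self.participant_id} lab {self.lab}: "
                f"bad call {self.printed_call!r}")


_COHORT_COLUMNS = {
    "participant_id": "participant_id", "group": "group",
    "abeta_status": "abeta_status", "neuropathology": "neuropathology",
    "parkinsonism": "parkinsonism", "fluctuations": "cognitive_fluctuations",
    "vh": "visual_hallucinations", "rbd": "probable_RBD", "dat_scan": "dat_scan",
}
_RESULT_COLUMNS = ("participant_id", "lab", "n_pos", "n_total", "call",
                   "early_aggregation", "repeated")


def _parse_bool(s: str) -> bool:
    if s.lower() in ("true", "1", "yes"):
        return True
    if s.lower() in ("false", "0", "no"):
        return False
    raise SchemaError(f"cannot parse boolean {s!r}")


def read_cohort_table(path) -> list[CohortRecord]:
    """Read a tab-separated cohort table (blank clinical cells -> unknown)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in ("participant_id", "group", "abeta_status") if c not in cols]
        if missing:
            raise SchemaError(f"cohort table missing required columns {missing}")
        records, seen = [], set()
        for row in reader:
            kwargs = {}
            for col, field_name in _COHORT_COLUMNS.items():
                value = (row.get(col) or "").strip()
                if col == "participant_id":
                    kwargs[field_name] = int(value)
                elif value == "":
                    if field_name in ("group", "abeta_status"):
                        raise SchemaError(f"blank {col} for participant {row['participant_id']}")
                    kwargs[field_name] = "unknown" if field_name not in (
                        "neuropathology", "dat_scan") else (
                        "none" if field_name == "neuropathology" else "not_applicable")
                else:
                    kwargs[field_name] = value
            rec = CohortRecord(**kwargs)
            if rec.participant_id in seen:
                raise ValidationError(f"duplicate participant_id {rec.participant_id}")
            seen.add(rec.participant_id)
            records.append(rec)
    return records


def write_cohort_table(records: Iterable[CohortRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COHORT_COLUMNS)
        for rec in records:
            d = asdict(rec)
            writer.writerow([d[f] for f in _COHORT_COLUMNS.values()])


def read_lab_results(path) -> list[PrintedLabResult]:
    """Read a tab-separated lab-results table."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in _RESULT_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"lab-results table missing required columns {missing}")
        results, seen = [], set()
        for row in reader:
            res = PrintedLabResult(
                participant_id=int(row["participant_id"]), lab=row["lab"].strip(),
                n_pos=int(row["n_pos"]), n_total=int(row["n_total"]),
                printed_call=row["call"].strip(),
                early_aggregation_flag=_parse_bool(row["early_aggregation"]),
                was_repeated=_parse_bool(row["repeated"]))
            key = (res.participant_id, res.lab)
            if key in seen:
                raise ValidationError(f"duplicate result for participant {key[0]} lab {key[1]}")
            seen.add(key)
            results.append(res)
    return results


def write_lab_results(results: Iterable[PrintedLabResult], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_RESULT_COLUMNS)
        for r in results:
            writer.writerow([r.participant_id, r.lab, r.n_pos, r.n_total,
                             r.printed_call, str(r.early_aggregation_flag).lower(),
                             str(r.was_repeated).lower()])


def validate_cohort(records: Sequence[CohortRecord],
                    lab_results: Sequence[PrintedLabResult]) -> list[str]:
    """Check the reference-design invariants; returns violations (empty = valid)."""
    violations: list[str] = []
    dlb = [r for r in records if r.group == "DLB"]
    ctl = [r for r in records if r.group == "control"]
    if len(dlb) != 20:
        violations.append(f"expected 20 DLB records, found {len(dlb)}")
    if len(ctl) != 10:
        violations.append(f"expected 10 control records, found {len(ctl)}")
    n_abeta_pos = sum(r.abeta_status == "positive" for r in dlb)
    n_abeta_neg = sum(r.abeta_status == "negative" for r in dlb)
    if n_abeta_pos != 10:
        violations.append(f"expected 10 Abeta-positive DLB records, found {n_abeta_pos}")
    if n_abeta_neg != 10:
        violations.append(f"expected 10 Abeta-negative DLB records, found {n_abeta_neg}")
    by_id = {r.participant_id: r for r in records}
    if 9 in by_id and by_id[9].neuropathology != "LBD":
        violations.append("participant 9 must have neuropathology=LBD")
    if 18 in by_id and by_id[18].neuropathology != "LBD_with_AD":
        violations.append("participant 18 must have neuropathology=LBD_with_AD")
    for r in dlb:
        if r.dat_scan != "positive":
            violations.append(f"DLB participant {r.participant_id} must have dat_scan=positive")

    allowed_totals = {"A": {4, 8}, "B": {3, 6}, "C": {3}, "D": {3}}
    for res in lab_results:
        tag = f"participant {res.participant_id} lab {res.lab}"
        if res.n_pos > res.n_total:
            violations.append(f"{tag}: n_pos {res.n_pos} > n_total {res.n_total}")
        if res.n_total not in allowed_totals[res.lab]:
            violations.append(f"{tag}: replicate total {res.n_total} not allowed for lab {res.lab}")
        if res.early_aggregation_flag and res.lab != "D":
            violations.append(f"{tag}: early-aggregation flag outside lab D")
        if res.was_repeated != (res.n_total in (6, 8)):
            violations.append(f"{tag}: repeated flag inconsistent with replicate total")
        if res.participant_id not in by_id:
            violations.append(f"{tag}: no matching cohort record")
    return violations


def load_reference_cohort() -> tuple[list[CohortRecord], list[PrintedLabResult]]:
    """Load and validate the packaged cohort and per-sample published calls."""
    base = resources.files("saaconcord").joinpath("data")
    with resources.as_file(base.joinpath("cohort.tsv")) as path:
        records = read_cohort_table(path)
    with resources.as_file(base.joinpath("lab_results.tsv")) as path:
        results = read_lab_results(path)
    violations = validate_cohort(records, results)
    if violations:
        raise IntegrityError("packaged reference data corrupt: " + "; ".join(violations))
    if len(results) != 120:
        raise IntegrityError(f"expected 120 lab results, found {len(results)}")
    return records, results


# ---------------------------------------------------------------------------
# Run-level calls reconstructed from the published table


def _ruleset(lab: str) -> LabRuleSet:
    return reference_rulesets()[lab]


def initial_call(result: PrintedLabResult) -> SampleCall:
    """First-run call: inconclusive with one crossing replicate if repeated."""
    if result.was_repeated:
        return SampleCall(str(result.participant_id), result.lab, "initial",
                          INCONCLUSIVE, 1, result.n_total // 2)
    return SampleCall(str(result.participant_id), result.lab, "initial",
                      result.printed_call, result.n_pos, result.n_total)


def repeat_call(result: PrintedLabResult) -> SampleCall | None:
    """Repeat-run call (None when the sample was not repeated)."""
    if not result.was_repeated:
        return None
    n_total = result.n_total // 2
    n_pos = result.n_pos - 1
    category = call_sample_counts(n_pos, n_total, _ruleset(result.lab))
    return SampleCall(str(result.participant_id), result.lab, "repeat",
                      category, n_pos, n_total)


def final_call(result: PrintedLabResult) -> SampleCall:
    """Published final call (pooled counts for repeated samples)."""
    return SampleCall(str(result.participant_id), result.lab, "final",
                      result.printed_call, result.n_pos, result.n_total)


def calls_by_lab(results: Sequence[PrintedLabResult],
                 run_level: str = "final") -> dict[str, dict[str, SampleCall]]:
    """Calls per lab keyed by sample id, at the requested run level."""
    maker = {"initial": initial_call, "final": final_call}.get(run_level)
    if maker is None:
        raise ValidationError(f"run_level must be 'initial' or 'final', got {run_level!r}")
    out: dict[str, dict[str, SampleCall]] = {lab: {} for lab in LABS}
    for res in results:
        out[res.lab][str(res.participant_id)] = maker(res)
    return out


def truth_map(records: Iterable[CohortRecord]) -> dict[str, str]:
    """sample_id -> group, as the diagnostics module expects."""
    return {str(r.participant_id): r.group for r in records}


def abeta_map(records: Iterable[CohortRecord]) -> dict[str, str]:
    """sample_id -> abeta_status for DLB patients."""
    return {str(r.participant_id): r.abeta_status
            for r in records if r.group == "DLB"}
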