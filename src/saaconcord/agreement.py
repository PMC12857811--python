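"""Inter-laboratory agreement of qualitative SAA calls.

Agreement between pairs of laboratories is quantified with unweighted
Cohen's kappa over the categories positive / negative / inconclusive:

    kappa = (p_o - p_e) / (1 - p_e)

where ``p_o`` is the observed proportion of samples on which the two
laboratories agree and ``p_e`` the agreement expected by chance from the two
laboratories' marginal call frequencies.  Inconclusive is a first-class
third category by default; it can alternatively be dropped or recoded as
negative (``inconclusive_mode``), because published pairwise summaries do
not always state which convention was used.  Kappa values are interpreted on
the Landis-Koch scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import INCONCLUSIVE, NEGATIVE, POSITIVE
from .errors import InputError, ParameterError

__all__ = [
    "DEFAULT_CATEGORIES", "KappaResult",
    "cohens_kappa", "pairwise_kappa", "interpret_kappa", "agreement_frame",
]

DEFAULT_CATEGORIES = (POSITIVE, NEGATIVE, INCONCLUSIVE)

# Landis-Koch bands, upper ends closed.
_BANDS = [(-1.0, 0.0, "poor"), (0.0, 0.20, "slight"), (0.20, 0.40, "fair"),
          (0.40, 0.60, "moderate"), (0.60, 0.80, "substantial"),
          (0.80, 1.0, "almost_perfect")]


@dataclass(frozen=True)
class KappaResult:
    """Pairwise agreement between two laboratories."""

    lab_i: str
    lab_j: str
    n: int
    categories: tuple[str, ...]
    contingency: np.ndarray  # categories x categories counts, rows = lab_i
    p_observed: float
    p_expected: float
    kappa: float
    band: str
    degenerate: bool = False  # p_expected == 1: kappa is a sentinel


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch interpretation band for a kappa value."""
    if not -1.0 <= kappa <= 1.0:
        raise ParameterError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0.0:
        return "poor"
    for low, high, band in _BANDS[1:]:
        if kappa <= high:
            return band
    return "almost_perfect"


def _apply_mode(calls: Mapping[str, str], mode: str) -> dict[str, str]:
    if mode == "category":
        return dict(calls)
    if mode == "negative":
        return {k: (NEGATIVE if v == INCONCLUSIVE else v) for k, v in calls.items()}
    if mode == "drop":
        return {k: v for k, v in calls.items() if v != INCONCLUSIVE}
    raise ParameterError(f"unknown inconclusive_mode {mode!r}")


def cohens_kappa(
    calls_i: Mapping[str, str],
    calls_j: Mapping[str, str],
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    *,
    lab_i: str = "i",
    lab_j: str = "j",
    inconclusive_mode: str = "category",
) -> KappaResult:
    """Unweighted Cohen's kappa between two laboratories' call sets.

    ``calls_*`` map sample id to category.  Under ``inconclusive_mode='drop'``
    samples inconclusive in either laboratory are removed before
    cross-tabulation; under ``'negative'`` inconclusives are recoded.

    When chance agreement is 1 (both raters constant on the same category),
    kappa is undefined; a sentinel is reported (1 when observed agreement is
    also 1, else 0) with ``degenerate=True``.
    """
    calls_i = _apply_mode(calls_i, inconclusive_mode)
    calls_j = _apply_mode(calls_j, inconclusive_mode)
    if inconclusive_mode == "drop":
        common = sorted(set(calls_i) & set(calls_j))
        calls_i = {k: calls_i[k] for k in common}
        calls_j = {k: calls_j[k] for k in common}
        categories = tuple(c for c in categories if c != INCONCLUSIVE)
    if set(calls_i) != set(calls_j):
        raise InputError("the two call sets cover different participants")
    cats = tuple(categories)
    index = {c: k for k, c in enumerate(cats)}
    n = len(calls_i)
    if n == 0:
        raise InputError("no samples to compare")
    table = np.zeros((len(cats), len(cats)), dtype=int)
    for sid in calls_i:
        ci, cj = calls_i[sid], calls_j[sid]
        if ci not in index or cj not in index:
            raise InputError(f"call outside category set for sample {sid}")
        table[index[ci], index[cj]] += 1

    p_o = float(np.trace(table)) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float(np.dot(row, col))
    degenerate = bool(abs(1.0 - p_e) < 1e-12)
    if degenerate:
        kappa = 1.0 if abs(1.0 - p_o) < 1e-12 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(lab_i=lab_i, lab_j=lab_j, n=n, categories=cats,
                       contingency=table, p_observed=p_o, p_expected=p_e,
                       kappa=float(kappa), band=interpret_kappa(float(kappa)),
                       degenerate=degenerate)


def pairwise_kappa(
    calls_by_lab: Mapping[str, Mapping[str, str]],
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    inconclusive_mode: str = "category",
) -> tuple[dict[tuple[str, str], KappaResult], float]:
    """All unordered laboratory pairs plus the unweighted mean kappa."""
    labs = sorted(calls_by_lab)
    if len(labs) < 2:
        raise InputError("pairwise agreement needs at least 2 laboratories")
    results: dict[tuple[str, str], KappaResult] = {}
    for a, b in itertools.combinations(labs, 2):
        results[(a, b)] = cohens_kappa(calls_by_lab[a], calls_by_lab[b],
                                       categories, lab_i=a, lab_j=b,
                                       inconclusive_mode=inconclusive_mode)
    average = float(np.mean([r.kappa for r in results.values()]))
    return results, average


def agreement_frame(results: Mapping[tuple[str, str], KappaResult]) -> pd.DataFrame:
    """Flat export: one row per laboratory pair."""
    rows = [{"lab_i": r.lab_i, "lab_j": r.lab_j, "n": r.n,
             "p_observed": r.p_observed, "p_expected": r.p_expected,
             "kappa": r.kappa, "band": r.band}
            for r in results.values()]
    return pd.DataFrame(rows)
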