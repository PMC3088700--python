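"""Method-comparison harness.

Treats the most sensitive method (massively parallel sequencing) as
the reference truth set and scores the other methods against it:
per-method sensitivity, misdiagnosis counts, responder detection,
in-cohort minimum detected allele fraction, and the correlation of
histopathological tumor-content estimates with measured mutant-allele
fractions.  `predicted_call_matrix` reproduces the observed per-method
call columns from allele fractions alone via each method's detection
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .cohort import Cohort, mutated_specimens, responders
from .poisson import ErrorModel, detection_limit
from .sanger import SangerLoD

__all__ = [
    "Sensitivity",
    "Correlation",
    "sensitivity",
    "misdiagnosis_count",
    "responder_detection",
    "min_detected_fraction",
    "purity_frequency_correlation",
    "predicted_call_matrix",
    "benchmark_report",
    "round_half_up_percent",
]

DEFAULT_COVERAGE = 1079  # cohort-average amplicon coverage


def round_half_up_percent(detected: int, total: int) -> int:
    """Integer percentage with exact half-up rounding (12/18 -> 67)."""
    return int(math.floor(100 * detected / total + 0.5))


@dataclass(frozen=True)
class Sensitivity:
    detected: int
    total: int
    percent: int | None  # None when the truth set is empty


def sensitivity(
    cohort: Cohort, method: str, reference: str = "parallel"
) -> Sensitivity:
    """Fraction of reference-MUT rows also called MUT by ``method``."""
    truth = mutated_specimens(cohort, reference)
    detected = sum(1 for rec in truth if rec.call(method) == "MUT")
    if not truth:
        return Sensitivity(0, 0, None)
    return Sensitivity(detected, len(truth), round_half_up_percent(detected, len(truth)))


def misdiagnosis_count(
    cohort: Cohort, method: str, reference: str = "parallel"
) -> int:
    """Rows where ``method`` disagrees with the reference call."""
    return sum(1 for rec in cohort if rec.call(method) != rec.call(reference))


def responder_detection(cohort: Cohort, method: str) -> tuple[int, int]:
    """(detected, total) partial-response patients whose PR specimen carries a
    sensitizing mutation called MUT by ``method``.

    Resistance-only rows (e.g. T790M) never qualify as detection of the
    sensitizing lesion.
    """
    pr = responders(cohort)
    detected = sum(
        1
        for rec in pr.values()
        if rec.sensitizing and rec.call(method) == "MUT"
    )
    return detected, len(pr)


def min_detected_fraction(cohort: Cohort, method: str) -> float | None:
    """Smallest allele percentage among rows called MUT by ``method``."""
    fractions = [
        rec.allele_pct
        for rec in mutated_specimens(cohort, method)
        if rec.allele_pct is not None
    ]
    return min(fractions) if fractions else None


@dataclass(frozen=True)
class Correlation:
    r: float
    r_squared: float
    n_pairs: int
    p_value: float


def purity_frequency_correlation(cohort: Cohort) -> Correlation:
    """Pearson correlation of tumor-content estimate vs mutant-allele %.

    Computed over mutation-positive rows (reference = parallel) with
    both values present; p-value from the t-distribution with n-2 df.
    """
    pairs = [
        (rec.tumor_content_pct, rec.allele_pct)
        for rec in mutated_specimens(cohort, "parallel")
        if rec.tumor_content_pct is not None and rec.allele_pct is not None
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(pairs)}")
    purity, fraction = zip(*pairs)
    if len(set(purity)) == 1 or len(set(fraction)) == 1:
        raise ValueError("zero variance in tumor content or allele fraction")
    r, p = stats.pearsonr(purity, fraction)
    return Correlation(float(r), float(r) ** 2, len(pairs), float(p))


def predicted_call_matrix(
    cohort: Cohort,
    sanger_lod: SangerLoD = SangerLoD(threshold=0.29),
    pyro_lod: float = 0.11,
    parallel_model: ErrorModel = ErrorModel(),
    coverage_per_row: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Predict each method's call from the allele fraction alone.

    Dideoxy and pyrosequencing use hard fraction thresholds; parallel
    sequencing calls MUT when the fraction reaches its Poisson detection
    limit at the row's coverage (default: the cohort-average 1079x).
    Rows without an allele fraction are treated as mutant-free (f = 0).
    """
    rows = []
    for rec in cohort:
        f = (rec.allele_pct or 0.0) / 100.0
        coverage = (coverage_per_row or {}).get(rec.row_key, DEFAULT_COVERAGE)
        limit = detection_limit(coverage, parallel_model)
        rows.append(
            {
                "case_id": rec.case_id,
                "specimen_label": rec.specimen_label or "none",
                "allele_pct": rec.allele_pct,
                "pred_dideoxy": "MUT" if f >= sanger_lod.threshold else "WT",
                "pred_pyro": "MUT" if f >= pyro_lod else "WT",
                "pred_parallel": "MUT" if f >= limit else "WT",
                "obs_dideoxy": rec.call_dideoxy,
                "obs_pyro": rec.call_pyro,
                "obs_parallel": rec.call_parallel,
            }
        )
    columns = [
        "case_id", "specimen_label", "allele_pct",
        "pred_dideoxy", "pred_pyro", "pred_parallel",
        "obs_dideoxy", "obs_pyro", "obs_parallel",
    ]
    return pd.DataFrame(rows, columns=columns)


def benchmark_report(cohort: Cohort, reference: str = "parallel") -> dict:
    """Full method-comparison report as a stable-keyed, JSON-ready dict."""
    methods = ("dideoxy", "pyro", "parallel")
    total = len(mutated_specimens(cohort, reference))
    per_method = {}
    for method in methods:
        sens = sensitivity(cohort, method, reference)
        det_pr, total_pr = responder_detection(cohort, method)
        per_method[method] = {
            "detected": sens.detected,
            "sensitivity_pct": sens.percent,
            "min_detected_allele_pct": min_detected_fraction(cohort, method),
            "misdiagnoses": misdiagnosis_count(cohort, method, reference),
            "responders_detected": det_pr,
        }
    corr = purity_frequency_correlation(cohort)
    _, total_pr = responder_detection(cohort, reference)
    return {
        "n_rows": cohort.n_rows,
        "n_specimens": cohort.n_specimens,
        "n_patients": cohort.n_patients,
        "total_mutations": total,
        "reference": reference,
        "methods": per_method,
        "responders_total": total_pr,
        "correlation": {
            "r": corr.r,
            "r_squared": corr.r_squared,
            "n_pairs": corr.n_pairs,
            "p_value": corr.p_value,
        },
    }
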