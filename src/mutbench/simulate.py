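"""Synthetic tumor-specimen generator.

Emulates the statistical structure of the benchmark cohort so every
pipeline stage is testable without clinical data.  A specimen is a
mixture of tumor cells (purity p) carrying m mutant copies out of C_t
locus copies and diploid normal bystander cells, giving a true
mutant-allele fraction

    f = p * m / (p * C_t + 2 * (1 - p)).

Histopathology is emulated as a noisy purity estimate rounded to the
5% steps a pathologist reports; deep sequencing as binomial read
sampling at 600-1500x coverage with a 0.1% error rate pushing reads
toward the mutant allele; and each specimen gets MUT/WT calls from the
three method models (fraction thresholds for dideoxy and
pyrosequencing, the Poisson caller for parallel sequencing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, SpecimenRecord
from .poisson import ErrorModel, PileupCounts, call_variant
from .sanger import SangerLoD, call_dideoxy

__all__ = [
    "TumorModel",
    "SimSpecimen",
    "expected_allele_fraction",
    "simulate_specimen",
    "simulate_cohort",
]

DEFAULT_PURITY_RANGE = (0.05, 0.95)
DEFAULT_COVERAGE_RANGE = (600, 1500)
DEFAULT_PURITY_NOISE_SD = 0.15
DEFAULT_PYRO_LOD = 0.11


@dataclass(frozen=True)
class TumorModel:
    """Purity/copy-number/multiplicity description of one tumor specimen."""

    purity: float
    tumor_copy_number: int = 2
    multiplicity: int = 1
    normal_copy_number: int = 2  # diploid bystander cells

    def __post_init__(self) -> None:
        if not 0 <= self.purity <= 1:
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")
        if self.tumor_copy_number < 1:
            raise ValueError("tumor copy number must be >= 1")
        if not 1 <= self.multiplicity <= self.tumor_copy_number:
            raise ValueError(
                "multiplicity must be in [1, tumor_copy_number], got "
                f"{self.multiplicity}/{self.tumor_copy_number}"
            )


def expected_allele_fraction(model: TumorModel) -> float:
    """True mutant-allele fraction implied by purity, copies and multiplicity."""
    p = model.purity
    numerator = p * model.multiplicity
    denominator = p * model.tumor_copy_number + model.normal_copy_number * (1 - p)
    return numerator / denominator if denominator > 0 else 0.0


def _round_to_step(value: float, step: float = 5.0) -> float:
    return step * round(value / step)


@dataclass(frozen=True)
class SimSpecimen:
    model: TumorModel
    f_true: float
    purity_estimate_pct: float  # histopathology surrogate, 5% steps
    pileup: PileupCounts
    seed: int


def simulate_specimen(
    model: TumorModel,
    coverage: int,
    error_model: ErrorModel = ErrorModel(),
    purity_noise_sd: float = DEFAULT_PURITY_NOISE_SD,
    seed: int = 0,
    specimen_id: str = "sim",
    locus_label: str = "synthetic_locus",
) -> SimSpecimen:
    """Draw one synthetic specimen: noisy purity estimate plus a binomial pileup.

    Error reads add toward the mutant allele (worst case), so the
    per-read success probability is f + (1-f)*e.
    """
    if coverage < 1:
        raise ValueError(f"coverage must be >= 1, got {coverage}")
    rng = np.random.default_rng(seed)
    f = expected_allele_fraction(model)
    p_read = f + (1 - f) * error_model.e
    k = int(rng.binomial(coverage, p_read))
    noisy = model.purity + rng.normal(0.0, purity_noise_sd) if purity_noise_sd else model.purity
    estimate = _round_to_step(100.0 * min(1.0, max(0.0, noisy)))
    return SimSpecimen(
        model=model,
        f_true=f,
        purity_estimate_pct=estimate,
        pileup=PileupCounts(specimen_id, locus_label, coverage, k),
        seed=seed,
    )


def simulate_cohort(
    n: int,
    purity_range: tuple[float, float] = DEFAULT_PURITY_RANGE,
    copy_number_distribution: Sequence[int] = (2,),
    multiplicity_distribution: Sequence[int] = (1,),
    purity_noise_sd: float = DEFAULT_PURITY_NOISE_SD,
    coverage_range: tuple[int, int] = DEFAULT_COVERAGE_RANGE,
    seed: int = 0,
    error_model: ErrorModel = ErrorModel(),
    sanger_lod: SangerLoD = SangerLoD(),
    pyro_lod: float = DEFAULT_PYRO_LOD,
) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort of mutant tumor specimens with per-method calls.

    Purity is uniform over ``purity_range``; locus copy number and
    mutation multiplicity are drawn uniformly from the given supports
    (pairs violating m <= C_t are redrawn by clipping m); coverage is
    uniform over ``coverage_range``.  Dideoxy and pyrosequencing calls
    threshold the true template fraction; the parallel call runs the
    Poisson caller on the binomial pileup.  Returns the cohort table
    plus a per-specimen frame pairing true and estimated quantities.
    All randomness flows from ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not copy_number_distribution or not multiplicity_distribution:
        raise ValueError("copy number and multiplicity supports must be nonempty")
    lo, hi = purity_range
    if not 0 <= lo <= hi <= 1:
        raise ValueError(f"invalid purity range {purity_range}")
    cov_lo, cov_hi = coverage_range
    if not 1 <= cov_lo <= cov_hi:
        raise ValueError(f"invalid coverage range {coverage_range}")

    rng = np.random.default_rng(seed)
    records: list[SpecimenRecord] = []
    rows = []
    for i in range(n):
        purity = float(rng.uniform(lo, hi))
        c_t = int(rng.choice(np.asarray(copy_number_distribution)))
        m = min(int(rng.choice(np.asarray(multiplicity_distribution))), c_t)
        model = TumorModel(purity, c_t, m)
        spec_seed = int(rng.integers(0, 2**31 - 1))
        coverage = int(rng.integers(cov_lo, cov_hi + 1))
        case_id = f"S{i:04d}"
        spec = simulate_specimen(
            model,
            coverage,
            error_model=error_model,
            purity_noise_sd=purity_noise_sd,
            seed=spec_seed,
            specimen_id=case_id,
        )
        dideoxy = call_dideoxy(spec.f_true, sanger_lod)
        pyro = "MUT" if spec.f_true >= pyro_lod else "WT"
        parallel_call = call_variant(spec.pileup, error_model)
        parallel = parallel_call.status
        mutated = parallel == "MUT"
        records.append(
            SpecimenRecord(
                case_id=case_id,
                specimen_label=None,
                histotype="AD",
                sex="F" if i % 2 else "M",
                age=60,
                tissue_type="FF",
                specimen_type="synthetic specimen",
                tumor_content_pct=spec.purity_estimate_pct,
                allele_pct=round(100.0 * parallel_call.fraction_hat, 1) if mutated else None,
                tki_response=None,
                call_dideoxy=dideoxy,
                call_pyro=pyro,
                call_parallel=parallel,
                gene="EGFR" if mutated else "none",
                mutation_label="EGFR exon 19 del (synthetic)" if mutated else "no mutation",
                sensitizing=mutated,
            )
        )
        rows.append(
            {
                "case_id": case_id,
                "purity": purity,
                "purity_estimate_pct": spec.purity_estimate_pct,
                "copy_number": c_t,
                "multiplicity": m,
                "f_true": spec.f_true,
                "coverage": coverage,
                "mutant_count": spec.pileup.mutant_count,
                "fraction_hat": parallel_call.fraction_hat,
                "call_dideoxy": dideoxy,
                "call_pyro": pyro,
                "call_parallel": parallel,
                "seed": spec_seed,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "case_id", "purity", "purity_estimate_pct", "copy_number",
            "multiplicity", "f_true", "coverage", "mutant_count",
            "fraction_hat", "call_dideoxy", "call_pyro", "call_parallel", "seed",
        ],
    )
    cohort = Cohort(records, provenance=f"synthetic cohort (n={n}, seed={seed})")
    return cohort, truth
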