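"""Poisson error-model mutation calling for deep amplicon sequencing.

Under the null hypothesis that a locus is wild type, the number of
reads supporting the queried mutant allele at coverage N is modelled as
Poisson with mean N·e, where e is the per-read per-site miscall rate
toward that allele (default 0.1%, elevated at homopolymer-flagged
sites).  A mutation is called when the observed mutant-read count k
reaches the smallest count whose upper Poisson tail P(X ≥ k) falls at
or below the significance level α, so the coverage-dependent detection
limit is k_min/N.  At the 600–1500× coverage typical of amplicon deep
sequencing this limit sits between ~0.3% and 0.5% mutant alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ErrorModel",
    "PileupCounts",
    "VariantCall",
    "GroupComparison",
    "min_significant_count",
    "detection_limit",
    "call_variant",
    "compare_low_freq_groups",
    "read_pileups",
    "write_vcf",
]


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing error model: e at ordinary sites, e_homopolymer at flagged ones."""

    e: float = 0.001
    e_homopolymer: float = 0.01
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.e <= self.e_homopolymer < 1:
            raise ValueError(
                "require 0 <= e <= e_homopolymer < 1, got "
                f"e={self.e}, e_homopolymer={self.e_homopolymer}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def rate(self, homopolymer: bool = False) -> float:
        return self.e_homopolymer if homopolymer else self.e


@dataclass(frozen=True)
class PileupCounts:
    """Read counts at one locus: coverage N and mutant-supporting count k."""

    specimen_id: str
    locus_label: str
    coverage: int
    mutant_count: int
    homopolymer: bool = False

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise ValueError(f"coverage must be >= 1, got {self.coverage}")
        if not 0 <= self.mutant_count <= self.coverage:
            raise ValueError(
                f"mutant_count must be in [0, coverage], got "
                f"{self.mutant_count}/{self.coverage}"
            )


@dataclass(frozen=True)
class VariantCall:
    status: str  # MUT or WT
    fraction_hat: float
    k_min: int
    detection_limit: float
    tail_probability: float


def min_significant_count(
    N: int, model: ErrorModel = ErrorModel(), homopolymer: bool = False
) -> int:
    """Smallest k ≥ 1 with upper Poisson tail P(X ≥ k) ≤ α at mean N·e.

    The tail is the exact survival function, not a normal approximation.
    """
    if N < 1:
        raise ValueError(f"coverage must be >= 1, got {N}")
    mu = N * model.rate(homopolymer)
    k = 1
    # sf(k-1) = P(X >= k); mu <= 1500*0.01 keeps this loop short.
    while stats.poisson.sf(k - 1, mu) > model.alpha:
        k += 1
    return k


def detection_limit(
    N: int, model: ErrorModel = ErrorModel(), homopolymer: bool = False
) -> float:
    """Coverage-dependent detection limit k_min/N as a mutant-allele fraction."""
    return min_significant_count(N, model, homopolymer) / N


def call_variant(p: PileupCounts, model: ErrorModel = ErrorModel()) -> VariantCall:
    """Call one pileup: MUT iff k ≥ k_min; allele fraction is k/N regardless."""
    k_min = min_significant_count(p.coverage, model, p.homopolymer)
    mu = p.coverage * model.rate(p.homopolymer)
    tail = float(stats.poisson.sf(p.mutant_count - 1, mu))
    return VariantCall(
        status="MUT" if p.mutant_count >= k_min else "WT",
        fraction_hat=p.mutant_count / p.coverage,
        k_min=k_min,
        detection_limit=k_min / p.coverage,
        tail_probability=tail,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-group screen of per-sample mutant-read frequencies (per 1000 reads)."""

    mean_a: float
    mean_b: float
    t_statistic: float | None
    p_value: float | None


def compare_low_freq_groups(
    freqs_a: Sequence[float],
    freqs_b: Sequence[float],
    welch: bool = False,
) -> GroupComparison:
    """Student's t-test on per-sample mutant-read frequencies.

    Used to screen for low-frequency resistance alleles (e.g. T790M in
    pre-treatment specimens) between two patient groups.  Means are
    reported on a per-1000-reads scale; the default is the
    pooled-variance Student form, ``welch=True`` drops the equal-variance
    assumption.  With fewer than two values in either group the means
    are still returned and the test is flagged unavailable (None).
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value for a mean")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.size < 2 or b.size < 2:
        return GroupComparison(mean_a, mean_b, None, None)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(mean_a, mean_b, float(t), float(p))


def read_pileups(path: str | Path) -> list[PileupCounts]:
    """Read a pileup TSV: specimen_id, locus_label, coverage, mutant_count, homopolymer."""
    pileups = []
    with Path(path).open(encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["specimen_id", "locus_label", "coverage", "mutant_count", "homopolymer"]
        if header != expected:
            raise ValueError(f"{path}: pileup header must be {expected}")
        for line in handle:
            if not line.strip():
                continue
            sid, locus, cov, k, homo = line.rstrip("\n").split("\t")
            pileups.append(
                PileupCounts(sid, locus, int(cov), int(k), homo.strip() == "1")
            )
    return pileups


def write_vcf(
    pileups: Sequence[PileupCounts],
    calls: Sequence[VariantCall],
    path: str | Path,
    locus_map: dict[str, tuple[str, int, str, str]] | None = None,
    model: ErrorModel = ErrorModel(),
) -> int:
    """Write MUT calls as a minimal VCF v4.2; returns the number of records.

    ``locus_map`` maps locus_label -> (CHROM, POS, REF, ALT); unmapped
    loci get placeholder coordinates.  INFO carries DP (coverage) and
    AF (observed mutant-allele fraction).
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=mutbench Poisson error-model caller "
        f"(e={model.e},e_homopolymer={model.e_homopolymer},alpha={model.alpha})",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Amplicon coverage">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Mutant allele fraction k/N">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    n = 0
    for p, call in zip(pileups, calls, strict=True):
        if call.status != "MUT":
            continue
        chrom, pos, ref, alt = (locus_map or {}).get(
            p.locus_label, (".", 0, "N", "N")
        )
        lines.append(
            f"{chrom}\t{pos}\t{p.specimen_id}:{p.locus_label}\t{ref}\t{alt}\t.\tPASS\t"
            f"DP={p.coverage};AF={call.fraction_hat:.4f}"
        )
        n += 1
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return n
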