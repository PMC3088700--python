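"""Dideoxy ("Sanger") sequencing detection surrogate.

Chain-termination sequencing reads a mixed template population as a
superimposed electropherogram and loses minor alleles in baseline
noise below roughly 20-30% mutant fraction.  Rather than modelling
peak heights, detection is summarized by an allele-fraction limit of
detection: a hard threshold (default 29%, the smallest mutant fraction
detected in the benchmark cohort) or a seeded logistic soft threshold.
Fragment-length analysis of in-frame deletions (e.g. EGFR exon 19) is
a deterministic length comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SangerLoD", "call_dideoxy", "detection_probability", "fragment_length"]


@dataclass(frozen=True)
class SangerLoD:
    """Allele-fraction limit of detection for dideoxy sequencing."""

    threshold: float = 0.29
    mode: str = "hard"  # 'hard' or 'logistic'
    logistic_width: float = 0.03

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.mode not in {"hard", "logistic"}:
            raise ValueError(f"mode must be 'hard' or 'logistic', got {self.mode!r}")
        if self.logistic_width <= 0:
            raise ValueError("logistic_width must be positive")


def detection_probability(f: float, lod: SangerLoD) -> float:
    """Probability that a mutant fraction f is detected under the model."""
    if not 0 <= f <= 1:
        raise ValueError(f"mutant fraction must be in [0, 1], got {f}")
    if lod.mode == "hard":
        return 1.0 if f >= lod.threshold else 0.0
    return float(1.0 / (1.0 + np.exp(-(f - lod.threshold) / lod.logistic_width)))


def call_dideoxy(
    f: float, lod: SangerLoD = SangerLoD(), seed: int | None = None
) -> str:
    """MUT/WT call at true mutant fraction f.

    Hard mode is deterministic (boundary inclusive: f = threshold is
    MUT); logistic mode draws a seeded Bernoulli with detection
    probability 1/(1+exp(-(f-threshold)/width)).
    """
    prob = detection_probability(f, lod)
    if lod.mode == "hard":
        return "MUT" if prob == 1.0 else "WT"
    rng = np.random.default_rng(seed)
    return "MUT" if rng.random() < prob else "WT"


def fragment_length(wt_amplicon_bp: int, deletion_bp: int) -> tuple[int, bool]:
    """Mutant amplicon length after an in-frame deletion, and detectability.

    Detection requires at least 1 bp of length difference at the
    capillary's resolution.
    """
    if wt_amplicon_bp < 0 or deletion_bp < 0:
        raise ValueError("amplicon and deletion lengths must be nonnegative")
    if deletion_bp >= wt_amplicon_bp:
        raise ValueError("deletion must be shorter than the wild-type amplicon")
    mutant = wt_amplicon_bp - deletion_bp
    return mutant, abs(wt_amplicon_bp - mutant) >= 1
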