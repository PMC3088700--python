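"""Pyrosequencing assay model.

Pyrosequencing-by-synthesis dispenses nucleotides in a fixed cyclic
order; each dispensation produces a light signal proportional to the
number of template bases incorporated (0 for a mismatch, h for a
homopolymer run of length h).  The vector of signals over dispensation
events is the flowgram (pyrogram).  A specimen containing a fraction f
of mutant templates produces, after normalization against known
wild-type signals, the elementwise mixture (1−f)·wt + f·mut, so mutant
and wild-type alleles contribute non-interfering signals and f can be
estimated by least squares on the dispensations where the two expected
flowgrams differ.

Mutation calling follows the assay's statistical treatment of
experimental noise: absolute residuals from the expected wild-type
flowgram at mutation-informative dispensations are compared against
those at wild-type-only dispensations with a one-sided two-sample
t-test at p ≤ 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "Flowgram",
    "PyroAssay",
    "PyroCall",
    "DilutionSeries",
    "expected_flowgram",
    "cyclic_dispensation",
    "mixture_flowgram",
    "normalize_flowgram",
    "estimate_fraction",
    "call_pyro",
    "dilution_lod",
    "load_assay",
    "read_pyrogram",
    "write_pyrogram",
]

_BASES = set("ACGT")
_RESIDUAL_EPS = 1e-9


def expected_flowgram(template: str, dispensation_events: str) -> np.ndarray:
    """Noise-free flowgram of a pure template under explicit dispensations.

    A cursor walks the template; each dispensed base yields a signal
    equal to the maximal run of that base at the cursor and advances the
    cursor past the run.
    """
    template = template.upper()
    events = dispensation_events.upper()
    bad = (set(template) | set(events)) - _BASES
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    if not events:
        raise ValueError("at least one dispensation event is required")
    signal = np.zeros(len(events), dtype=int)
    cursor = 0
    for i, base in enumerate(events):
        run = 0
        while cursor + run < len(template) and template[cursor + run] == base:
            run += 1
        signal[i] = run
        cursor += run
    return signal


def cyclic_dispensation(order: str, n_events: int) -> str:
    """Expand a cyclic dispensation order (e.g. 'ACGT') to n_events events."""
    if not order:
        raise ValueError("dispensation order must be nonempty")
    reps = -(-n_events // len(order))
    return (order * reps)[:n_events]


@dataclass(frozen=True)
class Flowgram:
    """Dispensation events plus one nonnegative signal per event."""

    dispensation: str
    signal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if len(self.dispensation) != self.signal.size:
            raise ValueError("signal length must equal number of dispensations")


@dataclass(frozen=True)
class PyroAssay:
    """One pyrosequencing assay: wild-type and mutant templates, dispensations.

    ``informative_set`` holds dispensation indices where the expected
    wild-type and mutant flowgrams differ; ``wt_only_set`` holds indices
    where they agree with positive signal (used for normalization and as
    the within-run noise reference).
    """

    wt_template: str
    mut_template: str
    dispensation_order: str = "ACGT"
    n_events: int | None = None  # default: 3x wild-type template length
    noise_sd: float = 0.05
    name: str = ""

    events: str = field(init=False)
    wt_signal: np.ndarray = field(init=False)
    mut_signal: np.ndarray = field(init=False)
    informative_set: np.ndarray = field(init=False)
    wt_only_set: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = self.n_events or 3 * len(self.wt_template)
        events = cyclic_dispensation(self.dispensation_order, n)
        wt = expected_flowgram(self.wt_template, events)
        mut = expected_flowgram(self.mut_template, events)
        informative = np.flatnonzero(wt != mut)
        wt_only = np.flatnonzero((wt == mut) & (wt > 0))
        if informative.size == 0:
            raise ValueError(
                "degenerate assay: expected mutant and wild-type flowgrams "
                "are identical"
            )
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "wt_signal", wt)
        object.__setattr__(self, "mut_signal", mut)
        object.__setattr__(self, "informative_set", informative)
        object.__setattr__(self, "wt_only_set", wt_only)


def mixture_flowgram(
    wt_signal: np.ndarray, mut_signal: np.ndarray, f: float
) -> np.ndarray:
    """Expected flowgram of a template mixture: (1−f)·wt + f·mut elementwise."""
    wt = np.asarray(wt_signal, dtype=float)
    mut = np.asarray(mut_signal, dtype=float)
    if wt.shape != mut.shape:
        raise ValueError(f"signal length mismatch: {wt.shape} vs {mut.shape}")
    if not 0 <= f <= 1:
        raise ValueError(f"mutant fraction must be in [0, 1], got {f}")
    return (1 - f) * wt + f * mut


def normalize_flowgram(
    raw_signal: np.ndarray, assay: PyroAssay
) -> tuple[np.ndarray, float]:
    """Rescale a raw pyrogram against the known wild-type signals.

    The scale factor is the mean of expected/raw over the wild-type-only
    dispensations (zero raw signals are skipped); returns the rescaled
    signal and the factor.
    """
    raw = np.asarray(raw_signal, dtype=float)
    if assay.wt_only_set.size == 0:
        raise ValueError("assay has no wild-type-only dispensations")
    expected = assay.wt_signal[assay.wt_only_set].astype(float)
    observed = raw[assay.wt_only_set]
    usable = observed != 0
    if not usable.any():
        raise ValueError("all wild-type-only signals are zero; cannot normalize")
    factor = float(np.mean(expected[usable] / observed[usable]))
    return raw * factor, factor


def estimate_fraction(observed: np.ndarray, assay: PyroAssay) -> float:
    """Least-squares mutant-fraction estimate on informative dispensations.

    Regresses observed−wt on mut−wt over the informative set and clamps
    the slope to [0, 1]; exact for noise-free mixtures.
    """
    obs = np.asarray(observed, dtype=float)
    idx = assay.informative_set
    diff = (assay.mut_signal - assay.wt_signal)[idx].astype(float)
    denom = float(diff @ diff)
    if denom == 0:
        raise ValueError("degenerate assay: no signal difference to regress on")
    f_hat = float((obs - assay.wt_signal)[idx] @ diff) / denom
    return min(1.0, max(0.0, f_hat))


@dataclass(frozen=True)
class PyroCall:
    status: str  # MUT or WT
    p_value: float
    f_hat: float


def call_pyro(
    observed: np.ndarray, assay: PyroAssay, alpha: float = 0.05
) -> PyroCall:
    """Statistical mutation call from a normalized pyrogram.

    Absolute residuals from the expected wild-type flowgram at
    informative dispensations are tested (one-sided two-sample t-test)
    against those at wild-type-only dispensations; MUT requires p ≤ α
    and a positive estimated mutant fraction.  When both residual
    groups are constant the test degenerates and any informative
    residual above numerical noise is called MUT.
    """
    obs = np.asarray(observed, dtype=float)
    if assay.informative_set.size < 2:
        raise ValueError("informative_set needs >= 2 dispensations for the test")
    if assay.wt_only_set.size < 2:
        raise ValueError("wt_only_set needs >= 2 dispensations for the test")
    residuals = obs - assay.wt_signal
    informative = np.abs(residuals[assay.informative_set])
    reference = np.abs(residuals[assay.wt_only_set])
    f_hat = estimate_fraction(obs, assay)
    if informative.max(initial=0.0) < _RESIDUAL_EPS and reference.max(
        initial=0.0
    ) < _RESIDUAL_EPS:
        return PyroCall("WT", 1.0, f_hat)
    t, p = stats.ttest_ind(informative, reference, alternative="greater")
    if np.isnan(p):  # both groups constant: zero-variance degenerate case
        mut = bool((informative > _RESIDUAL_EPS).any())
        return PyroCall("MUT" if mut else "WT", 0.0 if mut else 1.0, f_hat)
    status = "MUT" if (p <= alpha and f_hat > 0) else "WT"
    return PyroCall(status, float(p), f_hat)


@dataclass(frozen=True)
class DilutionSeries:
    """Result of a simulated dilution series: per-fraction detection rates."""

    rates: dict[float, float]
    lod: float | None  # smallest fraction with rate >= min_rate, else None
    replicates: int
    seed: int


def dilution_lod(
    assay: PyroAssay,
    fractions: list[float],
    replicates: int = 500,
    seed: int = 0,
    min_rate: float = 0.95,
    alpha: float = 0.05,
) -> DilutionSeries:
    """Empirical limit of detection from a simulated dilution series.

    Mutant and wild-type templates are mixed at each fraction,
    per-dispensation Gaussian noise of scale ``assay.noise_sd`` is
    added, and the detection rate of :func:`call_pyro` over seeded
    replicates is recorded; the LoD is the smallest fraction detected
    in at least ``min_rate`` of replicates.
    """
    if not fractions:
        raise ValueError("fraction list must be nonempty")
    if sorted(fractions) != list(fractions):
        raise ValueError("fractions must be sorted ascending")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rates: dict[float, float] = {}
    lod = None
    for f in fractions:
        expected = mixture_flowgram(assay.wt_signal, assay.mut_signal, f)
        hits = 0
        for _ in range(replicates):
            obs = expected + rng.normal(0.0, assay.noise_sd, expected.size)
            if call_pyro(obs, assay, alpha=alpha).status == "MUT":
                hits += 1
        rates[f] = hits / replicates
        if lod is None and f > 0 and rates[f] >= min_rate:
            lod = f
    return DilutionSeries(rates=rates, lod=lod, replicates=replicates, seed=seed)


def load_assay(path: str | Path) -> PyroAssay:
    """Load an assay definition from a flat-key YAML config."""
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return PyroAssay(
        wt_template=cfg["wt_template"],
        mut_template=cfg["mut_template"],
        dispensation_order=cfg.get("dispensation_order", "ACGT"),
        n_events=cfg.get("n_events"),
        noise_sd=float(cfg.get("noise_sd", 0.05)),
        name=cfg.get("name", Path(path).stem),
    )


def read_pyrogram(path: str | Path) -> Flowgram:
    """Read a pyrogram CSV with columns event_index, base, signal."""
    bases: list[str] = []
    signal: list[float] = []
    with Path(path).open(encoding="utf-8") as handle:
        header = handle.readline().strip().split(",")
        if header != ["event_index", "base", "signal"]:
            raise ValueError(f"{path}: pyrogram header must be event_index,base,signal")
        for line in handle:
            if not line.strip():
                continue
            _, base, value = line.strip().split(",")
            bases.append(base)
            signal.append(float(value))
    return Flowgram("".join(bases), np.array(signal))


def write_pyrogram(flowgram: Flowgram, path: str | Path) -> None:
    lines = ["event_index,base,signal"]
    for i, (base, value) in enumerate(zip(flowgram.dispensation, flowgram.signal)):
        lines.append(f"{i},{base},{value:g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
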