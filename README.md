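# mutbench

Benchmarking of clinical mutation diagnostics for non-small-cell lung
cancer (NSCLC): how reliably do dideoxy ("Sanger") sequencing and
pyrosequencing detect therapeutically decisive *EGFR* and *KRAS*
hotspot mutations, when judged against deep ("massively parallel")
amplicon sequencing as the sensitive reference?

The package is aimed at molecular-diagnostics developers and
computational biologists who want the whole comparison — detection
models, cohort statistics, and a synthetic specimen generator — as
tested, reproducible code. It reimplements the pipeline behind a
24-specimen / 22-patient benchmark cohort in which the reference method
found 18 mutations, conventional dideoxy sequencing only 12, and
pyrosequencing 16 — differences that directly change which patients
would have received an EGFR inhibitor.

## Models

**Poisson error-model caller** (deep amplicon sequencing). Under the
wild-type null, mutant-supporting reads at coverage *N* are Poisson
with mean *N·e* (*e* = 0.1% per read per site; 1% at
homopolymer-flagged sites). The caller computes the minimal significant
count

  k_min(N) = min { k : P(X ≥ k) ≤ α },  X ~ Poisson(N·e),  α = 0.05,

calls MUT when the observed mutant count reaches k_min, and reports the
allele fraction k/N. The detection limit k_min/N is 0.5% at 600× and
≈0.33% at 1500×.

**Pyrosequencing flowgram model.** Templates are read through a cyclic
dispensation order; each dispensation yields a signal equal to the
incorporated homopolymer run length. A specimen with mutant fraction
*f* produces the mixture (1−f)·wt + f·mut; *f* is recovered by least
squares on the dispensations where wild-type and mutant expected
flowgrams differ, and mutations are called by a one-sided two-sample
t-test (p ≤ 0.05) of absolute residuals at mutation-informative vs
wild-type-only dispensations. Simulated dilution series put the limit
of detection of the bundled assays at 5–10% mutant alleles.

**Dideoxy surrogate.** Sanger sequencing is summarized by an
allele-fraction limit of detection (hard threshold 0.29, the smallest
fraction it detected in the cohort; optional logistic soft mode), plus
deterministic fragment-length analysis for exon 19 deletions.

**Benchmark harness and generator.** The harness scores each method
against the parallel-sequencing truth set (sensitivity, misdiagnoses,
responder detection, minimum detected fraction, tumor-content vs
allele-fraction correlation). The generator simulates specimens from a
purity/copy-number/multiplicity model, f = p·m / (p·C_t + 2(1−p)), with
histopathology noise rounded to 5% steps and binomial read sampling.

## Worked example

```python
>>> import mutbench as mb
>>> cohort = mb.load_table1()              # bundled benchmark cohort
>>> mb.sensitivity(cohort, "dideoxy")
Sensitivity(detected=12, total=18, percent=67)
>>> mb.sensitivity(cohort, "pyro")
Sensitivity(detected=16, total=18, percent=89)
>>> mb.responder_detection(cohort, "dideoxy")
(7, 11)
>>> corr = mb.purity_frequency_correlation(cohort)
>>> round(corr.r_squared, 3), corr.n_pairs, round(corr.p_value, 3)
(0.279, 17, 0.029)
>>> mb.min_significant_count(600), mb.min_significant_count(1500)
(3, 5)
```

Reading: dideoxy sequencing recovers only 12 of the 18 mutations (67%)
and finds the sensitizing *EGFR* mutation in just 7 of the 11 patients
with a confirmed partial response to erlotinib; pyrosequencing reaches
89% and 9/11. The pathologist's tumor-content estimate explains only
~28% of the variance in measured allele fraction (17 specimens with
both values), so histopathology cannot substitute for analytic
sensitivity. At 600× coverage, 3 mutant reads are already significant
under the Poisson error model.

The numbered scripts under `analysis/` run the full story —
`01_cohort_overview.py` through `05_synthetic_benchmark.py` — and write
their tables to `results/`. The command-line interface mirrors them
(`mutbench cohort validate`, `mutbench limits`, `mutbench bench`,
`mutbench pyro-lod`, `mutbench simulate`, ...).

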