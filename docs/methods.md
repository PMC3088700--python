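# Methods

## Scope and data

The package benchmarks three mutation-detection technologies on a
bundled NSCLC cohort table and on synthetic specimens. The fixture
(`src/mutbench/data/table1.tsv`) is a cell-for-cell transcription of
the published clinical table: 25 rows covering 24 physical specimens
from 22 patients. One relapse liver biopsy carries two mutations (a
sensitizing exon 19 deletion at 95% allele fraction and T790M at 20%)
and therefore occupies two rows; `Cohort.n_specimens` collapses rows of
one case with an identical tissue/specimen/tumor-content description,
which merges exactly that pair. All benchmark statistics are row-level
(one row = one mutation event or one wild-type specimen), matching how
the published counts (18 mutations, 6 of 24 misdiagnoses) were formed.
A printed typo in one specimen-type cell is transcribed verbatim.

The bundled pileup table (`pileups_low_frequency.tsv`) back-calculates
mutant read counts from the printed low-frequency variant reports
(e.g. 11% of 1315 reads → k = 145); it exists so the caller can be
exercised on the actual reported coverages.

## Poisson error-model caller

Null model: at a non-homopolymer site covered by N reads, reads
miscalled toward the queried mutant allele are Poisson with mean N·e.

Parameters:

| parameter | default | meaning |
|---|---|---|
| e | 0.001 | per-read per-site miscall rate toward the queried allele |
| e_homopolymer | 0.01 | rate at homopolymer-flagged sites (configurable; the source protocol states only the non-homopolymer rate, and pyrosequencing-by-synthesis chemistry is roughly an order of magnitude worse in homopolymer runs) |
| α | 0.05 | one-sided tail significance level |

k_min(N) is the smallest k ≥ 1 with the exact Poisson survival
probability P(X ≥ k) ≤ α — computed with `scipy.stats.poisson.sf`,
never a normal approximation. α is not stated in the source protocol;
0.05 is the unique conventional level whose limits at the 600×/1500×
coverage endpoints (0.5% and 0.33%) reproduce the reported 0.3–0.5%
band (α = 0.01 would give 0.67% at 600×). The detection-limit *range*
is reported at the two coverage endpoints; over all integer coverages
in between, the saw-tooth k_min/N dips slightly below 0.3% (0.296% just
before k_min steps up), which `analysis/02_poisson_limits.py` tabulates.

The test is one-sided: only an excess of mutant reads is evidence of a
mutation. The false-positive control property (simulated null MUT rate
≤ α) holds by construction and is verified by simulation at 10,000
replicates.

The low-frequency group screen (`compare_low_freq_groups`) is a
two-sample Student t-test (pooled variance by default, Welch optional)
on per-sample mutant-read frequencies reported per 1000 reads. Since
per-sample clinical frequencies are not published, this operation is
exercised on synthetic data only.

## Pyrosequencing model

`expected_flowgram` implements standard pyrosequencing-by-synthesis
signal logic: a cursor walks the template; each dispensed base yields a
signal equal to the maximal matching run at the cursor. Cyclic
dispensation orders are expanded to 3× the wild-type template length by
default, enough to read any template through.

Design choices that the assay description leaves open, decided here:

- **Noise reference for the t-test.** "Significant calling from
  experimental noise" is operationalized as a one-sided two-sample
  t-test of |residual from expected wild-type signal| at
  mutation-informative dispensations vs wild-type-only dispensations —
  the within-run dispensations where no mutation signal can appear
  serve as the noise sample. Paired and one-sample variants would also
  be defensible; this construction is a package decision, not the
  original authors' documented intent. When both residual groups are
  constant (noise-free input) the test degenerates and any informative
  residual above 10⁻⁹ is called MUT.
- **Fraction estimator.** Ordinary least squares of (observed − wt) on
  (mut − wt) over informative dispensations, clamped to [0, 1]. It
  inverts noise-free mixtures exactly (property-tested on a dense f
  grid) and is unbiased to within 0.002 at the calibrated noise level.
- **Normalization.** Scale factor = mean of expected/observed over
  wild-type-only dispensations with nonzero observed signal; exact for
  any uniform rescaling.

Noise is i.i.d. Gaussian per dispensation in normalized signal units.
The default scale 0.05 places the EGFR-deletion assay's dilution-series
limit of detection (smallest fraction with ≥95% seeded detection rate)
at 10%, inside the 5–10% window the assays were validated to. The KRAS
G12V point-substitution assay exposes only two informative
dispensations under a cyclic ACGT order, so its config uses a tighter
noise scale (0.03) to reach the same window — real assays achieve this
with tailored dispensation orders, which are out of scope. Bundled
templates are short synthetic hotspot-context sequences, not
proprietary assay designs.

## Dideoxy surrogate

No electropherogram data are available, so Sanger detection is reduced
to an allele-fraction limit of detection. The hard threshold defaults
to 0.29 — the smallest allele fraction dideoxy sequencing detected in
the cohort — rather than the midpoint of the 20–30% mixing-experiment
range, because it reproduces the observed call column exactly
(boundary inclusive: the 29% specimen was detected). A logistic mode
(width 0.03) provides a differentiable soft threshold centered at the
same point for simulation studies. Fragment-length analysis is exact
subtraction with 1-bp capillary resolution; the wild-type amplicon
length is an argument because the source reports both 118 bp (protocol)
and 115 bp (figure) for the same assay.

Applying thresholds (dideoxy 0.29, pyro 0.11, Poisson limit at the
cohort-average 1079× coverage) to the fixture's allele-fraction column
regenerates all three observed call columns on all rows — the
threshold models and the clinical calls are mutually consistent.

## Benchmark harness

Sensitivity uses the parallel-sequencing calls as the truth set and
half-up integer percentage rounding (12/18 → 67, 16/18 → 89).
Misdiagnoses count rows where a method disagrees with the reference.
Responder detection counts a partial-response patient as detected only
if their PR-annotated specimen carries a *sensitizing* mutation (exon
19 deletion or L858R — T790M and KRAS never qualify) called MUT by the
method. The tumor-content/allele-fraction correlation is Pearson over
all mutation-positive rows with both values present — 17 pairs on the
fixture (one CSF specimen lacks a tumor-content estimate), giving
r² = 0.279, p = 0.029. The exact pair set behind the originally
reported two-decimal r² is not recoverable, so tests assert the
interval [0.25, 0.30] rather than an equality; the p-value matches to
three decimals.

## Synthetic-specimen generator

A specimen is tumor purity p, locus copy number C_t in tumor cells,
mutant multiplicity m (m ≤ C_t), diploid normal cells:
f = p·m / (p·C_t + 2(1−p)). Defaults emulate the cohort's composition:
purity uniform on 5–95%, coverage uniform on 600–1500×, heterozygous
diploid (C_t = 2, m = 1) unless varied. Histopathology is emulated as
purity + Gaussian noise (sd 0.15 on the purity scale), clamped and
rounded to the 5% steps pathologists report; sd 0.15 with copy-number
support {2,3,4} and multiplicity {1,2} yields r² ≈ 0.3 between
estimated purity and true fraction — the "low correlation" regime —
versus ≈ 0.997 for the noise-free heterozygous-diploid control. Error
reads add toward the mutant allele only (worst case); there is no
per-base substitution matrix, FFPE damage chemistry, or read-level
(FASTQ) simulation. All randomness flows from one explicit seed.

The copy-number/contamination mechanism is one plausible explanation
for specimens whose allele fraction far undershoots their estimated
purity; it is a modeling choice, not an inference about the clinical
samples.

What passing synthetic tests do **not** show: real pyrograms have
correlated, signal-proportional noise; real purity estimates are not
unbiased Gaussian perturbations; and real cohorts mix tissue qualities
(FFPE degradation) the generator ignores.

## Problem sizes and determinism

Simulation sizes are chosen for desk-scale runs: 10,000 replicates for
false-positive control, 500 for dilution series and detection rates,
200-specimen synthetic cohorts. Hypothesis property tests run
derandomized. The full suite and all analysis drivers complete in well
under a minute on one CPU.
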