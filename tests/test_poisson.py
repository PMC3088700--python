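"""Poisson error-model caller: thresholds, limits, calls, group screen."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mutbench.poisson import (
    ErrorModel,
    GroupComparison,
    PileupCounts,
    call_variant,
    compare_low_freq_groups,
    detection_limit,
    min_significant_count,
    read_pileups,
    write_vcf,
)

DEFAULT = ErrorModel()


def brute_force_k_min(N: int, e: float, alpha: float) -> int:
    """Independent oracle: accumulate Poisson pmf terms directly."""
    mu = N * e
    k = 1
    while True:
        tail = 1.0 - sum(
            math.exp(-mu) * mu**j / math.factorial(j) for j in range(k)
        )
        if tail <= alpha:
            return k
        k += 1


@pytest.mark.parametrize(
    "N, expected",
    [(600, 3), (1000, 4), (1500, 5)],
)
def test_min_significant_count_at_reported_coverages(N, expected):
    assert min_significant_count(N, DEFAULT) == expected


def test_zero_error_rate_makes_any_mutant_read_significant():
    model = ErrorModel(e=0.0)
    assert min_significant_count(937, model) == 1


def test_invalid_coverage_rejected():
    with pytest.raises(ValueError):
        min_significant_count(0, DEFAULT)


def test_error_model_invariants_enforced():
    with pytest.raises(ValueError):
        ErrorModel(e=0.02, e_homopolymer=0.01)
    with pytest.raises(ValueError):
        ErrorModel(alpha=0.0)


@pytest.mark.parametrize(
    "N, limit",
    [(600, 0.005), (1500, pytest.approx(0.003333, abs=1e-4))],
)
def test_detection_limits_at_coverage_endpoints(N, limit):
    """Limits at 600x and 1500x fall in the 0.3-0.5% band."""
    value = detection_limit(N, DEFAULT)
    assert value == limit
    assert 0.003 <= value <= 0.005


def test_agrees_with_brute_force_tail_oracle():
    for N in (100, 600, 1000, 1500, 5000):
        assert min_significant_count(N, DEFAULT) == brute_force_k_min(
            N, DEFAULT.e, DEFAULT.alpha
        )


@given(
    n1=st.integers(100, 5000),
    n2=st.integers(100, 5000),
    e1=st.floats(1e-4, 5e-3),
    e2=st.floats(1e-4, 5e-3),
)
def test_k_min_monotone_in_coverage_and_error(n1, n2, e1, e2):
    if n1 > n2:
        n1, n2 = n2, n1
    if e1 > e2:
        e1, e2 = e2, e1
    assert min_significant_count(n1, ErrorModel(e=e1)) <= min_significant_count(
        n2, ErrorModel(e=e1)
    )
    assert min_significant_count(n1, ErrorModel(e=e1)) <= min_significant_count(
        n1, ErrorModel(e=e2)
    )


def test_homopolymer_sites_use_elevated_rate():
    p = PileupCounts("s", "hp_locus", 1000, 12, homopolymer=True)
    call = call_variant(p, DEFAULT)
    assert call.k_min == min_significant_count(1000, DEFAULT, homopolymer=True)
    assert call.k_min > min_significant_count(1000, DEFAULT)


@pytest.mark.parametrize(
    "coverage, k, status, fraction",
    [
        # mirrors the reported 6%-of-1081-reads low-frequency deletion
        (1081, 65, "MUT", pytest.approx(0.060, abs=1e-3)),
        (1000, 0, "WT", 0.0),
        (1000, 3, "WT", 0.003),  # k_min = 4 at 1000x
        (1000, 4, "MUT", 0.004),
    ],
)
def test_call_variant(coverage, k, status, fraction):
    call = call_variant(PileupCounts("s", "locus", coverage, k), DEFAULT)
    assert call.status == status
    assert call.fraction_hat == fraction
    assert (call.status == "MUT") == (k >= call.k_min)


def test_pileup_count_bounds_enforced():
    with pytest.raises(ValueError):
        PileupCounts("s", "l", 100, 101)
    with pytest.raises(ValueError):
        PileupCounts("s", "l", 0, 0)


def test_false_positive_rate_controlled_under_null():
    """Simulating error-only pileups, the MUT rate stays at or below alpha."""
    rng = np.random.default_rng(2024)
    N, reps = 1000, 10_000
    counts = rng.poisson(N * DEFAULT.e, size=reps)
    k_min = min_significant_count(N, DEFAULT)
    fp_rate = float(np.mean(counts >= k_min))
    # three-sigma binomial slack on top of alpha
    assert fp_rate <= DEFAULT.alpha + 3 * math.sqrt(DEFAULT.alpha / reps)


def test_bundled_low_frequency_pileups_all_called():
    """The shipped pileup table (printed read counts) yields MUT throughout."""
    from importlib import resources

    ref = resources.files("mutbench.data") / "pileups_low_frequency.tsv"
    with resources.as_file(ref) as path:
        pileups = read_pileups(path)
    assert len(pileups) == 6
    calls = [call_variant(p, DEFAULT) for p in pileups]
    assert all(c.status == "MUT" for c in calls)
    by_id = {p.specimen_id: c for p, c in zip(pileups, calls)}
    assert by_id["05"].fraction_hat == pytest.approx(0.11, abs=0.005)
    assert by_id["31"].fraction_hat == pytest.approx(0.06, abs=0.005)


def test_vcf_writer_emits_only_mut_records(tmp_path):
    pileups = [
        PileupCounts("a", "locus1", 1000, 50),
        PileupCounts("b", "locus2", 1000, 1),
    ]
    calls = [call_variant(p, DEFAULT) for p in pileups]
    out = tmp_path / "calls.vcf"
    n = write_vcf(pileups, calls, out, locus_map={"locus1": ("7", 55242464, "A", "T")})
    text = out.read_text()
    assert n == 1
    assert text.startswith("##fileformat=VCFv4.2")
    assert "DP=1000;AF=0.0500" in text
    assert "locus2" not in text


class TestLowFrequencyGroupScreen:
    def test_identical_groups(self):
        result = compare_low_freq_groups([2, 3, 4], [2, 3, 4])
        assert result.mean_a == result.mean_b == 3.0
        assert result.t_statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        """n=3 per group, unit variances: t = 3/sqrt(2/3) = 3.674."""
        result = compare_low_freq_groups([4, 5, 6], [1, 2, 3])
        assert result.t_statistic == pytest.approx(3.674, abs=1e-3)
        assert result.p_value == pytest.approx(0.021, abs=1e-3)

    def test_single_value_group_flags_test_unavailable(self):
        result = compare_low_freq_groups([2.5], [0.5, 1.0])
        assert result == GroupComparison(2.5, 0.75, None, None)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_low_freq_groups([], [1, 2])

    def test_welch_option(self):
        pooled = compare_low_freq_groups([4, 5, 6], [1, 2, 3])
        welch = compare_low_freq_groups([4, 5, 6], [1, 2, 3], welch=True)
        # equal group sizes and variances: same t, same p here
        assert welch.t_statistic == pytest.approx(pooled.t_statistic)
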