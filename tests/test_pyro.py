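"""Pyrosequencing flowgram model, estimators, calling, and dilution LoD."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mutbench.pyro import (
    Flowgram,
    PyroAssay,
    call_pyro,
    cyclic_dispensation,
    dilution_lod,
    estimate_fraction,
    expected_flowgram,
    mixture_flowgram,
    normalize_flowgram,
    read_pyrogram,
    write_pyrogram,
)


@pytest.mark.parametrize(
    "template, events, expected",
    [
        ("AATG", "ACGTACG", [2, 0, 0, 1, 0, 0, 1]),
        ("", "ACGT", [0, 0, 0, 0]),
        ("A", "CA", [0, 1]),
    ],
)
def test_expected_flowgram_run_length_walk(template, events, expected):
    assert expected_flowgram(template, events).tolist() == expected


def test_expected_flowgram_rejects_non_acgt():
    with pytest.raises(ValueError, match="non-ACGT"):
        expected_flowgram("AANG", "ACGT")


@given(st.text(alphabet="ACGT", min_size=1, max_size=30))
def test_flowgram_signal_sums_to_template_length(template):
    """With enough dispensations to read through, total signal = template length."""
    events = cyclic_dispensation("ACGT", 4 * len(template))
    assert expected_flowgram(template, events).sum() == len(template)


def test_mixture_endpoints_and_midpoint(egfr_del_assay):
    wt, mut = egfr_del_assay.wt_signal, egfr_del_assay.mut_signal
    assert np.array_equal(mixture_flowgram(wt, mut, 0.0), wt)
    assert np.array_equal(mixture_flowgram(wt, mut, 1.0), mut)
    mid = mixture_flowgram(wt, mut, 0.5)
    assert np.allclose(mid, (wt + mut) / 2)


def test_mixture_length_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        mixture_flowgram(np.ones(3), np.ones(4), 0.5)


def test_degenerate_assay_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        PyroAssay(wt_template="ACGT", mut_template="ACGT")


class TestNormalization:
    def test_uniform_double_scale_recovered(self, egfr_del_assay):
        raw = 2.0 * egfr_del_assay.wt_signal
        normalized, factor = normalize_flowgram(raw, egfr_del_assay)
        assert factor == pytest.approx(0.5)
        idx = egfr_del_assay.wt_only_set
        assert np.allclose(normalized[idx], egfr_del_assay.wt_signal[idx])

    def test_identity(self, egfr_del_assay):
        normalized, factor = normalize_flowgram(
            egfr_del_assay.wt_signal.astype(float), egfr_del_assay
        )
        assert factor == pytest.approx(1.0)
        assert np.allclose(normalized, egfr_del_assay.wt_signal)

    def test_seeded_noise_keeps_factor_near_one(self, egfr_del_assay):
        rng = np.random.default_rng(7)
        raw = egfr_del_assay.wt_signal + rng.normal(
            0, 0.05, egfr_del_assay.wt_signal.size
        )
        _, factor = normalize_flowgram(raw, egfr_del_assay)
        assert abs(factor - 1.0) < 0.05

    @given(scale=st.floats(0.1, 10.0))
    def test_inverts_any_positive_scale(self, egfr_del_assay, scale):
        raw = scale * egfr_del_assay.wt_signal
        normalized, _ = normalize_flowgram(raw, egfr_del_assay)
        idx = egfr_del_assay.wt_only_set
        assert np.allclose(normalized[idx], egfr_del_assay.wt_signal[idx])

    def test_all_zero_reference_signals_rejected(self, egfr_del_assay):
        with pytest.raises(ValueError, match="cannot normalize"):
            normalize_flowgram(
                np.zeros(egfr_del_assay.wt_signal.size), egfr_del_assay
            )


class TestFractionEstimate:
    @given(f=st.floats(0.0, 1.0))
    def test_exact_inversion_of_noise_free_mixture(self, egfr_del_assay, f):
        mix = mixture_flowgram(
            egfr_del_assay.wt_signal, egfr_del_assay.mut_signal, f
        )
        assert estimate_fraction(mix, egfr_del_assay) == pytest.approx(f, abs=1e-12)

    def test_wild_type_signal_estimates_zero(self, egfr_del_assay):
        assert estimate_fraction(
            egfr_del_assay.wt_signal.astype(float), egfr_del_assay
        ) == 0.0

    def test_seeded_monte_carlo_mean_near_truth(self, egfr_del_assay):
        rng = np.random.default_rng(7)
        mix = mixture_flowgram(
            egfr_del_assay.wt_signal, egfr_del_assay.mut_signal, 0.10
        )
        estimates = [
            estimate_fraction(
                mix + rng.normal(0, 0.05, mix.size), egfr_del_assay
            )
            for _ in range(200)
        ]
        assert np.mean(estimates) == pytest.approx(0.10, abs=0.02)


class TestCalling:
    def test_noise_free_mixture_called_mut(self, egfr_del_assay):
        mix = mixture_flowgram(
            egfr_del_assay.wt_signal, egfr_del_assay.mut_signal, 0.3
        )
        call = call_pyro(mix, egfr_del_assay)
        assert call.status == "MUT"
        assert call.f_hat == pytest.approx(0.3)

    def test_noise_free_wild_type_called_wt(self, egfr_del_assay):
        call = call_pyro(egfr_del_assay.wt_signal.astype(float), egfr_del_assay)
        assert call.status == "WT"
        assert call.p_value == 1.0

    def test_detection_rate_at_ten_percent(self, egfr_del_assay):
        """f=0.10 with the calibrated noise is detected in >=95% of runs."""
        rng = np.random.default_rng(5)
        mix = mixture_flowgram(
            egfr_del_assay.wt_signal, egfr_del_assay.mut_signal, 0.10
        )
        hits = sum(
            call_pyro(mix + rng.normal(0, 0.05, mix.size), egfr_del_assay).status
            == "MUT"
            for _ in range(500)
        )
        assert hits / 500 >= 0.95

    def test_small_reference_set_rejected(self):
        # wt GG vs mut GT: no shared positive dispensation -> empty wt_only_set
        assay = PyroAssay("GG", "GT", n_events=8)
        mix = assay.wt_signal.astype(float)
        with pytest.raises(ValueError, match="wt_only_set"):
            call_pyro(mix, assay)


class TestDilutionSeries:
    def test_zero_noise_detects_smallest_nonzero_fraction(self, egfr_del_assay):
        quiet = PyroAssay(
            egfr_del_assay.wt_template, egfr_del_assay.mut_template, noise_sd=0.0
        )
        series = dilution_lod(quiet, [0.0, 0.01, 0.05], replicates=3, seed=1)
        assert series.lod == 0.01
        assert series.rates[0.01] == 1.0

    def test_calibrated_lod_in_five_to_ten_percent_window(self, egfr_del_assay):
        series = dilution_lod(
            egfr_del_assay, [0.01, 0.05, 0.10, 0.20], replicates=500, seed=11
        )
        assert series.lod in (0.05, 0.10)

    def test_deterministic_under_fixed_seed(self, egfr_del_assay):
        kwargs = dict(fractions=[0.05, 0.10], replicates=1, seed=42)
        assert dilution_lod(egfr_del_assay, **kwargs) == dilution_lod(
            egfr_del_assay, **kwargs
        )

    def test_empty_fraction_list_rejected(self, egfr_del_assay):
        with pytest.raises(ValueError, match="nonempty"):
            dilution_lod(egfr_del_assay, [], replicates=1, seed=0)

    def test_unsorted_fractions_rejected(self, egfr_del_assay):
        with pytest.raises(ValueError, match="ascending"):
            dilution_lod(egfr_del_assay, [0.1, 0.05], replicates=1, seed=0)


def test_pyrogram_csv_roundtrip(tmp_path, egfr_del_assay):
    flowgram = Flowgram(egfr_del_assay.events, egfr_del_assay.wt_signal)
    path = tmp_path / "pyrogram.csv"
    write_pyrogram(flowgram, path)
    reread = read_pyrogram(path)
    assert reread.dispensation == flowgram.dispensation
    assert np.array_equal(reread.signal, flowgram.signal)
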