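"""Windowing, spectra, SNR gating and median-fused heart-rate estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aerorate.hr import (
    HRConfig,
    SpectrumWindow,
    accept_spectrum,
    compute_spectrum,
    estimate_hr,
    median_spectrum,
    peak_snr,
    window_signal,
)
from aerorate.rppg import PulseSignal


def brute_force_snr(freqs, power, peak, alpha):
    band = rest = 0.0
    for f, p in zip(freqs, power):
        if peak - alpha <= f <= peak + alpha:
            band += p
        else:
            rest += p
    return math.inf if rest == 0 else band / rest


class TestWindowing:
    @pytest.mark.parametrize(
        "L, expected_starts",
        [(45, [0]), (51, [0, 2, 4, 6]), (44, []), (46, [0]), (47, [0, 2])],
    )
    def test_counts_and_starts(self, L, expected_starts):
        wins = window_signal(np.arange(L, dtype=float), window=45, stride=2)
        assert len(wins) == len(expected_starts)
        for w, s in zip(wins, expected_starts):
            assert w[0] == s and w.size == 45

    @given(
        L=st.integers(0, 500),
        window=st.integers(2, 100),
        stride=st.integers(1, 10),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_count_formula_matches_enumeration(self, L, window, stride):
        wins = window_signal(np.zeros(L), window=window, stride=stride)
        expected = [s for s in range(0, max(L - window + 1, 0), stride)]
        formula = 0 if L < window else (L - window) // stride + 1
        assert len(wins) == len(expected) == formula


class TestSpectrum:
    def test_sinusoid_peak_position(self):
        fs, T = 15.0, 45
        x = np.sin(2 * np.pi * 1.2 * np.arange(T) / fs)  # 72 bpm
        spec = compute_spectrum(x, fs)
        assert spec.freqs_bpm[np.argmax(spec.power)] == pytest.approx(72.0, abs=1.0)

    def test_grid_resolution_and_coverage(self):
        spec = compute_spectrum(np.random.default_rng(0).standard_normal(45), 15.0)
        assert np.all(np.diff(spec.freqs_bpm) <= 1.0 + 1e-9)
        assert spec.freqs_bpm[0] == 0.0
        assert spec.freqs_bpm[-1] >= 180.0
        assert np.all(spec.power >= 0.0)

    def test_constant_input_all_zero(self):
        spec = compute_spectrum(np.full(45, 7.0), 15.0)
        assert np.allclose(spec.power, 0.0)

    def test_two_tone_peaks(self):
        fs, T = 15.0, 225
        t = np.arange(T) / fs
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 2.0 * t)  # 60 + 120 bpm
        spec = compute_spectrum(x, fs)
        in_band = spec.freqs_bpm > 10
        order = np.argsort(spec.power[in_band])[::-1]
        peaks = set()
        for f in spec.freqs_bpm[in_band][order]:
            if all(abs(f - p) > 10 for p in peaks):
                peaks.add(round(f))
            if len(peaks) == 2:
                break
        assert any(abs(p - 60) <= 1 for p in peaks)
        assert any(abs(p - 120) <= 1 for p in peaks)


class TestPeakSNR:
    def test_toy_seven_bin_spectrum(self):
        # hand-worked: band = bins 2..4 -> 1+8+1 = 10; rest = 10 -> SNR = 1.0
        spec = SpectrumWindow(
            freqs_bpm=np.arange(7.0), power=np.array([0, 0, 1, 8, 1, 0, 10.0])
        )
        assert peak_snr(spec, peak_bpm=3.0, alpha=1.0) == pytest.approx(1.0)

    def test_all_power_in_band_is_infinite(self):
        spec = SpectrumWindow(
            freqs_bpm=np.arange(5.0), power=np.array([0, 0, 4.0, 0, 0])
        )
        assert peak_snr(spec, peak_bpm=2.0, alpha=1.0) == math.inf

    def test_flat_spectrum_closed_form(self):
        n = 200
        spec = SpectrumWindow(freqs_bpm=np.linspace(0, 199, n), power=np.ones(n))
        alpha = 10.0
        got = peak_snr(spec, peak_bpm=100.0, alpha=alpha)
        in_band = np.sum(np.abs(spec.freqs_bpm - 100.0) <= alpha)
        f = in_band / n
        assert got == pytest.approx(f / (1 - f))

    def test_matches_brute_force_on_random_spectra(self, rng):
        for _ in range(1000):
            n = int(rng.integers(10, 60))
            freqs = np.sort(rng.uniform(0, 200, n))
            power = rng.uniform(0, 5, n)
            peak = float(rng.uniform(0, 200))
            alpha = float(rng.uniform(0.5, 20))
            spec = SpectrumWindow(freqs_bpm=freqs, power=power)
            assert peak_snr(spec, peak, alpha) == pytest.approx(
                brute_force_snr(freqs, power, peak, alpha)
            )


class TestAcceptance:
    def _spec_from(self, x, fs=15.0):
        return compute_spectrum(x, fs)

    def test_clean_pulse_accepted(self):
        t = np.arange(45) / 15.0
        spec = self._spec_from(np.sin(2 * np.pi * 1.2 * t))
        assert accept_spectrum(spec)

    def test_strong_low_frequency_drift_rejected(self):
        # 20 bpm drift dominating a weak 72 bpm pulse: low-band max exceeds
        # the target-band max -> rejected by the low-frequency condition
        t = np.arange(45) / 15.0
        x = 5.0 * np.sin(2 * np.pi * (20 / 60) * t) + 0.4 * np.sin(2 * np.pi * 1.2 * t)
        spec = self._spec_from(x)
        assert not accept_spectrum(spec)

    def test_flat_noise_rejected_by_snr(self):
        # near-uniform power: the best peak's band holds ~2 of ~450 bpm of
        # power, far below the 2.5% SNR gate once the low band is quiet
        freqs = np.linspace(0, 450, 451)
        power = np.ones_like(freqs)
        power[freqs < 50] = 0.0  # keep condition (b) satisfied
        spec = SpectrumWindow(freqs_bpm=freqs, power=power)
        assert not accept_spectrum(spec)

    def test_snr_gate_threshold(self):
        # one sharp in-band peak over a flat floor engineered just above the
        # 2.5% gate is accepted; the same spectrum far below the gate is not
        freqs = np.linspace(0, 450, 901)
        floor = np.full_like(freqs, 1.0)
        floor[freqs < 50] = 0.0
        strong = floor.copy()
        strong[np.argmin(np.abs(freqs - 90))] += 40.0
        assert accept_spectrum(SpectrumWindow(freqs_bpm=freqs, power=strong))
        weak = floor.copy()
        weak[np.argmin(np.abs(freqs - 90))] += 1.0
        assert not accept_spectrum(SpectrumWindow(freqs_bpm=freqs, power=weak))


class TestMedianSpectrum:
    def _sw(self, power):
        return SpectrumWindow(freqs_bpm=np.arange(len(power), dtype=float), power=np.asarray(power, float))

    def test_single_spectrum_identity(self):
        s = self._sw([1.0, 2.0, 3.0])
        assert np.array_equal(median_spectrum([s]).power, s.power)

    def test_odd_count_median(self):
        specs = [self._sw([1, 0, 0]), self._sw([2, 0, 0]), self._sw([9, 0, 0])]
        assert median_spectrum(specs).power[0] == 2.0

    def test_even_count_mid_mean(self):
        specs = [self._sw([1, 4, 0]), self._sw([3, 8, 0])]
        assert median_spectrum(specs).power.tolist() == [2.0, 6.0, 0.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_spectrum([])

    def test_mismatched_grids_rejected(self):
        a = self._sw([1.0, 2.0])
        b = SpectrumWindow(freqs_bpm=np.array([0.0, 5.0]), power=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            median_spectrum([a, b])


class TestEstimateHR:
    def _pulse(self, hr_bpm, method, T=300, fs=15.0, amp=1.0):
        t = np.arange(T) / fs
        v = amp * np.sin(2 * np.pi * hr_bpm / 60 * t)
        return PulseSignal(method, v - v.mean(), roi_label="roi", segment_id="s0")

    def test_single_rate_both_methods(self):
        sigs = [self._pulse(90, "CHROM"), self._pulse(90, "POS")]
        res = estimate_hr(sigs, 15.0)
        assert res.status == "ok"
        assert res.hr_final == pytest.approx(90, abs=1.0)
        assert res.hr_final == pytest.approx((res.hr_pos + res.hr_chrom) / 2)

    def test_methods_fused_by_mean(self):
        sigs = [self._pulse(80, "POS"), self._pulse(90, "CHROM")]
        res = estimate_hr(sigs, 15.0)
        assert res.hr_pos == pytest.approx(80, abs=1.0)
        assert res.hr_chrom == pytest.approx(90, abs=1.0)
        assert res.hr_final == pytest.approx(85, abs=1.0)

    def test_no_signals_status(self):
        res = estimate_hr([], 15.0)
        assert res.status == "failed_no_segments"
        assert res.hr_final is None

    def test_nothing_accepted_status(self):
        # pure sub-band drift: every window fails the low-frequency condition
        t = np.arange(300) / 15.0
        drift = np.sin(2 * np.pi * (20 / 60) * t)
        sigs = [PulseSignal("POS", drift - drift.mean())]
        res = estimate_hr(sigs, 15.0)
        assert res.status == "failed_no_accepted_spectra"
        assert res.hr_final is None

    def test_result_in_target_band(self, calm_signals):
        from aerorate.pipeline import estimate_from_roi_signals

        signals, gt, fm_f, fm_g = calm_signals
        res, _ = estimate_from_roi_signals(signals, fm_f, fm_g, 15.0)
        assert res.status == "ok"
        assert 50.0 <= res.hr_final <= 180.0
        assert res.hr_final == pytest.approx(70.0, abs=1.0)
        assert res.accepted_window_counts["POS"] > 0
        assert res.accepted_window_counts["CHROM"] > 0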