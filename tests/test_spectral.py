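"""Spectral chain: detrend, PSD normalization, peak/band logic, indices."""

import numpy as np
import pytest

from rtpcflow.io import FlowSignal
from rtpcflow.spectral import (
    BandError,
    Spectrum,
    band_auc,
    band_limits,
    bandpass_visual,
    compute_psd,
    detrend_poly,
    find_spectral_peaks,
    modulation_indices,
    spectral_summary,
)

FS = 1.0 / 0.0585  # image frame rate, Hz
N60 = int(round(60.0 * FS))


def sinusoid(freq, fs=FS, duration=60.0, amp=1.0, phase=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase), t


class TestBandpassVisual:
    def test_passband_center_unity_gain_zero_phase(self):
        y, t = sinusoid(0.25)
        out = bandpass_visual(FlowSignal(y, 1 / FS))
        core = slice(N60 // 4, -N60 // 4)  # avoid filter edge transients
        # fit amplitude and phase of the band-centre component
        design = np.column_stack(
            [np.sin(2 * np.pi * 0.25 * t[core]), np.cos(2 * np.pi * 0.25 * t[core])]
        )
        c, *_ = np.linalg.lstsq(design, out[core], rcond=None)
        amplitude = np.hypot(*c)
        phase_deg = np.degrees(np.arctan2(c[1], c[0]))
        assert amplitude == pytest.approx(1.0, abs=0.01)
        assert abs(phase_deg) < 1.0

    def test_cardiac_frequency_strongly_attenuated(self):
        y, _ = sinusoid(1.2)
        out = bandpass_visual(FlowSignal(y, 1 / FS))
        assert np.sqrt(np.mean(out**2)) < 0.05 * np.sqrt(np.mean(y**2))

    def test_zero_in_zero_out(self):
        out = bandpass_visual(FlowSignal(np.zeros(N60), 1 / FS))
        assert np.allclose(out, 0.0)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(BandError):
            bandpass_visual(FlowSignal(np.zeros(N60), 1 / FS), lo=0.15, hi=10.0)


class TestDetrendPoly:
    def test_exact_quartic_removed(self):
        t = np.arange(N60) / FS
        y = 2.0 + 0.5 * t - 0.02 * t**2 + 1e-3 * t**3 - 1e-5 * t**4
        resid, coef = detrend_poly(y, order=4, times=t)
        assert np.abs(resid).max() < 1e-8 * np.abs(y).max()
        assert len(coef) == 5

    def test_sinusoid_survives_detrending(self):
        t = np.arange(N60) / FS
        quartic = 1.0 + 0.1 * t - 0.01 * t**2 + 2e-4 * t**3 - 1e-6 * t**4
        s, _ = sinusoid(0.25, phase=np.pi / 2)  # even symmetry: minimal poly leakage
        resid, _ = detrend_poly(quartic + s, order=4, times=t)
        r = np.corrcoef(resid, s)[0, 1]
        assert r > 0.999

    def test_projection_contracts_variance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=N60)
        resid, _ = detrend_poly(y, order=4)
        assert resid.var() <= y.var()

    def test_residual_orthogonal_to_monomials(self):
        rng = np.random.default_rng(1)
        t = np.arange(N60) / FS
        resid, _ = detrend_poly(rng.normal(size=N60), order=4, times=t)
        scale = np.linalg.norm(resid)
        for k in range(5):
            mono = ((t - t.mean()) / np.ptp(t)) ** k
            assert abs(resid @ mono) < 1e-8 * scale * np.linalg.norm(mono)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend_poly(np.zeros(5), order=4)


class TestComputePsd:
    def test_sinusoid_total_power(self):
        y, _ = sinusoid(0.25)
        spec = compute_psd(y, FS)
        total = np.trapezoid(spec.psd, spec.freqs)
        assert total == pytest.approx(0.5, rel=0.05)

    def test_two_sinusoids_split_power(self):
        y1, _ = sinusoid(0.25)
        y2, _ = sinusoid(1.2, phase=1.0)
        spec = compute_psd(y1 + y2, FS)
        for f0 in (0.25, 1.2):
            assert band_auc(spec, f0 - 0.05, f0 + 0.05) == pytest.approx(0.5, rel=0.10)

    def test_constant_signal_has_no_power(self):
        spec = compute_psd(np.full(N60, 3.3), FS)
        assert np.trapezoid(spec.psd, spec.freqs) < 1e-10

    def test_parseval_on_noise(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=N60)
        spec = compute_psd(y, FS)
        assert np.trapezoid(spec.psd, spec.freqs) == pytest.approx(spec.variance, rel=0.05)

    def test_irregular_times_resampled(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 60, 1100))
        y = np.sin(2 * np.pi * 0.25 * t)
        spec = compute_psd(y, FS, times=t)
        hf, _ = find_spectral_peaks(spec)
        assert hf == pytest.approx(0.25, abs=2 / 60)

    def test_non_finite_rejected(self):
        y = np.zeros(N60)
        y[10] = np.nan
        with pytest.raises(ValueError):
            compute_psd(y, FS)


class TestFindPeaks:
    def test_two_tone_peaks_within_one_bin(self):
        y1, _ = sinusoid(0.22)
        y2, _ = sinusoid(1.3, phase=0.7)
        spec = compute_psd(y1 + y2, FS)
        hf, vhf = find_spectral_peaks(spec)
        bin_width = 1 / 60.0
        assert abs(hf - 0.22) <= bin_width
        assert abs(vhf - 1.3) <= bin_width

    def test_guidance_beats_taller_harmonic(self):
        y1, _ = sinusoid(1.2, amp=0.5)
        y2, _ = sinusoid(2.4, amp=1.0)  # taller 2nd harmonic
        yr, _ = sinusoid(0.25, amp=0.3)
        spec = compute_psd(y1 + y2 + yr, FS)
        _, vhf_unguided = find_spectral_peaks(spec)
        assert vhf_unguided == pytest.approx(2.4, abs=1 / 60)
        _, vhf = find_spectral_peaks(spec, card_rate=1.2)
        assert vhf == pytest.approx(1.2, abs=1 / 60)

    def test_flat_spectrum_tie_resolves_to_lowest_frequency(self):
        freqs = np.linspace(0, FS / 2, 513)
        spec = Spectrum(freqs=freqs, psd=np.ones_like(freqs), fs=FS, variance=1.0)
        hf, vhf = find_spectral_peaks(spec)
        assert hf == pytest.approx(0.10, abs=freqs[1])
        assert vhf == pytest.approx(0.60, abs=freqs[1])

    def test_window_outside_support_rejected(self):
        freqs = np.linspace(0, FS / 2, 513)
        spec = Spectrum(freqs=freqs, psd=np.ones_like(freqs), fs=FS, variance=1.0)
        with pytest.raises(BandError):
            find_spectral_peaks(spec, card_window=(9.0, 12.0))


class TestBandLimits:
    def test_typical_vessel_peaks(self):
        # median peak locations reported for these vessels: HF 0.24, VHF 1.29
        b = band_limits(0.24, 1.29)
        assert (b.resp_lo, b.resp_hi) == (0.15, 0.35)
        assert b.card_lo == pytest.approx(1.04)
        assert b.card_hi == pytest.approx(1.54)

    def test_low_cardiac_peak_overlap_rejected(self):
        with pytest.raises(BandError, match="overlap"):
            band_limits(0.24, 0.45)

    def test_cardiac_band_width_is_half_hz(self):
        b = band_limits(0.2, 1.0)
        assert b.card_hi - b.card_lo == pytest.approx(0.5)

    def test_peak_relative_mode(self):
        b = band_limits(0.24, 1.29, mode="peak-relative")
        assert b.resp_lo == pytest.approx(0.09)
        assert b.resp_hi == pytest.approx(0.59)


class TestBandAucAndIndices:
    def test_whole_support_integral_equals_variance(self):
        rng = np.random.default_rng(4)
        spec = compute_psd(rng.normal(size=N60), FS)
        assert band_auc(spec, spec.freqs[0] + 1e-9, spec.freqs[-1]) == pytest.approx(
            spec.variance, rel=0.05
        )

    def test_empty_band_has_no_power(self):
        y, _ = sinusoid(1.2)
        spec = compute_psd(y, FS)
        assert band_auc(spec, 3.0, 4.0) < 0.01 * spec.variance

    def test_respiratory_band_captures_sinusoid(self):
        y, _ = sinusoid(0.25)
        spec = compute_psd(y, FS)
        assert band_auc(spec, 0.15, 0.35) == pytest.approx(0.5, rel=0.05)

    def test_inverted_limits_rejected(self):
        y, _ = sinusoid(0.25)
        spec = compute_psd(y, FS)
        with pytest.raises(BandError):
            band_auc(spec, 0.35, 0.15)

    def test_equal_tones_give_unit_ratio(self):
        y1, _ = sinusoid(0.25)
        y2, _ = sinusoid(1.2, phase=0.4)
        spec = compute_psd(y1 + y2, FS)
        bands = band_limits(*find_spectral_peaks(spec), nyquist=spec.nyquist)
        summ = modulation_indices(spec, bands)
        assert summ.ratio_resp_card == pytest.approx(1.0, rel=0.10)
        assert summ.nauc_resp == pytest.approx(0.5, abs=0.05)
        assert summ.nauc_card == pytest.approx(0.5, abs=0.05)

    def test_pure_respiratory_signal(self):
        y, _ = sinusoid(0.25)
        spec = compute_psd(y, FS)
        bands = band_limits(0.25, 1.2, nyquist=spec.nyquist)
        summ = modulation_indices(spec, bands)
        assert summ.nauc_resp >= 0.9
        assert summ.nauc_card <= 0.05

    def test_white_noise_band_share_matches_bandwidth_fraction(self):
        # flat spectrum: expected respiratory share = band width / nyquist
        rng = np.random.default_rng(6)
        shares = []
        for _ in range(100):
            spec = compute_psd(rng.normal(size=N60), FS)
            bands = band_limits(0.25, 1.2, nyquist=spec.nyquist)
            shares.append(modulation_indices(spec, bands).nauc_resp)
        expected = 0.20 / (FS / 2)
        mc_err = 3 * np.std(shares) / 10  # 3 SE over 100 draws
        assert np.mean(shares) == pytest.approx(expected, abs=mc_err + 0.002)

    def test_ratio_is_nauc_quotient(self):
        rng = np.random.default_rng(7)
        spec = compute_psd(rng.normal(size=N60), FS)
        bands = band_limits(0.22, 1.3, nyquist=spec.nyquist)
        summ = modulation_indices(spec, bands)
        assert summ.ratio_resp_card == pytest.approx(summ.nauc_resp / summ.nauc_card)

    def test_nauc_bounds_and_sum(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            y = rng.normal(size=N60) + rng.uniform(0, 2) * np.sin(
                2 * np.pi * 0.25 * np.arange(N60) / FS
            )
            summ = spectral_summary(FlowSignal(y, 1 / FS))
            assert 0 <= summ.nauc_resp and 0 <= summ.nauc_card
            assert summ.nauc_resp + summ.nauc_card <= 1 + 0.05
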