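"""Smoothing branches: FIR low-pass contract and wavelet decomposition."""

import numpy as np
import pytest

from chewcount.errors import InvalidSpecError
from chewcount.processing import (DEFAULT_SPEED_BANDS, DwdSpec, LpfSpec, design_lowpass_fir,
                                  dwd_decompose, lowpass_filter, reconstruct_approximation,
                                  select_dwd_levels)
from chewcount.peaks import find_local_maxima
from chewcount.signal import ChewSignal

FS = 30.0


def tone(freq, amp=1.0, duration=60.0, fs=FS):
    t = np.arange(0, duration, 1 / fs)
    return ChewSignal(amp * np.sin(2 * np.pi * freq * t), fs)


def dft_amplitude(values, freq, fs):
    t = np.arange(len(values)) / fs
    return 2 * abs(np.exp(-2j * np.pi * freq * t) @ values) / len(values)


class TestLowpassFilter:
    def test_dc_passes_unchanged(self):
        sig = ChewSignal(np.full(600, 3.7), FS)
        np.testing.assert_allclose(lowpass_filter(sig).values, 3.7, rtol=2e-2)

    def test_inband_tone_preserved(self):
        out = lowpass_filter(tone(0.5))
        amp = dft_amplitude(out.values, 0.5, FS)
        assert 10 ** (-1 / 20) <= amp <= 10 ** (1 / 20)  # within 1 dB

    def test_stopband_tone_attenuated_40db(self):
        mix = tone(0.5).values + tone(5.0).values
        out = lowpass_filter(ChewSignal(mix, FS))
        assert dft_amplitude(out.values, 5.0, FS) < 10 ** (-40 / 20)
        assert dft_amplitude(out.values, 0.5, FS) == pytest.approx(1.0, abs=0.12)

    def test_zero_phase_output_same_length_and_aligned(self):
        sig = tone(0.8, duration=30.0)
        out = lowpass_filter(sig)
        assert len(out) == len(sig)
        # peak of the filtered tone stays at the same sample as the input's
        i_in = np.argmax(sig.values[:int(FS)])
        i_out = np.argmax(out.values[:int(FS)])
        assert abs(int(i_in) - int(i_out)) <= 1

    def test_linearity(self, rng):
        x = ChewSignal(rng.normal(size=900), FS)
        y = ChewSignal(rng.normal(size=900), FS)
        lhs = lowpass_filter(ChewSignal(2.0 * x.values + 3.0 * y.values, FS)).values
        rhs = 2.0 * lowpass_filter(x).values + 3.0 * lowpass_filter(y).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_peak_count_stable_for_clean_inband_tone(self):
        sig = tone(1.2, duration=20.0)
        before = len(find_local_maxima(sig.values))
        after = len(find_local_maxima(lowpass_filter(sig).values))
        assert before == after

    def test_resample_path(self):
        out = lowpass_filter(tone(0.5), LpfSpec(resample_hz=50.0))
        assert out.fps == 50.0
        assert dft_amplitude(out.values, 0.5, 50.0) == pytest.approx(1.0, abs=0.12)

    def test_passband_beyond_nyquist_rejected(self):
        with pytest.raises(InvalidSpecError):
            lowpass_filter(tone(0.5), LpfSpec(passband_hz=20.0))

    def test_designed_taps_are_symmetric_linear_phase(self):
        taps = design_lowpass_fir(LpfSpec(), FS)
        assert len(taps) % 2 == 1
        np.testing.assert_allclose(taps, taps[::-1])


class TestDwdDecompose:
    def test_perfect_reconstruction(self, rng):
        for _ in range(10):
            n = int(rng.integers(200, 2000))
            x = rng.normal(size=n)
            res = dwd_decompose(ChewSignal(x, FS), DwdSpec(levels=3))
            np.testing.assert_allclose(res.reconstruct(), x, rtol=1e-8, atol=1e-10)

    def test_energy_conservation_orthogonal_transform(self, rng):
        # exact orthogonality needs the length divisible by 2^levels
        # (periodized transform pads odd-length levels otherwise)
        x = rng.normal(size=1600)
        res = dwd_decompose(ChewSignal(x, FS), DwdSpec(levels=4))
        coeff_energy = sum(float((c ** 2).sum()) for c in [res.approximation, *res.details])
        assert coeff_energy == pytest.approx(float((x ** 2).sum()), rel=1e-10)

    def test_effective_rate_and_band(self):
        res = dwd_decompose(tone(0.5), DwdSpec(levels=3))
        assert res.effective_rate_hz == pytest.approx(3.75)
        assert res.approximation_band_hz == (0.0, pytest.approx(1.875))

    def test_low_tone_energy_stays_in_approximation(self):
        res = dwd_decompose(tone(0.5), DwdSpec(levels=3))
        approx_energy = float((res.approximation ** 2).sum())
        total = approx_energy + sum(float((d ** 2).sum()) for d in res.details)
        assert approx_energy / total >= 0.90

    def test_wavelet_filter_has_four_taps(self):
        import pywt

        assert pywt.Wavelet(DwdSpec().wavelet).dec_len == 4

    def test_too_short_signal_rejected(self):
        with pytest.raises(InvalidSpecError):
            dwd_decompose(ChewSignal(np.ones(8), FS), DwdSpec(levels=6))

    def test_detail_ordering_finest_first(self):
        res = dwd_decompose(tone(0.5), DwdSpec(levels=3))
        assert len(res.details) == 3
        assert len(res.details[0]) > len(res.details[-1])

    def test_reconstruct_approximation_is_bandlimited_projection(self):
        mix = ChewSignal(tone(0.5).values + tone(10.0).values, FS)
        res = dwd_decompose(mix, DwdSpec(levels=3))
        recon = reconstruct_approximation(res)
        assert len(recon) == len(mix)
        assert dft_amplitude(recon, 10.0, FS) < 0.1
        assert dft_amplitude(recon, 0.5, FS) > 0.8


class TestSelectDwdLevels:
    @pytest.mark.parametrize("fps,speed,expected", [
        (30.0, "normal", 3),
        (60.0, "normal", 4),
        (30.0, "slow", 4),
        (30.0, "fast", 2),
        (50.0, "slow", 5),
    ])
    def test_level_table(self, fps, speed, expected):
        assert select_dwd_levels(fps, speed) == expected

    def test_band_edge_property(self):
        # smallest L whose approximation edge is at or below the band edge
        for speed, edge in DEFAULT_SPEED_BANDS.items():
            for fps in (24.0, 30.0, 50.0, 60.0):
                L = select_dwd_levels(fps, speed)
                assert fps / 2 ** (L + 1) <= edge
                assert L == 1 or fps / 2 ** L > edge

    def test_unknown_speed_rejected(self):
        with pytest.raises(InvalidSpecError):
            select_dwd_levels(30.0, "frantic")
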