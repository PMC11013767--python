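"""Preprocessing chain tests: range processing, demodulation, filtering,
windowing, and the end-to-end displacement -> phase -> window round trip."""

import warnings

import numpy as np
import pytest

from radarhrv import preproc as pp
from radarhrv import vitalsim as vs


def _tone(f, fs, n, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * f * np.arange(n) / fs + phase)


def _fine_argmax(x, fs, fmin=0.05):
    n = 1 << 18
    spec = np.abs(np.fft.rfft(x - x.mean(), n=n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sel = freqs >= fmin
    return float(freqs[sel][np.argmax(spec[sel])])


class TestRangeProcessing:
    def test_tone_concentrates_in_one_bin(self):
        n_fast = 32
        t = np.arange(n_fast)
        row = np.exp(1j * 2 * np.pi * 5 * t / n_fast)
        cube = pp.RangeCube(np.tile(row, (10, 1)), frame_rate=100.0)
        spec = pp.range_fft(cube)
        mag = np.abs(spec.data).mean(axis=0)
        assert np.argmax(mag) == 5
        assert mag[5] > 100 * np.partition(mag, -2)[-2] or \
            np.partition(mag, -2)[-2] < 1e-9

    def test_parseval(self, rng):
        cube = pp.RangeCube(rng.standard_normal((6, 64))
                            + 1j * rng.standard_normal((6, 64)), 100.0)
        spec = pp.range_fft(cube)
        t_pow = np.sum(np.abs(cube.data) ** 2, axis=1)
        f_pow = np.sum(np.abs(spec.data) ** 2, axis=1) / 64
        np.testing.assert_allclose(t_pow, f_pow, rtol=1e-10)

    def test_zero_cube_zero_spectrum(self):
        spec = pp.range_fft(pp.RangeCube(np.zeros((4, 16)), 100.0))
        assert np.all(spec.data == 0)

    def test_too_few_fast_time_samples_error(self):
        with pytest.raises(ValueError):
            pp.range_fft(pp.RangeCube(np.ones((4, 1)), 100.0))

    def test_select_vibrating_bin(self):
        # one vibrating scatterer at bin 5, a stronger static one at bin 8
        disp = _tone(1.0, 20.0, 600, amp=0.5)
        cube = pp.synthetic_range_cube(disp, fs=20.0, target_bin=5,
                                       static_bins={8: 3.0}, seed=0)
        spec = pp.range_fft(cube)
        assert pp.select_range_bin(spec, k=3) == 5

    def test_single_strong_scatterer_found(self):
        disp = _tone(1.0, 20.0, 600, amp=0.5)
        cube = pp.synthetic_range_cube(disp, fs=20.0, target_bin=6, seed=1)
        assert pp.select_range_bin(pp.range_fft(cube), k=3) == 6

    def test_k1_degenerates_to_magnitude_argmax(self):
        disp = _tone(1.0, 20.0, 600, amp=0.2)
        cube = pp.synthetic_range_cube(disp, fs=20.0, target_bin=4,
                                       static_bins={7: 5.0}, seed=2)
        # with k=1 only the strongest magnitude peak is considered
        assert pp.select_range_bin(pp.range_fft(cube), k=1) == 7

    def test_no_peak_in_valid_range_error(self):
        cube = pp.RangeCube(np.zeros((10, 32), dtype=complex), 20.0,
                            range_res_m=0.2)
        spec = pp.range_fft(cube)
        with pytest.raises(ValueError):
            pp.select_range_bin(spec, k=2)


class TestDemodulation:
    def test_quadrature_convention(self):
        # I = sin(phi), Q = cos(phi); phi = 0 gives I=0, Q=1
        iq = pp.IqSeries(np.array([0.0]), np.array([1.0]), 100.0)
        assert pp.arctan_demodulate(iq).phase[0] == pytest.approx(0.0)

    def test_full_circle_recovery(self):
        phi = np.linspace(-np.pi + 0.01, np.pi, 100)
        iq = pp.IqSeries(np.sin(phi), np.cos(phi), 100.0)
        np.testing.assert_allclose(pp.arctan_demodulate(iq).phase, phi,
                                   atol=1e-12)

    def test_output_range(self, rng):
        iq = pp.IqSeries(rng.standard_normal(500), rng.standard_normal(500),
                         100.0)
        ph = pp.arctan_demodulate(iq).phase
        assert np.all(ph > -np.pi) and np.all(ph <= np.pi)

    def test_pure_rotation_is_sawtooth(self):
        # e^{j 2 pi t}: wrapped phase ramps and wraps once per second
        fs, n = 100.0, 300
        t = np.arange(n) / fs
        iq = pp.IqSeries(np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), fs)
        ph = pp.arctan_demodulate(iq).phase
        wraps = np.sum(np.diff(ph) < -np.pi)
        assert wraps == 3

    def test_literal_two_quadrant_folds(self):
        phi = np.array([2.0])  # outside (-pi/2, pi/2]
        iq = pp.IqSeries(np.sin(phi), np.cos(phi), 100.0)
        lit = pp.arctan_demodulate(iq, literal_two_quadrant=True).phase[0]
        assert -np.pi / 2 < lit < np.pi / 2
        assert lit != pytest.approx(2.0)

    def test_zero_magnitude_error_lists_indices(self):
        iq = pp.IqSeries(np.array([1.0, 0.0]), np.array([0.0, 0.0]), 100.0)
        with pytest.raises(ValueError, match="1"):
            pp.arctan_demodulate(iq)


class TestUnwrapAndFilters:
    def test_unwrap_recovers_ramp(self):
        ramp = np.linspace(0, 6 * np.pi, 500)
        wrapped = np.angle(np.exp(1j * ramp))
        p = pp.PhaseSeries(wrapped, 100.0)
        rec = pp.unwrap_phase(p).phase
        offset = rec[0] - ramp[0]
        np.testing.assert_allclose(rec - offset, ramp, atol=1e-9)
        assert (offset / (2 * np.pi)) == pytest.approx(
            round(offset / (2 * np.pi)), abs=1e-9)

    def test_unwrap_smooth_unchanged(self):
        smooth = 0.3 * np.sin(np.linspace(0, 4, 200))
        p = pp.PhaseSeries(smooth, 100.0)
        np.testing.assert_array_equal(pp.unwrap_phase(p).phase, smooth)

    def test_unwrap_flag_guard(self):
        p = pp.PhaseSeries(np.zeros(10), 100.0, unwrapped=True)
        with pytest.raises(ValueError):
            pp.unwrap_phase(p)

    def test_large_displacement_round_trip(self):
        # 12-mm breathing at 77 GHz spans ~6 two-way wavelengths; wrapping
        # then unwrapping must recover it to < 1% RMS
        lam = vs.wavelength_mm(77e9)
        disp = 12.0 * np.sin(2 * np.pi * 0.3 * np.arange(1000) / 100.0)
        rec = vs.displacement_to_phase(vs.VitalRecord(disp, 100, 10), lam)
        wrapped = np.angle(np.exp(1j * rec.samples))
        unwrapped = pp.unwrap_phase(pp.PhaseSeries(wrapped, 100.0)).phase
        back = unwrapped * lam / (4 * np.pi)
        back -= back.mean() - disp.mean()
        rms = np.sqrt(np.mean((back - disp) ** 2))
        assert rms / 12.0 < 0.01

    def test_bandpass_rejects_respiratory_tone(self):
        fs, n = 100.0, 4000
        x = _tone(0.2, fs, n)
        p = pp.bandpass(pp.PhaseSeries(x, fs))
        att = 20 * np.log10(np.std(x[500:-500]) / np.std(p.phase[500:-500]))
        assert att >= 20.0

    def test_bandpass_passes_cardiac_tone(self):
        fs, n = 100.0, 4000
        x = _tone(1.2, fs, n)
        p = pp.bandpass(pp.PhaseSeries(x, fs))
        gain = 20 * np.log10(np.std(p.phase[500:-500])
                             / np.std(x[500:-500]))
        assert abs(gain) <= 1.0

    def test_bandpass_removes_dc(self):
        p = pp.bandpass(pp.PhaseSeries(np.full(2000, 3.7), 100.0))
        assert np.max(np.abs(p.phase)) < 1e-6

    def test_bandpass_bad_cutoffs(self):
        with pytest.raises(ValueError):
            pp.bandpass(pp.PhaseSeries(np.zeros(100), 100.0), low=20.0,
                        high=10.0)

    def test_differentiate_tone_amplitude(self):
        fs = 100.0
        x = _tone(1.0, fs, 2000)
        d = pp.differentiate(pp.PhaseSeries(x, fs)).phase
        assert np.max(np.abs(d[10:-10])) == pytest.approx(2 * np.pi, rel=1e-2)

    def test_differentiate_constant_is_zero(self):
        d = pp.differentiate(pp.PhaseSeries(np.full(100, 2.0), 100.0)).phase
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_resample_halves_length(self):
        p = pp.PhaseSeries(_tone(1.0, 200.0, 800), 200.0)
        out = pp.resample_to(p, 100.0)
        assert out.phase.size == 400
        assert out.fs == 100.0
        assert _fine_argmax(out.phase, 100.0) == pytest.approx(1.0, abs=0.01)

    def test_resample_identity(self):
        p = pp.PhaseSeries(_tone(1.0, 100.0, 400), 100.0)
        out = pp.resample_to(p, 100.0)
        np.testing.assert_array_equal(out.phase, p.phase)

    def test_upsample_rejected(self):
        p = pp.PhaseSeries(np.zeros(100), 100.0)
        with pytest.raises(ValueError):
            pp.resample_to(p, 200.0)

    def test_normalize_example(self):
        p = pp.normalize_unit(pp.PhaseSeries(np.array([-3.0, 0.0, 3.0]),
                                             100.0))
        np.testing.assert_allclose(p.phase, [0.0, 0.5, 1.0])

    def test_normalize_idempotent_and_affine_invariant(self, rng):
        x = rng.standard_normal(200)
        a = pp.normalize_unit(pp.PhaseSeries(x, 100.0)).phase
        b = pp.normalize_unit(pp.PhaseSeries(3.5 * x + 11.0, 100.0)).phase
        np.testing.assert_allclose(a, b, atol=1e-12)
        again = pp.normalize_unit(pp.PhaseSeries(a, 100.0)).phase
        np.testing.assert_allclose(again, a, atol=1e-12)

    def test_normalize_constant_error(self):
        with pytest.raises(ValueError):
            pp.normalize_unit(pp.PhaseSeries(np.ones(10), 100.0))


class TestWindowing:
    def test_counting_formula(self):
        p = pp.PhaseSeries(np.zeros(1000), 100.0)  # 10 s
        wins = pp.window_stream(p, window_s=4.0, stride_s=0.05)
        assert len(wins) == 121
        assert all(w.samples.size == 400 for w in wins)

    def test_stride_equals_window_partitions(self):
        p = pp.PhaseSeries(np.arange(1200, dtype=float), 100.0)
        wins = pp.window_stream(p, window_s=4.0, stride_s=4.0)
        assert len(wins) == 3
        np.testing.assert_array_equal(wins[1].samples,
                                      np.arange(400, 800, dtype=float))

    def test_exact_length_single_window(self):
        p = pp.PhaseSeries(np.zeros(400), 100.0)
        assert len(pp.window_stream(p)) == 1

    def test_short_signal_warns_empty(self):
        p = pp.PhaseSeries(np.zeros(100), 100.0)
        with pytest.warns(UserWarning):
            wins = pp.window_stream(p)
        assert wins == []


class TestEndToEnd:
    def test_round_trip_recovers_heart_rate(self):
        """Displacement -> radar phase -> wrap -> unwrap -> band-pass ->
        differentiate -> window: spectral argmax matches the simulated rate.

        Uses a clean jitter-free heartbeat record so the spectral truth is
        unambiguous.
        """
        lam = vs.wavelength_mm(77e9)
        hp = vs.HeartbeatParams(0.5, 1.25, interval_jitter_ms=0.0)
        heart = vs.simulate_heartbeat(hp, 100, 30, seed=4)
        phase = vs.displacement_to_phase(heart, lam)
        wrapped = np.angle(np.exp(1j * phase.samples))
        p = pp.unwrap_phase(pp.PhaseSeries(wrapped, 100.0))
        p = pp.differentiate(pp.bandpass(p))
        # search the cardiac band: differentiation deliberately tilts the
        # spectrum upward, so the global argmax may sit on a pulse harmonic
        x = p.phase[200:-200] - p.phase[200:-200].mean()
        n = 1 << 18
        spec = np.abs(np.fft.rfft(x, n=n))
        freqs = np.fft.rfftfreq(n, 0.01)
        sel = (freqs >= 0.5) & (freqs <= 2.0)
        est = float(freqs[sel][np.argmax(spec[sel])])
        assert est == pytest.approx(1.25, abs=0.05)

    def test_stages_deterministic(self):
        x = _tone(1.1, 100.0, 800) + 0.3 * _tone(0.3, 100.0, 800)
        out1 = pp.preprocess_window(x[:400], 100.0)
        out2 = pp.preprocess_window(x[:400], 100.0)
        np.testing.assert_array_equal(out1, out2)

    def test_time_shift_commutes_up_to_edges(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.standard_normal(6000)) * 0.01
        p = pp.PhaseSeries(x, 100.0)
        full = pp.differentiate(pp.bandpass(p)).phase
        shifted = pp.differentiate(
            pp.bandpass(pp.PhaseSeries(x[1000:], 100.0))).phase
        # interior samples agree; edges differ by filter transients whose
        # tails at the 0.67-Hz corner extend a few hundred samples
        scale = np.std(full[2500:3500])
        np.testing.assert_allclose(full[2500:3500] / scale,
                                   shifted[1500:2500] / scale, atol=1e-3)
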