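"""Pulse synthesis, peak-to-peak metrics, deconvolution and correlations."""
import numpy as np
import pytest

from thzskin import (
    FrequencyGrid,
    PulseSeries,
    PulseTrace,
    ReflectanceSpectrum,
    attenuation_curve,
    deconvolved_response,
    frequency_attenuation_summary,
    peak_to_peak,
    per_frequency_correlation,
    synthesize_pulse,
)
from thzskin.errors import DomainError, UndefinedCorrelationError
from thzskin.signal import align, pulse_spectrum


def flat_reflectance(reference: PulseTrace, value: complex) -> ReflectanceSpectrum:
    grid = FrequencyGrid.from_sampling(1024, reference.dt_ps)
    return ReflectanceSpectrum(grid, np.full(len(grid), value, dtype=complex))


def series_from(reference, *amplitudes):
    taus = np.arange(len(amplitudes), dtype=float)
    return PulseSeries(taus, reference.times_ps, np.vstack(amplitudes))


class TestSynthesizePulse:
    def test_perfect_mirror_returns_reference(self, reference):
        out = synthesize_pulse(flat_reflectance(reference, 1.0), reference)
        np.testing.assert_allclose(out.amplitude_mv, reference.amplitude_mv, atol=1e-12)

    def test_scalar_reflector_scales_and_inverts(self, reference):
        out = synthesize_pulse(flat_reflectance(reference, -0.5), reference)
        np.testing.assert_allclose(out.amplitude_mv, -0.5 * reference.amplitude_mv, atol=1e-12)

    def test_frequency_flat_reflectance_scales_p2p(self, reference):
        r = interface = -0.32886
        out = synthesize_pulse(flat_reflectance(reference, interface), reference)
        assert peak_to_peak(out) == pytest.approx(abs(r) * peak_to_peak(reference), rel=1e-9)

    def test_parseval_consistency(self, reference):
        r = flat_reflectance(reference, 0.5 - 0.2j)
        out = synthesize_pulse(r, reference)
        _, ref_spec = pulse_spectrum(reference, 1024)
        _, out_spec = pulse_spectrum(out, 1024)
        expected = np.sum(np.abs(r.r * ref_spec) ** 2)
        assert np.sum(np.abs(out_spec) ** 2) == pytest.approx(expected, rel=1e-9)


class TestPeakToPeak:
    def test_constant_trace_is_zero(self):
        trace = PulseTrace(np.arange(10.0), np.full(10, 3.3))
        assert peak_to_peak(trace) == 0.0

    def test_unit_sine_is_two(self):
        t = np.linspace(0, 2 * np.pi, 1000)
        assert peak_to_peak(PulseTrace(t, np.sin(t))) == pytest.approx(2.0, abs=1e-4)

    def test_homogeneity(self, reference):
        scaled = PulseTrace(reference.times_ps, -3.0 * reference.amplitude_mv)
        assert peak_to_peak(scaled) == pytest.approx(3.0 * peak_to_peak(reference))


class TestAttenuationCurve:
    def test_identical_traces_give_constant_curve(self, reference):
        s = series_from(reference, reference.amplitude_mv, reference.amplitude_mv)
        _, p2p = attenuation_curve(s)
        assert p2p[0] == pytest.approx(p2p[1])

    def test_single_trace_series(self, reference):
        s = series_from(reference, reference.amplitude_mv)
        taus, p2p = attenuation_curve(s)
        assert len(taus) == len(p2p) == 1


class TestDeconvolvedResponse:
    def test_identity(self, reference):
        m = deconvolved_response(reference, reference)
        np.testing.assert_allclose(m.M[m.valid], 1.0, atol=1e-9)

    def test_pure_delay_has_unit_magnitude_linear_phase(self, reference):
        k = 40
        delayed = PulseTrace(reference.times_ps, np.roll(reference.amplitude_mv, k))
        m = deconvolved_response(delayed, reference)
        band = m.valid & (m.grid.values > 0.2) & (m.grid.values < 1.0)
        np.testing.assert_allclose(np.abs(m.M[band]), 1.0, atol=1e-6)
        phase = np.unwrap(np.angle(m.M[m.valid]))
        slopes = np.diff(phase) / np.diff(m.grid.values[m.valid])
        band2 = (m.grid.values[m.valid] > 0.2) & (m.grid.values[m.valid] < 1.0)
        np.testing.assert_allclose(
            slopes[band2[1:]], -2 * np.pi * k * reference.dt_ps, rtol=1e-3
        )

    def test_round_trip_recovers_reflectance(self, stack_config, reference):
        from thzskin.forward import stack_reflectance

        grid = FrequencyGrid.from_sampling(1024, reference.dt_ps)
        r = stack_reflectance(stack_config, grid, V_A1=0.5)
        sample = synthesize_pulse(r, reference)
        m = deconvolved_response(sample, reference)
        band = m.valid & (m.grid.values >= 0.2) & (m.grid.values <= 1.5)
        np.testing.assert_allclose(m.M[band], r.r[band], atol=1e-6)

    def test_weak_reference_bins_are_masked_not_divided(self, reference):
        m = deconvolved_response(reference, reference)
        assert not m.valid.all()
        np.testing.assert_array_equal(m.M[~m.valid], 0.0)


class TestFrequencyAttenuationSummary:
    def test_static_series_is_all_zero(self, reference):
        s = series_from(reference, reference.amplitude_mv, reference.amplitude_mv)
        _, delta, pct = frequency_attenuation_summary(s, reference)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)
        np.testing.assert_allclose(pct, 0.0, atol=1e-9)

    def test_scalar_scaling_gives_uniform_percentage(self, reference):
        s = series_from(reference, reference.amplitude_mv, 0.9 * reference.amplitude_mv)
        _, _, pct = frequency_attenuation_summary(s, reference)
        np.testing.assert_allclose(pct, -10.0, atol=1e-6)

    def test_single_trace_rejected(self, reference):
        s = series_from(reference, reference.amplitude_mv)
        with pytest.raises(DomainError):
            frequency_attenuation_summary(s, reference)


class TestPerFrequencyCorrelation:
    def _noisy_series(self, reference, scales):
        return series_from(reference, *[s * reference.amplitude_mv for s in scales])

    def test_identical_series_correlate_perfectly(self, reference):
        s = self._noisy_series(reference, [1.0, 0.9, 0.8, 0.7])
        r = per_frequency_correlation(s, s, reference, [0.3, 0.6, 1.0])
        np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_affine_transform_invariance(self, reference):
        a = self._noisy_series(reference, [1.0, 0.9, 0.8, 0.7])
        b = self._noisy_series(reference, [0.8, 0.75, 0.7, 0.65])
        r = per_frequency_correlation(a, b, reference, [0.5])
        assert r[0] == pytest.approx(1.0, abs=1e-9)

    def test_anti_correlated_pair(self, reference):
        a = self._noisy_series(reference, [1.0, 0.9, 0.8])
        b = self._noisy_series(reference, [0.8, 0.9, 1.0])
        r = per_frequency_correlation(a, b, reference, [0.5])
        assert r[0] == pytest.approx(-1.0, abs=1e-9)

    def test_too_few_taus_rejected(self, reference):
        a = self._noisy_series(reference, [1.0, 0.9])
        with pytest.raises(UndefinedCorrelationError):
            per_frequency_correlation(a, a, reference, [0.5])


class TestAlign:
    def test_alignment_undoes_integer_shift(self, reference):
        shifted = PulseTrace(reference.times_ps, np.roll(reference.amplitude_mv, 17))
        back = align(shifted, reference)
        core = slice(30, len(reference) - 30)
        np.testing.assert_allclose(
            back.amplitude_mv[core], reference.amplitude_mv[core], atol=1e-10
        )
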