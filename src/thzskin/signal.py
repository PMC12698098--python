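"""Time-domain pulses and the frequency-domain analysis quantities.

A simulated occlusion pulse is the reference pulse filtered by the stack
reflectance: E_sim(t) = F⁻¹[r(f)·E_ref(f)].  Analysis follows the raw-signal
philosophy: peak-to-peak attenuation in time, and the *unfiltered*
deconvolved response M(f) = E_sample(f)/E_ref(f) in frequency, with the
usable band taken as 0.2–1.5 THz.  No window functions or spectral filters
are applied anywhere; the only concession to numerics is a magnitude floor on
the reference spectrum below which M is flagged invalid rather than divided.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dielectrics import FrequencyGrid
from .errors import DomainError, GridMismatchError, UndefinedCorrelationError
from .fresnel import ReflectanceSpectrum

__all__ = [
    "PulseTrace",
    "PulseSeries",
    "FrequencyResponse",
    "DEFAULT_BAND_THZ",
    "synthesize_pulse",
    "peak_to_peak",
    "attenuation_curve",
    "align",
    "deconvolved_response",
    "frequency_attenuation_summary",
    "per_frequency_correlation",
]

#: High signal-to-noise analysis band, THz.
DEFAULT_BAND_THZ = (0.2, 1.5)

_UNIFORMITY_RTOL = 1e-9


@dataclass(frozen=True)
class PulseTrace:
    """A time-domain THz waveform on a uniform grid (times ps, amplitude mV)."""

    times_ps: np.ndarray
    amplitude_mv: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ps, dtype=float)
        a = np.asarray(self.amplitude_mv, dtype=float)
        if t.ndim != 1 or t.size < 2 or a.shape != t.shape:
            raise DomainError("trace needs matching 1-D times and amplitudes, length >= 2")
        steps = np.diff(t)
        if np.any(steps <= 0) or np.max(np.abs(steps - steps[0])) > _UNIFORMITY_RTOL * steps[0]:
            raise DomainError("time grid must be uniform and increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise DomainError("trace values must be finite")
        object.__setattr__(self, "times_ps", t)
        object.__setattr__(self, "amplitude_mv", a)

    @property
    def dt_ps(self) -> float:
        return float(self.times_ps[1] - self.times_ps[0])

    def __len__(self) -> int:
        return self.times_ps.size

    def same_grid(self, other: "PulseTrace") -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.times_ps, other.times_ps, rtol=1e-9, atol=1e-12)
        )


@dataclass(frozen=True)
class PulseSeries:
    """Traces indexed by compression time τ (seconds), sharing one time grid."""

    taus_s: np.ndarray
    times_ps: np.ndarray
    amplitudes_mv: np.ndarray  # shape (n_tau, n_t)

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus_s, dtype=float)
        t = np.asarray(self.times_ps, dtype=float)
        amps = np.asarray(self.amplitudes_mv, dtype=float)
        if taus.ndim != 1 or taus.size < 1:
            raise DomainError("series needs at least one tau")
        if np.any(np.diff(taus) <= 0) and taus.size > 1:
            raise DomainError("taus must be strictly increasing")
        if amps.shape != (taus.size, t.size):
            raise DomainError("amplitudes must have shape (n_tau, n_times)")
        object.__setattr__(self, "taus_s", taus)
        object.__setattr__(self, "times_ps", t)
        object.__setattr__(self, "amplitudes_mv", amps)

    def __len__(self) -> int:
        return self.taus_s.size

    def trace(self, i: int) -> PulseTrace:
        return PulseTrace(self.times_ps, self.amplitudes_mv[i])


@dataclass(frozen=True)
class FrequencyResponse:
    """Deconvolved complex response M per grid frequency, with validity mask."""

    grid: FrequencyGrid
    M: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.M).shape != self.grid.values.shape:
            raise GridMismatchError("M length does not match grid")
        if np.asarray(self.valid).shape != self.grid.values.shape:
            raise GridMismatchError("validity mask length does not match grid")


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def pulse_spectrum(trace: PulseTrace, nfft: int | None = None):
    """One-sided FFT of a trace; returns (FrequencyGrid in THz, complex spectrum)."""
    nfft = nfft or _next_pow2(len(trace))
    spec = np.fft.rfft(trace.amplitude_mv, nfft)
    return FrequencyGrid.from_sampling(nfft, trace.dt_ps), spec


def synthesize_pulse(
    r: ReflectanceSpectrum, reference: PulseTrace, nfft: int | None = None
) -> PulseTrace:
    """Simulated time-domain pulse: inverse transform of r(f)·E_ref(f).

    If the reflectance grid is exactly the reference's FFT grid it is used
    directly; otherwise it is linearly interpolated (real and imaginary parts
    separately), and a grid that would require extrapolation is an error.
    """
    grid, ref_spec = pulse_spectrum(reference, nfft)
    nfft = 2 * (len(grid) - 1)
    if r.grid.matches(grid):
        rf = r.r
    else:
        f = grid.values
        if f[0] < r.grid.values[0] - 1e-12 or f[-1] > r.grid.values[-1] + 1e-12:
            raise GridMismatchError(
                "reflectance grid does not cover the reference spectrum; "
                "extrapolation refused"
            )
        rf = np.interp(f, r.grid.values, r.r.real) + 1j * np.interp(
            f, r.grid.values, r.r.imag
        )
    out = np.fft.irfft(rf * ref_spec, nfft)[: len(reference)]
    return PulseTrace(reference.times_ps, out)


def peak_to_peak(trace: PulseTrace) -> float:
    """max − min of the amplitude, in mV."""
    return float(np.max(trace.amplitude_mv) - np.min(trace.amplitude_mv))


def attenuation_curve(series: PulseSeries):
    """The occlusion curve: (taus in s, peak-to-peak per trace in mV)."""
    p2p = series.amplitudes_mv.max(axis=1) - series.amplitudes_mv.min(axis=1)
    return series.taus_s.copy(), p2p


def align(moving: PulseTrace, target: PulseTrace) -> PulseTrace:
    """Shift ``moving`` by the integer lag maximising cross-correlation with
    ``target``; vacated samples are zero-filled."""
    if not moving.same_grid(target):
        raise GridMismatchError("alignment requires a shared time grid")
    xc = np.correlate(target.amplitude_mv, moving.amplitude_mv, mode="full")
    lag = int(np.argmax(xc)) - (len(moving) - 1)
    out = np.zeros_like(moving.amplitude_mv)
    if lag >= 0:
        out[lag:] = moving.amplitude_mv[: len(moving) - lag]
    else:
        out[:lag] = moving.amplitude_mv[-lag:]
    return PulseTrace(moving.times_ps, out)


def aligned_squared_error(a: PulseTrace, b: PulseTrace) -> float:
    """Squared L2 norm of the pointwise difference after integer-lag alignment."""
    shifted = align(a, b)
    return float(np.sum((shifted.amplitude_mv - b.amplitude_mv) ** 2))


def deconvolved_response(
    sample: PulseTrace,
    reference: PulseTrace,
    nfft: int | None = None,
    floor_fraction: float = 0.01,
) -> FrequencyResponse:
    """M(f) = E_sample(f) / E_ref(f), unfiltered.

    Frequencies where the reference magnitude falls below
    ``floor_fraction × max|E_ref|`` are flagged invalid (mask False) and M is
    set to 0 there instead of dividing by near-zero.
    """
    if not sample.same_grid(reference):
        raise GridMismatchError("sample and reference must share one time grid")
    grid, ref_spec = pulse_spectrum(reference, nfft)
    _, sam_spec = pulse_spectrum(sample, nfft)
    floor = floor_fraction * np.max(np.abs(ref_spec))
    valid = np.abs(ref_spec) >= floor
    M = np.zeros_like(ref_spec)
    np.divide(sam_spec, ref_spec, out=M, where=valid)
    return FrequencyResponse(grid, M, valid)


def band_indices(grid: FrequencyGrid, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return np.flatnonzero((grid.values >= lo) & (grid.values <= hi))


def frequency_attenuation_summary(
    series: PulseSeries,
    reference: PulseTrace,
    band: tuple[float, float] = DEFAULT_BAND_THZ,
    nfft: int | None = None,
):
    """Per-frequency change of |M| from the first to the last τ over a band.

    Returns (frequencies THz, Δ|M| absolute, Δ|M| in percent of the first).
    """
    if len(series) < 2:
        raise DomainError("need at least two traces to compute a change")
    m_first = deconvolved_response(series.trace(0), reference, nfft)
    m_last = deconvolved_response(series.trace(len(series) - 1), reference, nfft)
    idx = band_indices(m_first.grid, band)
    idx = idx[m_first.valid[idx] & m_last.valid[idx]]
    a0 = np.abs(m_first.M[idx])
    a1 = np.abs(m_last.M[idx])
    delta = a1 - a0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * delta / a0
    return m_first.grid.values[idx], delta, pct


def _abs_m_vs_tau(series: PulseSeries, reference: PulseTrace, nfft: int | None):
    """|M| as a (n_tau, n_freq) matrix, plus the FFT grid and validity mask."""
    grid, ref_spec = pulse_spectrum(reference, nfft)
    nfft_eff = 2 * (len(grid) - 1)
    floor = 0.01 * np.max(np.abs(ref_spec))
    valid = np.abs(ref_spec) >= floor
    spec = np.fft.rfft(series.amplitudes_mv, nfft_eff, axis=1)
    absM = np.zeros_like(spec, dtype=float)
    np.divide(np.abs(spec), np.abs(ref_spec)[None, :], out=absM, where=valid[None, :])
    return grid, absM, valid


def per_frequency_correlation(
    simulated: PulseSeries,
    measured: PulseSeries,
    reference: PulseTrace,
    frequencies_thz,
    nfft: int | None = None,
) -> np.ndarray:
    """Pearson r between simulated and measured |M|(τ) at chosen frequencies.

    Each requested frequency is mapped to the nearest FFT bin.
    """
    if len(simulated) != len(measured) or not np.allclose(
        simulated.taus_s, measured.taus_s, rtol=1e-9, atol=1e-12
    ):
        raise GridMismatchError("simulated and measured series must share tau grids")
    if len(simulated) < 3:
        raise UndefinedCorrelationError("Pearson correlation needs >= 3 tau points")
    grid, abs_sim, _ = _abs_m_vs_tau(simulated, reference, nfft)
    _, abs_meas, _ = _abs_m_vs_tau(measured, reference, nfft)
    out = np.empty(len(np.atleast_1d(frequencies_thz)))
    for k, f in enumerate(np.atleast_1d(frequencies_thz)):
        i = int(np.argmin(np.abs(grid.values - f)))
        a, b = abs_sim[:, i], abs_meas[:, i]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            # constant attenuation track: correlation defined only for the
            # degenerate identical case
            out[k] = 1.0 if np.allclose(a, b, rtol=1e-12, atol=1e-15) else np.nan
        else:
            out[k] = stats.pearsonr(a, b).statistic
    return out
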