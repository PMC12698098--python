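"""Synthetic occlusion measurements with known ground truth.

Emulates a 90 s window-contact measurement at ~12 pulses/s: a band-limited
single-cycle reference pulse, a monotonically decreasing deformation
trajectory V_A1(τ) with a fast exponential phase followed by a slow
quasi-linear phase (the elastic-then-viscous creep shape), and additive white
Gaussian amplitude noise.  Every generated series returns the exact
trajectory used, so parameter-recovery experiments need no external data.
"""
from __future__ import annotations

import numpy as np
import pydantic

from .errors import ConfigurationError, DomainError
from .forward import simulate_pulse
from .ridge_stack import StackConfig
from .signal import PulseSeries, PulseTrace, peak_to_peak

__all__ = ["OcclusionScenario", "make_reference_pulse", "va1_trajectory", "generate_series"]


class OcclusionScenario(pydantic.BaseModel):
    """Conditions of one synthetic occlusion measurement.

    ``va1_end`` is the asymptote of the exponential phase; the defaults are
    chosen so the realized trajectory runs from 0.57 at contact to ≈0.38 at
    90 s (a total change of ≈0.19) with a visible quasi-linear tail.
    """

    model_config = pydantic.ConfigDict(extra="forbid")

    duration_s: float = pydantic.Field(default=90.0, gt=0)
    rate_hz: float = pydantic.Field(default=12.0, gt=0)
    va1_start: float = pydantic.Field(default=0.57, ge=0.0, le=1.0)
    va1_end: float = pydantic.Field(default=0.398, ge=0.0, le=1.0)
    decay_time_s: float = pydantic.Field(default=15.0, gt=0)
    linear_slope_per_s: float = pydantic.Field(default=2.0e-4, ge=0.0)
    noise_sd_mv: float = pydantic.Field(default=0.002, ge=0.0)
    seed: int = 0

    @pydantic.model_validator(mode="after")
    def _ordered(self) -> "OcclusionScenario":
        if self.va1_end > self.va1_start:
            raise ValueError("va1_end must be <= va1_start (skin flattens under load)")
        return self

    @classmethod
    def validated(cls, **kwargs) -> "OcclusionScenario":
        try:
            return cls(**kwargs)
        except pydantic.ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc


def make_reference_pulse(
    centre_freq_thz: float = 0.5,
    bandwidth_thz: float = 0.5,
    n_samples: int = 1024,
    dt_ps: float = 0.1,
    seed: int = 0,
    p2p_mv: float = 1.0,
) -> PulseTrace:
    """Band-limited single-cycle reference pulse.

    Constructed in the frequency domain as an odd Gaussian band centred on
    ``centre_freq_thz`` (``bandwidth_thz`` is the FWHM of the magnitude
    spectrum) with linear phase placing the pulse a quarter of the way into
    the window, then normalised to the requested peak-to-peak amplitude.
    Fully deterministic; ``seed`` is accepted for interface symmetry with the
    noisy generators.
    """
    del seed  # deterministic construction
    if min(centre_freq_thz, bandwidth_thz, n_samples, dt_ps, p2p_mv) <= 0:
        raise DomainError("all reference-pulse parameters must be positive")
    f = np.fft.rfftfreq(n_samples, dt_ps)
    sigma = bandwidth_thz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    mag = np.exp(-((f - centre_freq_thz) ** 2) / (2 * sigma**2)) - np.exp(
        -((f + centre_freq_thz) ** 2) / (2 * sigma**2)
    )
    t0 = 0.25 * n_samples * dt_ps
    spec = mag * np.exp(-2j * np.pi * f * t0)
    amp = np.fft.irfft(spec, n_samples)
    amp *= p2p_mv / (amp.max() - amp.min())
    return PulseTrace(np.arange(n_samples) * dt_ps, amp)


def va1_trajectory(scenario: OcclusionScenario, tau_s):
    """Ground-truth deformation parameter at compression time τ (s).

    V_A1(τ) = va1_end + (va1_start − va1_end)·exp(−τ/decay_time) − slope·τ,
    clipped to [0, 1]; monotone non-increasing for valid scenarios.
    """
    tau = np.asarray(tau_s, dtype=float)
    if np.any(tau < 0) or np.any(tau > scenario.duration_s):
        raise DomainError(f"tau must lie in [0, {scenario.duration_s}] s")
    v = (
        scenario.va1_end
        + (scenario.va1_start - scenario.va1_end) * np.exp(-tau / scenario.decay_time_s)
        - scenario.linear_slope_per_s * tau
    )
    out = np.clip(v, 0.0, 1.0)
    return float(out) if np.isscalar(tau_s) else out


def generate_series(
    scenario: OcclusionScenario,
    stack_config: StackConfig,
    reference: PulseTrace,
    nfft: int | None = None,
):
    """Simulate the full occlusion measurement.

    Returns ``(PulseSeries, ground_truth_va1)``: one pulse per acquisition
    instant on the rate grid, each synthesised at the trajectory's V_A1 and
    perturbed by seeded white Gaussian noise of sd ``noise_sd_mv``.
    """
    n_pulses = int(round(scenario.duration_s * scenario.rate_hz))
    taus = np.arange(n_pulses) / scenario.rate_hz
    truth = va1_trajectory(scenario, taus)
    rng = np.random.default_rng(scenario.seed)
    amps = np.empty((n_pulses, len(reference)))
    for i, v in enumerate(truth):
        sim = simulate_pulse(stack_config, reference, V_A1=float(v), nfft=nfft)
        amps[i] = sim.amplitude_mv
    if scenario.noise_sd_mv > 0:
        amps += rng.normal(0.0, scenario.noise_sd_mv, size=amps.shape)
    return PulseSeries(taus, reference.times_ps.copy(), amps), truth


def series_snr_db(series: PulseSeries, noise_sd_mv: float) -> float:
    """Signal-band SNR of a generated series (P2P of the first trace over noise sd)."""
    if noise_sd_mv <= 0:
        return float("inf")
    return float(20.0 * np.log10(peak_to_peak(series.trace(0)) / noise_sd_mv))
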