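"""Forward model glue: config + reference pulse → simulated pulse.

Builds the ridge stack on the exact FFT grid of the reference trace so the
reflectance needs no interpolation, then filters the reference through it.
"""
from __future__ import annotations

import numpy as np

from .dielectrics import FrequencyGrid
from .fresnel import ReflectanceSpectrum, recursive_reflectance
from .ridge_stack import StackConfig, build_stack
from .signal import PulseTrace, _next_pow2, synthesize_pulse

__all__ = ["stack_reflectance", "simulate_pulse"]


def stack_reflectance(
    config: StackConfig,
    grid: FrequencyGrid,
    *,
    V_A1: float | None = None,
    d_f_um: float | None = None,
    L: int | None = None,
) -> ReflectanceSpectrum:
    """Reflectance of the configured stack on an arbitrary frequency grid."""
    stack = build_stack(config, grid, V_A1=V_A1, d_f_um=d_f_um, L=L)
    return recursive_reflectance(
        stack, angle=config.incidence_angle_rad, polarization=config.polarization
    )


def simulate_pulse(
    config: StackConfig,
    reference: PulseTrace,
    *,
    V_A1: float | None = None,
    d_f_um: float | None = None,
    L: int | None = None,
    nfft: int | None = None,
) -> PulseTrace:
    """Simulated time-domain reflection of the reference off the skin stack."""
    nfft = nfft or _next_pow2(len(reference))
    grid = FrequencyGrid(np.fft.rfftfreq(nfft, reference.dt_ps))
    r = stack_reflectance(config, grid, V_A1=V_A1, d_f_um=d_f_um, L=L)
    return synthesize_pulse(r, reference, nfft)
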