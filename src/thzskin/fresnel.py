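"""Reflectance of the stratified stack.

Two independent routes to the same quantity:

* :func:`recursive_reflectance` — the recursive single-interface relation
  r_i = (r_{i,i+1} + r_{i+1}·e^{−2jδ_{i+1}}) / (1 + r_{i,i+1}·r_{i+1}·e^{−2jδ_{i+1}})
  evaluated bottom-up from the deepest interface;
* :func:`transfer_matrix_reflectance` — 2×2 characteristic-matrix products,
  kept as an independent cross-check of the recursion.

Both use the package convention e^{+jωt}, Im(ε) ≤ 0, Im(n) ≤ 0, under which
the round-trip phase factor is e^{−2jδ} with δ = (2π/λ)·n·d·cosθ the complex
phase thickness of the layer being traversed, and the factor decays in lossy
media.  Oblique incidence uses the complex Snell invariant k_x = n₀·sinθ₀.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dielectrics import SPEED_OF_LIGHT_UM_PS, FrequencyGrid
from .errors import GridMismatchError, StackUsageError
from .ridge_stack import Layer, RidgeStack

__all__ = [
    "ReflectanceSpectrum",
    "interface_coefficient",
    "phase_thickness",
    "recursive_reflectance",
    "transfer_matrix_reflectance",
]

_PASSIVE_R_TOL = 1e-9


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Complex reflection coefficient of a stack per grid frequency."""

    grid: FrequencyGrid
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=complex)
        if r.shape != self.grid.values.shape:
            raise GridMismatchError("reflectance array length does not match grid")
        if np.any(np.abs(r) > 1.0 + _PASSIVE_R_TOL):
            raise StackUsageError("|r| > 1: stack is not passive under this convention")
        object.__setattr__(self, "r", r)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "frequency_THz": self.grid.values,
                "r_real": self.r.real,
                "r_imag": self.r.imag,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReflectanceSpectrum":
        df = pd.read_csv(path)
        return cls(
            FrequencyGrid(df["frequency_THz"].to_numpy()),
            df["r_real"].to_numpy() + 1j * df["r_imag"].to_numpy(),
        )


def _index(eps) -> np.ndarray:
    """√ε on the branch Im(n) ≤ 0 (decay into loss)."""
    n = np.sqrt(np.asarray(eps, dtype=complex))
    return np.where(n.imag > 0, -n, n)


def _cos_theta(n: np.ndarray, kx) -> np.ndarray:
    """cosθ inside a medium of index n for transverse invariant kx.

    Branch fixed so Im(n·cosθ) ≤ 0 (transmitted wave decays); for lossless
    propagating waves this reduces to the positive real root.
    """
    ct = np.sqrt(1.0 - (np.asarray(kx, dtype=complex) / n) ** 2)
    q = n * ct
    flip = (q.imag > 1e-15) | ((np.abs(q.imag) <= 1e-15) & (q.real < 0))
    return np.where(flip, -ct, ct)


def _admittance(n: np.ndarray, ct: np.ndarray, polarization: str) -> np.ndarray:
    if polarization == "s":
        return n * ct
    if polarization == "p":
        return n / ct
    raise StackUsageError(f"polarization must be 's' or 'p', got {polarization!r}")


def interface_coefficient(eps_a, eps_b, angle: float = 0.0, polarization: str = "s"):
    """Single-interface Fresnel reflection coefficient from medium a into b.

    ``angle`` is the incidence angle in medium *a* (radians).  Both
    polarizations use the admittance form r = (η_a − η_b)/(η_a + η_b), so s
    and p coincide at normal incidence, where r = (n_a − n_b)/(n_a + n_b).
    """
    na, nb = _index(eps_a), _index(eps_b)
    kx = na * math.sin(angle)
    ea = _admittance(na, _cos_theta(na, kx), polarization)
    eb = _admittance(nb, _cos_theta(nb, kx), polarization)
    return (ea - eb) / (ea + eb)


def phase_thickness(layer: Layer, frequency_thz, angle: float = 0.0, kx=None):
    """Complex phase thickness δ = (2π/λ)·n·d·cosθ of one finite layer.

    ``angle`` is the propagation angle *inside the layer*; alternatively pass
    the transverse Snell invariant ``kx`` (as used internally during the
    recursion) and the in-layer angle is derived from it.
    """
    if layer.is_half_space:
        raise StackUsageError("phase thickness is undefined for a half-space")
    f = np.asarray(frequency_thz, dtype=float)
    n = _index(layer.permittivity.eps)
    if kx is None:
        ct = np.cos(np.asarray(angle, dtype=complex))
    else:
        ct = _cos_theta(n, kx)
    return 2.0 * np.pi * f / SPEED_OF_LIGHT_UM_PS * n * layer.thickness_um * ct


def _stack_arrays(stack: RidgeStack):
    eps = [lay.permittivity.eps for lay in stack.layers]
    d = [lay.thickness_um for lay in stack.layers]
    return eps, d


def recursive_reflectance(
    stack: RidgeStack, angle: float = 0.0, polarization: str = "s"
) -> ReflectanceSpectrum:
    """Total reflection coefficient seen from the incidence medium.

    Evaluates the recursion bottom-up: the base case is the bare interface to
    the substrate half-space, then each finite layer above contributes its
    interface coefficient and round-trip phase e^{−2jδ}.
    """
    layers = stack.layers
    if len(layers) < 2:
        raise StackUsageError("reflectance needs at least two media")
    eps, d = _stack_arrays(stack)
    f = stack.grid.values
    n = [_index(e) for e in eps]
    kx = n[0] * math.sin(angle)
    ct = [_cos_theta(ni, kx) for ni in n]
    eta = [_admittance(ni, ci, polarization) for ni, ci in zip(n, ct)]

    m = len(layers)
    r = (eta[m - 2] - eta[m - 1]) / (eta[m - 2] + eta[m - 1])
    for i in range(m - 3, -1, -1):
        r_if = (eta[i] - eta[i + 1]) / (eta[i] + eta[i + 1])
        delta = 2.0 * np.pi * f / SPEED_OF_LIGHT_UM_PS * n[i + 1] * d[i + 1] * ct[i + 1]
        phase = np.exp(-2j * delta)
        r = (r_if + r * phase) / (1.0 + r_if * r * phase)
    return ReflectanceSpectrum(stack.grid, r)


def transfer_matrix_reflectance(
    stack: RidgeStack, angle: float = 0.0, polarization: str = "s"
) -> ReflectanceSpectrum:
    """Characteristic-matrix (Abelès) evaluation of the stack reflectance.

    Independent of the recursion: each finite layer contributes
    M = [[cosδ, −j·sinδ/η], [−j·η·sinδ, cosδ]] (signs per the package phase
    convention) and r = (η₀B − C)/(η₀B + C) with (B, C)ᵀ = ΠM·(1, η_s)ᵀ.
    """
    layers = stack.layers
    if len(layers) < 2:
        raise StackUsageError("reflectance needs at least two media")
    eps, d = _stack_arrays(stack)
    f = stack.grid.values
    n = [_index(e) for e in eps]
    kx = n[0] * math.sin(angle)
    ct = [_cos_theta(ni, kx) for ni in n]
    eta = [_admittance(ni, ci, polarization) for ni, ci in zip(n, ct)]

    B = np.ones_like(f, dtype=complex)
    C = np.array(eta[-1], dtype=complex) * np.ones_like(f, dtype=complex)
    for i in range(len(layers) - 2, 0, -1):
        delta = 2.0 * np.pi * f / SPEED_OF_LIGHT_UM_PS * n[i] * d[i] * ct[i]
        cd, sd = np.cos(delta), np.sin(delta)
        B, C = cd * B + 1j * sd / eta[i] * C, 1j * eta[i] * sd * B + cd * C
    r = (eta[0] * B - C) / (eta[0] * B + C)
    return ReflectanceSpectrum(stack.grid, r)
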