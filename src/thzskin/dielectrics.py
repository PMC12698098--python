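"""Frequency-dependent complex permittivities of the model's constituent materials.

The skin model treats every material as a complex relative permittivity
sampled on a common terahertz frequency grid: air and quartz are lossless
constants, liquid (bound) water follows a double-Debye dispersion, and skin
itself is a Landau–Lifshitz–Looyenga (LLL) effective medium of a "dry"
biological background and water at a depth-dependent hydration fraction.

Sign convention (used consistently across the whole package)
------------------------------------------------------------
Time dependence ``e^{+jωt}``; complex permittivity is written
``ε = ε' − jε''`` with ``ε'' ≥ 0`` for passive media, i.e. ``Im(ε) ≤ 0`` as a
Python complex number.  The refractive index ``n = √ε`` is taken on the
branch with ``Im(n) ≤ 0`` so that waves decay as they propagate into lossy
media.  This is the convention under which multiplying a numpy ``rfft``
spectrum by a reflection coefficient and inverting yields causal echoes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, GridMismatchError, InvalidMaterialError

__all__ = [
    "SPEED_OF_LIGHT_UM_PS",
    "FrequencyGrid",
    "MaterialSpectrum",
    "DebyeModel",
    "WATER_DOUBLE_DEBYE",
    "debye_permittivity",
    "water_permittivity",
    "dry_background",
    "constant_material",
    "lll_mix",
    "skin_permittivity",
    "hydration_profile",
]

#: Speed of light in micrometres per picosecond (µm·THz).
SPEED_OF_LIGHT_UM_PS = 299.792458

_UNIFORMITY_RTOL = 1e-9
_PASSIVITY_ATOL = 1e-12


@dataclass(frozen=True)
class FrequencyGrid:
    """A uniform, strictly increasing grid of frequencies in THz."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise DomainError("frequency grid must be 1-D with at least 2 points")
        if arr[0] < 0:
            raise DomainError("frequency grid must be non-negative")
        steps = np.diff(arr)
        if np.any(steps <= 0):
            raise DomainError("frequency grid must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > _UNIFORMITY_RTOL * max(steps[0], 1.0):
            raise DomainError("frequency grid must be uniformly spaced")
        object.__setattr__(self, "values", arr)

    @property
    def df(self) -> float:
        """Grid spacing in THz."""
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def from_range(cls, f_min: float, f_max: float, n: int) -> "FrequencyGrid":
        return cls(np.linspace(f_min, f_max, n))

    @classmethod
    def from_sampling(cls, n_samples: int, dt_ps: float) -> "FrequencyGrid":
        """The one-sided FFT frequency grid of a real trace (dt in ps ⇒ f in THz)."""
        return cls(np.fft.rfftfreq(n_samples, dt_ps))

    def matches(self, other: "FrequencyGrid", rtol: float = 1e-9) -> bool:
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, rtol=rtol, atol=1e-12)
        )


@dataclass(frozen=True)
class MaterialSpectrum:
    """Complex relative permittivity of one material sampled on a grid.

    Passivity under the package convention requires ``Im(ε) ≤ 0`` at every
    frequency; this is validated on construction.
    """

    grid: FrequencyGrid
    eps: np.ndarray

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=complex)
        if eps.shape != self.grid.values.shape:
            raise GridMismatchError("permittivity array length does not match grid")
        if np.any(eps.imag > _PASSIVITY_ATOL):
            raise InvalidMaterialError(
                "passivity violated: Im(eps) must be <= 0 under the e^{+jwt} convention"
            )
        object.__setattr__(self, "eps", eps)

    @property
    def n(self) -> np.ndarray:
        """Complex refractive index √ε on the decaying branch (Im ≤ 0)."""
        n = np.sqrt(self.eps)
        return np.where(n.imag > 0, -n, n)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "frequency_THz": self.grid.values,
                "eps_real": self.eps.real,
                "eps_imag": self.eps.imag,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MaterialSpectrum":
        df = pd.read_csv(path)
        grid = FrequencyGrid(df["frequency_THz"].to_numpy())
        return cls(grid, df["eps_real"].to_numpy() + 1j * df["eps_imag"].to_numpy())


@dataclass(frozen=True)
class DebyeModel:
    """A multi-term Debye relaxation model.

    ε(f) = ε_inf + Σ_k Δε_k / (1 + j·2πf·τ_k), with Δε dimensionless and τ in
    picoseconds.  Under the package sign convention the imaginary part of each
    term is negative (loss).
    """

    eps_inf: float
    terms: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        terms = tuple((float(d), float(t)) for d, t in self.terms)
        object.__setattr__(self, "terms", terms)
        if not terms and self.eps_inf <= 0:
            raise InvalidMaterialError(
                "Debye model with no relaxation terms requires eps_inf > 0"
            )
        for d, t in terms:
            if d < 0:
                raise InvalidMaterialError(f"Debye strength must be >= 0, got {d}")
            if t <= 0:
                raise InvalidMaterialError(f"Debye relaxation time must be > 0, got {t}")


#: Literature double-Debye parameters for liquid water at skin temperature
#: (slow reorientational term plus a fast sub-ps term).  Overridable wherever
#: a water model is accepted.
WATER_DOUBLE_DEBYE = DebyeModel(eps_inf=3.3, terms=((75.0, 8.24), (1.6, 0.18)))


def debye_permittivity(model: DebyeModel, grid: FrequencyGrid) -> MaterialSpectrum:
    """Evaluate a Debye model on a frequency grid.

    Static limit f→0 gives ε_inf + ΣΔε; optical limit f→∞ gives ε_inf.
    """
    f = grid.values
    eps = np.full_like(f, model.eps_inf, dtype=complex)
    for delta, tau in model.terms:
        eps = eps + delta / (1.0 + 2j * np.pi * f * tau)
    return MaterialSpectrum(grid, eps)


def water_permittivity(grid: FrequencyGrid, model: DebyeModel | None = None) -> MaterialSpectrum:
    """Double-Debye water permittivity (default literature parameters)."""
    return debye_permittivity(model or WATER_DOUBLE_DEBYE, grid)


def dry_background(grid: FrequencyGrid, eps: float = 2.5) -> MaterialSpectrum:
    """Nondispersive real permittivity of the dry biological background."""
    if eps <= 0:
        raise InvalidMaterialError(f"dry background permittivity must be > 0, got {eps}")
    return MaterialSpectrum(grid, np.full(len(grid), eps, dtype=complex))


def constant_material(n: float, grid: FrequencyGrid) -> MaterialSpectrum:
    """Lossless nondispersive material of refractive index ``n`` (ε = n²)."""
    if n <= 0:
        raise InvalidMaterialError(f"refractive index must be > 0, got {n}")
    return MaterialSpectrum(grid, np.full(len(grid), n * n, dtype=complex))


def lll_mix(eps_a, eps_b, fraction_b: float):
    """Landau–Lifshitz–Looyenga two-phase mixing.

    ε_eff = ((1−v)·ε_a^{1/3} + v·ε_b^{1/3})³ with ``v = fraction_b`` the volume
    fraction of phase *b*.  Cube roots are principal-branch, which keeps
    passive inputs passive.  Accepts scalars or arrays elementwise.
    """
    if not 0.0 <= fraction_b <= 1.0:
        raise DomainError(f"volume fraction must be in [0, 1], got {fraction_b}")
    ca = np.asarray(eps_a, dtype=complex) ** (1.0 / 3.0)
    cb = np.asarray(eps_b, dtype=complex) ** (1.0 / 3.0)
    return ((1.0 - fraction_b) * ca + fraction_b * cb) ** 3


def skin_permittivity(
    hydration: float, water: MaterialSpectrum, dry: MaterialSpectrum
) -> MaterialSpectrum:
    """Skin as an LLL effective medium of dry background and bound water.

    ``hydration`` is the water volume fraction in [0, 1].
    """
    if not water.grid.matches(dry.grid):
        raise GridMismatchError("water and dry-background spectra must share one grid")
    eps = lll_mix(dry.eps, water.eps, hydration)
    # principal cube roots can leave Im at +0.0 round-off for real inputs
    eps = np.where(eps.imag > 0, eps.real + 1j * np.minimum(eps.imag, 0.0), eps)
    return MaterialSpectrum(water.grid, eps)


def hydration_profile(
    depth_um: float,
    total_ridge_height_um: float,
    surface_h: float = 0.20,
    bottom_h: float = 0.65,
    kind: str = "linear",
) -> float:
    """Water volume fraction at a given depth into the ridge layers.

    A monotone interpolant between the surface hydration (default 20%) and the
    hydration at the bottom of the deepest ridge layer (default 65%),
    consistent with Raman-measured stratum-corneum gradients.  ``kind`` is
    ``"linear"`` (default) or ``"cosine"`` for a smooth ramp with zero slope at
    both ends.
    """
    if not 0.0 <= surface_h <= bottom_h <= 1.0:
        raise DomainError("require 0 <= surface_h <= bottom_h <= 1")
    if total_ridge_height_um <= 0:
        raise DomainError("total ridge height must be > 0")
    if not 0.0 <= depth_um <= total_ridge_height_um:
        raise DomainError(
            f"depth {depth_um} um outside [0, {total_ridge_height_um}] um"
        )
    x = depth_um / total_ridge_height_um
    if kind == "linear":
        w = x
    elif kind == "cosine":
        w = 0.5 * (1.0 - np.cos(np.pi * x))
    else:
        raise DomainError(f"unknown hydration profile kind {kind!r}")
    return float(surface_h + (bottom_h - surface_h) * w)
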