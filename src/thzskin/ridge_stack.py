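"""The layered model of window-compressed skin.

From top to bottom: a quartz imaging window (the incidence medium), ``L``
"ridge layers" — thin slabs of equal thickness ``d_f`` that discretise the
skin's furrow-and-ridge topography as skin–air effective media — and a bulk
skin half-space.  The air volume fraction of ridge layer ``N`` follows a
squared-cosine profile anchored at ``V_A1`` in the first layer; the skin
component of each layer is hydrated according to a depth profile evaluated at
the layer's centre.  ``V_A1`` is the single deformation parameter: perfectly
flattened skin has ``V_A1 = 0``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pydantic

from .dielectrics import (
    FrequencyGrid,
    MaterialSpectrum,
    DebyeModel,
    constant_material,
    debye_permittivity,
    dry_background,
    hydration_profile,
    lll_mix,
    skin_permittivity,
)
from .errors import ConfigurationError, DomainError

__all__ = ["Layer", "RidgeStack", "StackConfig", "air_fraction_profile", "build_stack", "lll_mix"]

#: Thickness value marking a semi-infinite medium.
HALF_SPACE = math.inf


@dataclass(frozen=True)
class Layer:
    """One medium of the stratified system.

    ``thickness_um`` is ``math.inf`` for the two terminal half-spaces.
    """

    thickness_um: float
    permittivity: MaterialSpectrum
    label: str = ""

    @property
    def is_half_space(self) -> bool:
        return math.isinf(self.thickness_um)


@dataclass(frozen=True)
class RidgeStack:
    """Ordered media, incidence half-space first, bulk-skin half-space last."""

    layers: tuple[Layer, ...]
    L: int
    d_f_um: float
    V_A1: float

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ConfigurationError("a stack needs at least two media")
        if not self.layers[0].is_half_space or not self.layers[-1].is_half_space:
            raise ConfigurationError("first and last media must be half-spaces")
        for lay in self.layers[1:-1]:
            if not (lay.thickness_um >= 0 and math.isfinite(lay.thickness_um)):
                raise ConfigurationError("internal layers must have finite thickness >= 0")

    @property
    def grid(self) -> FrequencyGrid:
        return self.layers[0].permittivity.grid

    @property
    def total_ridge_height_um(self) -> float:
        return self.L * self.d_f_um


class StackConfig(pydantic.BaseModel):
    """Validated parameters of the layered model.

    Defaults follow the reference geometry: a 2 mm quartz window of index
    1.98, twelve ridge layers of 2.5 µm, hydration rising linearly from 20%
    at the surface to 65% at the bottom of the deepest ridge layer, normal
    incidence.
    """

    model_config = pydantic.ConfigDict(extra="forbid")

    quartz_n: float = pydantic.Field(default=1.98, gt=0)
    quartz_thickness_mm: float = pydantic.Field(default=2.0, gt=0)
    L: int = pydantic.Field(default=12, ge=1, le=30)
    d_f_um: float = pydantic.Field(default=2.5, gt=0)
    V_A1: float = pydantic.Field(default=0.5, ge=0.0, le=1.0)
    hydration_surface: float = pydantic.Field(default=0.20, ge=0.0, le=1.0)
    hydration_bottom: float = pydantic.Field(default=0.65, ge=0.0, le=1.0)
    hydration_profile_kind: str = "linear"
    incidence_angle_deg: float = pydantic.Field(default=0.0, ge=0.0, lt=90.0)
    polarization: str = "s"
    dry_eps: float = pydantic.Field(default=2.5, gt=0)
    water_eps_inf: float = pydantic.Field(default=3.3, gt=0)
    water_debye_terms: tuple[tuple[float, float], ...] = ((75.0, 8.24), (1.6, 0.18))
    #: include the quartz window as a finite layer under an air incidence
    #: half-space instead of treating quartz as the incidence medium
    include_quartz_layer: bool = False
    #: optional CSV (frequency_THz, eps_real, eps_imag) for measured bulk skin
    bulk_skin_csv: str | None = None

    @pydantic.model_validator(mode="after")
    def _check_hydration_order(self) -> "StackConfig":
        if self.hydration_surface > self.hydration_bottom:
            raise ValueError("hydration_surface must be <= hydration_bottom")
        if self.polarization not in ("s", "p"):
            raise ValueError("polarization must be 's' or 'p'")
        return self

    @property
    def incidence_angle_rad(self) -> float:
        return math.radians(self.incidence_angle_deg)

    @classmethod
    def validated(cls, **kwargs) -> "StackConfig":
        """Construct, re-raising pydantic errors as ConfigurationError."""
        try:
            return cls(**kwargs)
        except pydantic.ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc


def air_fraction_profile(V_A1: float, L: int) -> np.ndarray:
    """Air volume fraction of ridge layers 1..L.

    V_A^N = V_A1 · cos²((N−1)·π / (2L)): the first layer carries the full
    deformation parameter and the fraction decays over a quarter period so the
    deepest layer approaches (without being forced to) zero.  Non-increasing
    for any valid inputs.
    """
    if not 0.0 <= V_A1 <= 1.0:
        raise DomainError(f"V_A1 must be in [0, 1], got {V_A1}")
    if L < 1:
        raise DomainError(f"L must be >= 1, got {L}")
    n = np.arange(1, L + 1)
    return V_A1 * np.cos((n - 1) * np.pi / (2 * L)) ** 2


def build_stack(
    config: StackConfig,
    grid: FrequencyGrid,
    *,
    V_A1: float | None = None,
    d_f_um: float | None = None,
    L: int | None = None,
) -> RidgeStack:
    """Assemble the layered system on a frequency grid.

    Keyword overrides allow sweeping ``V_A1``, ``d_f`` and ``L`` without
    re-validating a full config (they are validated here instead).
    """
    va1 = config.V_A1 if V_A1 is None else float(V_A1)
    d_f = config.d_f_um if d_f_um is None else float(d_f_um)
    n_layers = config.L if L is None else int(L)
    if not 0.0 <= va1 <= 1.0:
        raise ConfigurationError(f"V_A1 must be in [0, 1], got {va1}")
    if d_f <= 0:
        raise ConfigurationError(f"d_f_um must be > 0, got {d_f}")
    if n_layers < 1:
        raise ConfigurationError(f"L must be >= 1, got {n_layers}")

    water = debye_permittivity(
        DebyeModel(config.water_eps_inf, config.water_debye_terms), grid
    )
    dry = dry_background(grid, config.dry_eps)
    air = constant_material(1.0, grid)
    quartz = constant_material(config.quartz_n, grid)

    total = n_layers * d_f
    fractions = air_fraction_profile(va1, n_layers)

    layers: list[Layer] = []
    if config.include_quartz_layer:
        layers.append(Layer(HALF_SPACE, air, "air (incidence)"))
        layers.append(Layer(config.quartz_thickness_mm * 1000.0, quartz, "quartz window"))
    else:
        # the probe references off the quartz–skin boundary; the window's own
        # front-face echo is separated in time and removed upstream
        layers.append(Layer(HALF_SPACE, quartz, "quartz (incidence)"))

    for N in range(1, n_layers + 1):
        centre = (N - 0.5) * d_f
        h = hydration_profile(
            centre,
            total,
            config.hydration_surface,
            config.hydration_bottom,
            config.hydration_profile_kind,
        )
        skin_n = skin_permittivity(h, water, dry)
        eps_eff = lll_mix(skin_n.eps, air.eps, fractions[N - 1])
        eps_eff = np.where(eps_eff.imag > 0, eps_eff.real + 0j, eps_eff)
        layers.append(
            Layer(d_f, MaterialSpectrum(grid, eps_eff), f"ridge layer {N}")
        )

    if config.bulk_skin_csv is not None:
        measured = MaterialSpectrum.from_csv(config.bulk_skin_csv)
        eps_bulk = np.interp(grid.values, measured.grid.values, measured.eps.real) + 1j * np.interp(
            grid.values, measured.grid.values, measured.eps.imag
        )
        bulk = MaterialSpectrum(grid, eps_bulk)
    else:
        bulk = skin_permittivity(config.hydration_bottom, water, dry)
    layers.append(Layer(HALF_SPACE, bulk, "bulk skin"))

    return RidgeStack(tuple(layers), L=n_layers, d_f_um=d_f, V_A1=va1)
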