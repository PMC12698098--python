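"""Robustness analysis selecting the number of ridge layers L.

For a chosen total ridge height d, the THz signal is simulated for every
combination of V_A1 (M grid values) and layer count L (N values, with
d_f = d/L), and the squared-L2 error against a measured pulse fills an
[M, N] error matrix.  A per-L robustness metric combines the mean and
standard deviation of each column (both max-normalised so the two terms are
scale-free); L values scoring within a tolerance (default 5%) of the minimum
form the acceptable set.  Repeating over several ridge heights, the selected
L is the smallest value present in every acceptable set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, NoConsensusError
from .fitting import FitConfig, loss
from .forward import simulate_pulse
from .ridge_stack import StackConfig
from .signal import PulseTrace

__all__ = [
    "ErrorMatrix",
    "simulation_error",
    "build_error_matrix",
    "robustness_metric",
    "acceptable_set",
    "select_layer_count",
]

#: Physically sensible per-layer thickness range, µm.
LAYER_THICKNESS_RANGE_UM = (0.25, 100.0)

DEFAULT_VA1_GRID = np.linspace(0.0, 1.0, 10)
DEFAULT_LAYER_GRID = tuple(range(1, 16))
DEFAULT_RIDGE_HEIGHTS_UM = (15.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class ErrorMatrix:
    """Simulation errors over an M×N grid of (V_A1, L)."""

    va1_values: np.ndarray
    layer_counts: np.ndarray
    errors: np.ndarray  # shape (M, N)

    def __post_init__(self) -> None:
        va1 = np.asarray(self.va1_values, dtype=float)
        ls = np.asarray(self.layer_counts, dtype=int)
        err = np.asarray(self.errors, dtype=float)
        if err.shape != (va1.size, ls.size):
            raise DomainError("error matrix shape must be (len(va1), len(L))")
        if np.any(err < 0):
            raise DomainError("errors must be non-negative")
        object.__setattr__(self, "va1_values", va1)
        object.__setattr__(self, "layer_counts", ls)
        object.__setattr__(self, "errors", err)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.errors, index=self.va1_values, columns=self.layer_counts)


def simulation_error(
    stack_config: StackConfig,
    V_A1: float,
    L: int,
    d_um: float,
    measured: PulseTrace,
    reference: PulseTrace,
    nfft: int | None = None,
) -> float:
    """Squared-L2 error between the simulated and measured pulse.

    The L ridge layers share thickness d_f = d/L; traces are integer-lag
    aligned before differencing, so the error is invariant to a common shift.
    """
    d_f = d_um / L
    lo, hi = LAYER_THICKNESS_RANGE_UM
    if not lo <= d_f <= hi:
        raise DomainError(
            f"layer thickness d/L = {d_f:.3g} um outside the sensible range {LAYER_THICKNESS_RANGE_UM}"
        )
    sim = simulate_pulse(stack_config, reference, V_A1=V_A1, d_f_um=d_f, L=L, nfft=nfft)
    return loss(sim, measured)


def build_error_matrix(
    stack_config: StackConfig,
    va1_grid,
    layer_grid,
    d_um: float,
    measured: PulseTrace,
    reference: PulseTrace,
    nfft: int | None = None,
) -> ErrorMatrix:
    """Populate the [M, N] error matrix for one total ridge height."""
    va1_grid = np.asarray(va1_grid, dtype=float)
    layer_grid = np.asarray(layer_grid, dtype=int)
    if va1_grid.size == 0 or layer_grid.size == 0:
        raise DomainError("grids must be nonempty")
    err = np.empty((va1_grid.size, layer_grid.size))
    for j, L in enumerate(layer_grid):
        for i, v in enumerate(va1_grid):
            err[i, j] = simulation_error(
                stack_config, float(v), int(L), d_um, measured, reference, nfft
            )
    return ErrorMatrix(va1_grid, layer_grid, err)


def robustness_metric(matrix: ErrorMatrix, mean_weight: float = 0.5) -> np.ndarray:
    """Per-L metric combining column mean and standard deviation.

    metric(L) = w·mean_L/max(mean) + (1−w)·std_L/max(std); both terms are
    max-normalised so they are scale-free, and w defaults to equal weighting.
    Lower is better.
    """
    if not 0.0 <= mean_weight <= 1.0:
        raise DomainError("mean_weight must be in [0, 1]")
    means = matrix.errors.mean(axis=0)
    stds = matrix.errors.std(axis=0)
    mmax = means.max()
    smax = stds.max()
    mterm = means / mmax if mmax > 0 else np.zeros_like(means)
    sterm = stds / smax if smax > 0 else np.zeros_like(stds)
    return mean_weight * mterm + (1.0 - mean_weight) * sterm


def acceptable_set(layer_counts, metrics, tolerance: float = 0.05) -> set[int]:
    """Layer counts scoring within ``tolerance`` of the minimum metric."""
    metrics = np.asarray(metrics, dtype=float)
    layer_counts = np.asarray(layer_counts, dtype=int)
    if metrics.size == 0 or metrics.size != layer_counts.size:
        raise DomainError("metrics and layer counts must be nonempty and matched")
    cutoff = (1.0 + tolerance) * metrics.min()
    return {int(L) for L, m in zip(layer_counts, metrics) if m <= cutoff}


def select_layer_count(
    stack_config: StackConfig,
    d_values_um,
    measured: PulseTrace,
    reference: PulseTrace,
    va1_grid=DEFAULT_VA1_GRID,
    layer_grid=DEFAULT_LAYER_GRID,
    tolerance: float = 0.05,
    nfft: int | None = None,
    return_tables: bool = False,
):
    """Smallest L present in every ridge height's acceptable set.

    Raises :class:`NoConsensusError` (carrying the per-d sets) if the
    intersection is empty.  With ``return_tables=True`` also returns a
    per-height DataFrame of (L, mean, std, metric, accepted).
    """
    d_values_um = list(np.atleast_1d(np.asarray(d_values_um, dtype=float)))
    if not d_values_um:
        raise DomainError("need at least one total ridge height")
    per_d_sets: dict[float, set[int]] = {}
    tables: dict[float, pd.DataFrame] = {}
    for d in d_values_um:
        mat = build_error_matrix(
            stack_config, va1_grid, layer_grid, d, measured, reference, nfft
        )
        metric = robustness_metric(mat)
        acc = acceptable_set(mat.layer_counts, metric, tolerance)
        per_d_sets[d] = acc
        tables[d] = pd.DataFrame(
            {
                "L": mat.layer_counts,
                "mean_error": mat.errors.mean(axis=0),
                "std_error": mat.errors.std(axis=0),
                "metric": metric,
                "accepted": [int(L) in acc for L in mat.layer_counts],
            }
        )
    common = set.intersection(*per_d_sets.values())
    if not common:
        raise NoConsensusError(per_d_sets)
    selected = min(common)
    if return_tables:
        return selected, tables
    return selected
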