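"""Fitting the deformation parameter V_A1 to a measured pulse series.

Two-stage procedure: first the common ridge-layer thickness d_f is optimised
once with V_A1 held at 0.5 (bounds 2–10 µm); then, for every stride-selected
compression time τ, V_A1 ∈ [0, 1] is found by minimising the squared-L2 loss
between the simulated and measured pulse.  Both minimisations use seeded
Gaussian-process Bayesian optimization; successive τ fits are warm-started at
the previous optimum because the deformation trajectory is slowly varying.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pydantic

from ._bayesopt import minimize_scalar_gp
from .errors import ConfigurationError, DomainError
from .forward import simulate_pulse
from .ridge_stack import StackConfig
from .signal import PulseSeries, PulseTrace, align

__all__ = ["FitConfig", "FitResult", "loss", "optimize_df", "fit_va1_series", "loss_surface"]


class FitConfig(pydantic.BaseModel):
    """Optimizer settings and search bounds."""

    model_config = pydantic.ConfigDict(extra="forbid")

    va1_bounds: tuple[float, float] = (0.0, 1.0)
    df_bounds_um: tuple[float, float] = (2.0, 10.0)
    fit_stride: int = pydantic.Field(default=10, ge=1)
    n_initial: int = pydantic.Field(default=10, ge=1)
    n_iter: int = pydantic.Field(default=40, ge=0)
    seed: int = 0
    polish: bool = True
    warm_start: bool = True
    #: use the squared-signal loss Σ(E_sim² − E_meas²)² instead of the
    #: squared difference of the signals themselves (sensitivity check)
    squared_signal_loss: bool = False
    nfft: int | None = None

    @pydantic.model_validator(mode="after")
    def _ordered(self) -> "FitConfig":
        if self.va1_bounds[0] > self.va1_bounds[1] or self.df_bounds_um[0] > self.df_bounds_um[1]:
            raise ValueError("bounds must be ordered (lo, hi)")
        return self

    @classmethod
    def validated(cls, **kwargs) -> "FitConfig":
        try:
            return cls(**kwargs)
        except pydantic.ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc


@dataclass(frozen=True)
class FitResult:
    """Per-τ optimised deformation parameter plus diagnostics."""

    df_opt_um: float
    taus_s: np.ndarray
    va1: np.ndarray
    loss: np.ndarray
    rmse: np.ndarray
    n_evals: np.ndarray
    converged: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau_s": self.taus_s,
                "va1": self.va1,
                "loss": self.loss,
                "rmse_mV": self.rmse,
                "n_evals": self.n_evals,
                "converged": self.converged,
            }
        )


def loss(
    e_sim: PulseTrace, e_meas: PulseTrace, squared_signal: bool = False
) -> float:
    """Squared L2 norm of the difference between two pulses after alignment.

    With ``squared_signal=True`` the loss is Σ(E_sim² − E_meas²)² instead.
    """
    shifted = align(e_sim, e_meas)
    a, b = shifted.amplitude_mv, e_meas.amplitude_mv
    if squared_signal:
        return float(np.sum((a**2 - b**2) ** 2))
    return float(np.sum((a - b) ** 2))


def _trace_loss(
    stack_config: StackConfig,
    reference: PulseTrace,
    measured: PulseTrace,
    va1: float,
    d_f_um: float,
    fit: FitConfig,
) -> float:
    sim = simulate_pulse(stack_config, reference, V_A1=va1, d_f_um=d_f_um, nfft=fit.nfft)
    return loss(sim, measured, squared_signal=fit.squared_signal_loss)


def optimize_df(
    series: PulseSeries,
    reference: PulseTrace,
    stack_config: StackConfig,
    fit: FitConfig | None = None,
):
    """Optimised ridge-layer thickness d_f (µm), with V_A1 fixed at 0.5.

    The compression time at which the skin actually sits at the assumed
    mid-range deformation V_A1 = 0.5 is unknown, so it is profiled out: the
    objective for each candidate d_f is the *minimum* loss over the
    stride-selected pulses of the series.  When the deformation trajectory
    passes through 0.5 this removes the bias a fixed (e.g. first) pulse would
    imprint on d_f.  Returns (d_f_um, BOResult).
    """
    fit = fit or FitConfig()
    idx = np.arange(0, len(series), fit.fit_stride)
    traces = [series.trace(int(i)) for i in idx]

    def objective(d: float) -> float:
        sim = simulate_pulse(stack_config, reference, V_A1=0.5, d_f_um=d, nfft=fit.nfft)
        return min(loss(sim, m, squared_signal=fit.squared_signal_loss) for m in traces)

    res = minimize_scalar_gp(
        objective,
        fit.df_bounds_um,
        n_initial=fit.n_initial,
        n_iter=fit.n_iter,
        seed=fit.seed,
        polish=fit.polish,
    )
    return float(res.x), res


def fit_va1_series(
    series: PulseSeries,
    reference: PulseTrace,
    df_opt_um: float,
    stack_config: StackConfig,
    fit: FitConfig | None = None,
) -> FitResult:
    """Extract V_A1 at every stride-selected τ by loss minimisation."""
    fit = fit or FitConfig()
    lo, hi = fit.df_bounds_um
    if not lo <= df_opt_um <= hi:
        raise DomainError(f"df_opt {df_opt_um} um outside bounds {fit.df_bounds_um}")
    idx = np.arange(0, len(series), fit.fit_stride)
    taus, va1s, losses, rmses, nevals, convs = [], [], [], [], [], []
    x_prev = 0.5 * (fit.va1_bounds[0] + fit.va1_bounds[1])
    for k, i in enumerate(idx):
        measured = series.trace(int(i))
        res = minimize_scalar_gp(
            lambda v: _trace_loss(stack_config, reference, measured, v, df_opt_um, fit),
            fit.va1_bounds,
            n_initial=fit.n_initial,
            n_iter=fit.n_iter,
            seed=fit.seed + k,
            x0=x_prev if fit.warm_start else None,
            polish=fit.polish,
        )
        if fit.warm_start:
            x_prev = res.x
        taus.append(series.taus_s[i])
        va1s.append(res.x)
        losses.append(res.fun)
        rmses.append(np.sqrt(res.fun / len(measured)))
        nevals.append(res.n_evals)
        convs.append(res.converged)
    return FitResult(
        df_opt_um=float(df_opt_um),
        taus_s=np.asarray(taus),
        va1=np.asarray(va1s),
        loss=np.asarray(losses),
        rmse=np.asarray(rmses),
        n_evals=np.asarray(nevals),
        converged=np.asarray(convs, dtype=bool),
        seed=fit.seed,
    )


def loss_surface(
    trace: PulseTrace,
    reference: PulseTrace,
    df_opt_um: float,
    va1_grid,
    stack_config: StackConfig,
    fit: FitConfig | None = None,
) -> np.ndarray:
    """Loss at each V_A1 grid value — the identifiability diagnostic."""
    fit = fit or FitConfig()
    va1_grid = np.asarray(va1_grid, dtype=float)
    if va1_grid.size == 0:
        raise DomainError("va1 grid must be nonempty")
    return np.array(
        [_trace_loss(stack_config, reference, trace, v, df_opt_um, fit) for v in va1_grid]
    )
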