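"""One-dimensional Bayesian optimization with Gaussian processes.

A small, seeded GP/expected-improvement minimizer built on sklearn's
GaussianProcessRegressor: seeded uniform initial design (optionally including
a warm-start point), Matérn-5/2 + white-noise kernel, EI acquisition
maximised over a dense deterministic candidate grid.  GP hyperparameters are
re-optimised only every few iterations and frozen in between, which keeps the
per-evaluation overhead small without changing the search behaviour
appreciably.  An optional bounded local polish around the incumbent tightens
the final answer on smooth objectives.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = ["BOResult", "minimize_scalar_gp"]


@dataclass
class BOResult:
    x: float
    fun: float
    x_iters: list[float] = field(default_factory=list)
    fun_iters: list[float] = field(default_factory=list)
    n_evals: int = 0
    converged: bool = True
    message: str = ""


def _expected_improvement(mu, sd, y_best, xi):
    imp = y_best - mu - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, imp / np.where(sd > 0, sd, 1.0), 0.0)
        ei = np.where(sd > 0, imp * stats.norm.cdf(z) + sd * stats.norm.pdf(z), 0.0)
    return ei


def minimize_scalar_gp(
    func,
    bounds: tuple[float, float],
    *,
    n_initial: int = 10,
    n_iter: int = 40,
    seed: int = 0,
    x0: float | None = None,
    polish: bool = True,
    hyperopt_every: int = 5,
    n_candidates: int = 512,
) -> BOResult:
    """Minimise ``func`` on ``[lo, hi]``; deterministic for a fixed seed."""
    lo, hi = float(bounds[0]), float(bounds[1])
    if hi < lo:
        raise ValueError(f"bounds must be ordered, got {bounds}")
    if hi == lo:
        return BOResult(x=lo, fun=float(func(lo)), x_iters=[lo], n_evals=1,
                        message="degenerate bounds")

    rng = np.random.default_rng(seed)
    span = hi - lo
    xs: list[float] = []
    if x0 is not None:
        xs.append(float(np.clip(x0, lo, hi)))
    while len(xs) < max(2, n_initial):
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - x) > 1e-12 * span for x in xs):
            xs.append(cand)
    ys = [float(func(x)) for x in xs]

    kernel = ConstantKernel(1.0, (1e-4, 1e4)) * Matern(
        length_scale=0.2 * span,
        length_scale_bounds=(1e-3 * span, 10.0 * span),
        nu=2.5,
    ) + WhiteKernel(1e-8, (1e-14, 1e-2))
    fitted_kernel = kernel

    grid = np.linspace(lo, hi, n_candidates)
    for it in range(n_iter):
        X = np.asarray(xs)[:, None]
        y = np.asarray(ys)
        reoptimize = it % max(1, hyperopt_every) == 0
        gp = GaussianProcessRegressor(
            kernel=kernel if reoptimize else fitted_kernel,
            optimizer="fmin_l_bfgs_b" if reoptimize else None,
            normalize_y=True,
            alpha=1e-10,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(X, y)
        if reoptimize:
            fitted_kernel = gp.kernel_
        mu, sd = gp.predict(grid[:, None], return_std=True)
        y_best = float(np.min(y))
        xi = 0.01 * (float(np.max(y)) - y_best + 1e-12)
        ei = _expected_improvement(mu, sd, y_best, xi)
        # never resample an already-evaluated point
        taken = np.min(np.abs(grid[:, None] - np.asarray(xs)[None, :]), axis=1)
        ei[taken < 1e-9 * span] = -np.inf
        if np.all(~np.isfinite(ei)) or float(np.max(ei)) <= 0.0:
            x_next = float(rng.uniform(lo, hi))
        else:
            x_next = float(grid[int(np.argmax(ei))])
        xs.append(x_next)
        ys.append(float(func(x_next)))

    i_best = int(np.argmin(ys))
    x_best, f_best = xs[i_best], ys[i_best]
    n_evals = len(xs)

    if polish:
        w = 0.05 * span
        res = optimize.minimize_scalar(
            func,
            bounds=(max(lo, x_best - w), min(hi, x_best + w)),
            method="bounded",
            options={"xatol": 1e-6 * span},
        )
        n_evals += int(res.nfev)
        if res.fun <= f_best:
            x_best, f_best = float(res.x), float(res.fun)

    # non-convergence heuristic: meaningful improvement still arriving in the
    # final quarter of the BO budget
    tail = max(3, n_iter // 4)
    best_before_tail = float(np.min(ys[: len(ys) - tail])) if len(ys) > tail else f_best
    spread = float(np.max(ys) - np.min(ys)) + 1e-300
    converged = (best_before_tail - float(np.min(ys))) <= 0.05 * spread
    return BOResult(
        x=x_best,
        fun=f_best,
        x_iters=xs,
        fun_iters=ys,
        n_evals=n_evals,
        converged=converged,
        message="" if converged else "objective still improving at budget end",
    )
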