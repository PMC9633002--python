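"""Multi-start maximum-likelihood fitting of single-trace kinetic models.

Each dilution-compensated total-GFP trace is fitted independently by
bounded local optimization of the negative Gaussian log-likelihood in
log10 parameter space, started from Latin-hypercube-sampled points. If
fewer than ``min_converged`` starts end within ``convergence_tol`` log-
likelihood units of the best start, the number of starts is escalated
(20 -> 50 -> 100 -> 200 by default) before the trace is flagged as
non-converged. Profile likelihoods re-optimize all remaining parameters
on a grid of one parameter to assess identifiability.

Parameter bounds follow the fitting convention for 1e-7-rescaled
fluorescence: every initial/rate/noise parameter in log10 within [-10, 1];
the repression response delay within [-2, log10(2)] (36 s to 2 h).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from . import models
from .models import Theta, ThetaNoRepression, ThetaRepression
from .preprocessing import CompensatedTrace

__all__ = [
    "OptimizationConfig",
    "FitResult",
    "param_names",
    "default_bounds_log10",
    "lhs_starts",
    "assess_convergence",
    "fit_trace",
    "profile_likelihood",
]

ModelKind = Literal["repression", "no_repression"]
NoiseKind = Literal["constant", "timedep"]

_BOUNDS_GENERIC = (-10.0, 1.0)

# L-BFGS-B settings: tight tolerances so near-tied local optima (pure-decay
# vs. peak-shaped repression fits) are resolved, and a finite-difference
# step suited to log10-scaled parameters of magnitude O(1).
_LBFGSB_OPTIONS = dict(maxiter=1000, maxfun=20000, ftol=1e-12, gtol=1e-9,
                       eps=1e-6)
_BOUNDS_TDELAY = (-2.0, float(np.log10(2.0)))


def param_names(model_kind: ModelKind, noise_kind: NoiseKind) -> list[str]:
    """Ordered free-parameter names: 4/5 (constant) or 5/6 (timedep)."""
    if model_kind == "repression":
        names = ["GFP_0", "r_prod", "r_deg", "t_delay", "sigma"]
    elif model_kind == "no_repression":
        names = ["GFP_0", "r_basal", "r_deg", "sigma"]
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    if noise_kind == "timedep":
        names = names + ["Var_0"]
    elif noise_kind != "constant":
        raise ValueError(f"unknown noise_kind {noise_kind!r}")
    return names


def default_bounds_log10(model_kind: ModelKind,
                         noise_kind: NoiseKind) -> list[tuple[float, float]]:
    """log10 bounds per parameter, in :func:`param_names` order."""
    return [_BOUNDS_TDELAY if n == "t_delay" else _BOUNDS_GENERIC
            for n in param_names(model_kind, noise_kind)]


@dataclass(frozen=True)
class OptimizationConfig:
    """Knobs of the multi-start optimizer.

    ``n_starts_ladder`` lists cumulative start counts tried until at least
    ``min_converged`` starts agree with the best log-likelihood to within
    ``convergence_tol``.
    """

    bounds_log10: tuple[tuple[float, float], ...] | None = None
    n_starts_ladder: tuple[int, ...] = (20, 50, 100, 200)
    convergence_tol: float = 0.1
    min_converged: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.n_starts_ladder) != sorted(set(self.n_starts_ladder)):
            raise ValueError("n_starts_ladder must be strictly increasing")


@dataclass(frozen=True)
class FitResult:
    """Best fit of one model to one trace, with multistart diagnostics."""

    theta_hat: Theta
    logL: float
    model_kind: ModelKind
    noise_kind: NoiseKind
    n_starts_used: int
    n_converged: int
    converged_flag: bool
    all_start_logLs: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        """Number of fitted parameters."""
        return len(param_names(self.model_kind, self.noise_kind))


def lhs_starts(bounds_log10: Sequence[tuple[float, float]], n: int,
               seed: int | np.random.Generator) -> np.ndarray:
    """``n`` Latin-hypercube start vectors (log10 scale) within bounds.

    Each coordinate's ``n`` samples occupy ``n`` distinct equal-width
    strata of that coordinate's interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bounds = np.asarray(bounds_log10, dtype=float)
    if np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("lower bound exceeds upper bound")
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(bounds), rng=rng)
    unit = sampler.random(n)
    return qmc.scale(unit, bounds[:, 0], bounds[:, 1])


def _theta_from_vector(x_nat: np.ndarray, model_kind: ModelKind,
                       noise_kind: NoiseKind) -> Theta:
    d = dict(zip(param_names(model_kind, noise_kind), x_nat))
    if model_kind == "repression":
        return ThetaRepression(GFP_0=d["GFP_0"], r_prod=d["r_prod"],
                               r_deg=d["r_deg"], t_delay=d["t_delay"],
                               sigma=d["sigma"], Var_0=d.get("Var_0", 0.0))
    return ThetaNoRepression(GFP_0=d["GFP_0"], r_basal=d["r_basal"],
                             r_deg=d["r_deg"], sigma=d["sigma"],
                             Var_0=d.get("Var_0", 0.0))


def _make_objective(trace: CompensatedTrace, model_kind: ModelKind,
                    noise_kind: NoiseKind):
    """Fast negative log-likelihood in log10 space on raw arrays.

    Takes the full parameter vector in :func:`param_names` order.
    """
    y = np.asarray(trace.total_gfp, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    log2pi = np.log(2.0 * np.pi)
    n = len(y)
    repression = model_kind == "repression"
    timedep = noise_kind == "timedep"

    def negloglik_log10(x_log10: np.ndarray) -> float:
        p = 10.0 ** np.asarray(x_log10, dtype=float)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if repression:
                gfp0, r_prod, r_deg, t_delay, sigma = p[:5]
                mu = models._mean_rep_raw(t, gfp0, r_prod, r_deg, t_delay)
                if timedep:
                    var = sigma ** 2 + models._var_rep_raw(
                        t, gfp0, r_prod, r_deg, t_delay, p[5])
                else:
                    var = sigma ** 2
            else:
                gfp0, r_basal, r_deg, sigma = p[:4]
                mu = models._mean_norep_raw(t, gfp0, r_basal, r_deg)
                if timedep:
                    var = sigma ** 2 + models._var_norep_raw(
                        t, gfp0, r_basal, r_deg, p[4])
                else:
                    var = sigma ** 2
            val = 0.5 * np.sum(log2pi + np.log(var) + (y - mu) ** 2 / var) \
                if timedep else \
                0.5 * (n * (log2pi + np.log(var))
                       + np.sum((y - mu) ** 2) / var)
        return float(val) if np.isfinite(val) else 1e300

    return negloglik_log10


def _make_concentrated_objective(trace: CompensatedTrace,
                                 model_kind: ModelKind):
    """Constant-noise objective with sigma profiled out in closed form.

    For fixed mean parameters the constant-variance Gaussian likelihood is
    maximized by ``sigma_hat^2 = mean((y - mu)^2)``, giving the
    concentrated negative log-likelihood ``n/2 (log(2 pi sigma_hat^2)+1)``.
    Optimizing only the 3-4 mean parameters removes the pathological
    sigma dimension from the multistart search; the maximum is the same.
    Takes the parameter vector in :func:`param_names` order *without*
    sigma.
    """
    y = np.asarray(trace.total_gfp, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    log2pi = np.log(2.0 * np.pi)
    n = len(y)
    repression = model_kind == "repression"

    def negloglik_log10(x_log10: np.ndarray) -> float:
        p = 10.0 ** np.asarray(x_log10, dtype=float)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if repression:
                mu = models._mean_rep_raw(t, p[0], p[1], p[2], p[3])
            else:
                mu = models._mean_norep_raw(t, p[0], p[1], p[2])
            s2 = np.mean((y - mu) ** 2)
            val = 0.5 * n * (log2pi + np.log(s2) + 1.0)
        return float(val) if np.isfinite(val) else 1e300

    return negloglik_log10


def _make_concentrated_fungrad(trace: CompensatedTrace,
                               model_kind: ModelKind, eps: float = 1e-6):
    """Concentrated objective returning (value, forward-difference gradient).

    The value and all ``d`` perturbed evaluations are computed in a single
    broadcast pass over a ``(d+1, n_times)`` array, which is what makes the
    multistart affordable at cohort scale.
    """
    y = np.asarray(trace.total_gfp, dtype=float)
    t = np.asarray(trace.times, dtype=float)[None, :]
    log2pi = np.log(2.0 * np.pi)
    n = y.size
    repression = model_kind == "repression"
    d = 4 if repression else 3
    shifts = np.vstack([np.zeros(d), np.eye(d) * eps])

    def fungrad(x_log10: np.ndarray) -> tuple[float, np.ndarray]:
        X = np.asarray(x_log10, dtype=float)[None, :] + shifts
        p = 10.0 ** X
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if repression:
                mu = models._mean_rep_raw(t, p[:, 0:1], p[:, 1:2],
                                          p[:, 2:3], p[:, 3:4])
            else:
                mu = models._mean_norep_raw(t, p[:, 0:1], p[:, 1:2],
                                            p[:, 2:3])
            s2 = np.mean((y[None, :] - mu) ** 2, axis=1)
            vals = 0.5 * n * (log2pi + np.log(s2) + 1.0)
        vals = np.where(np.isfinite(vals), vals, 1e300)
        return float(vals[0]), (vals[1:] - vals[0]) / eps

    return fungrad


def assess_convergence(all_start_logLs, tol: float,
                       min_converged: int) -> tuple[int, bool]:
    """Count starts within ``tol`` of the best log-likelihood.

    Returns ``(n_converged, n_converged >= min_converged)``.
    """
    logLs = np.asarray(all_start_logLs, dtype=float)
    if logLs.size == 0:
        raise ValueError("empty log-likelihood list")
    finite = logLs[np.isfinite(logLs)]
    if finite.size == 0:
        return 0, False
    best = finite.max()
    n_conv = int(np.sum(best - finite < tol))
    return n_conv, n_conv >= min_converged


def derive_seed(master_seed: int, *tokens) -> int:
    """Stable per-item seed: crc32 of the tokens mixed with the master seed.

    Adding traces to a dataset never reshuffles the seeds of other traces.
    """
    key = "|".join(str(t) for t in tokens).encode()
    return (zlib.crc32(key) ^ (master_seed * 0x9E3779B1 & 0xFFFFFFFF)) % (2 ** 31)


def fit_trace(
    trace: CompensatedTrace,
    model_kind: ModelKind,
    noise_kind: NoiseKind = "constant",
    config: OptimizationConfig | None = None,
) -> FitResult:
    """Multi-start bounded MLE of one kinetic model on one trace.

    L-BFGS-B minimizes the negative log-likelihood in log10 space from
    Latin-hypercube starts, escalating the number of starts along
    ``config.n_starts_ladder`` until at least ``config.min_converged``
    starts lie within ``config.convergence_tol`` of the best. The fit is
    returned on the natural scale; a trace that exhausts the ladder keeps
    its best fit but carries ``converged_flag=False``.
    """
    if len(trace.times) == 0:
        raise ValueError("empty trace")
    config = config or OptimizationConfig()
    bounds_full = (list(config.bounds_log10)
                   if config.bounds_log10 is not None
                   else default_bounds_log10(model_kind, noise_kind))
    names = param_names(model_kind, noise_kind)
    concentrated = noise_kind == "constant"
    if concentrated:
        sigma_idx = names.index("sigma")
        opt_idx = [i for i in range(len(names)) if i != sigma_idx]
        bounds = [bounds_full[i] for i in opt_idx]
        objective = _make_concentrated_fungrad(trace, model_kind)
        use_jac = True
    else:
        bounds = bounds_full
        objective = _make_objective(trace, model_kind, noise_kind)
        use_jac = False
    seed = derive_seed(config.seed, trace.mother_id, trace.repression_label,
                       model_kind, noise_kind)
    rng = np.random.default_rng(seed)

    logLs: list[float] = []
    xs: list[np.ndarray] = []
    n_done = 0
    n_conv, flag = 0, False
    for n_target in config.n_starts_ladder:
        starts = lhs_starts(bounds, n_target - n_done, rng)
        for x0 in starts:
            res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                    jac=use_jac, bounds=bounds,
                                    options=_LBFGSB_OPTIONS)
            # one restart from the terminal point: resets the Hessian
            # memory and finite differences, completing descents that
            # stalled on the t_delay kink
            res2 = optimize.minimize(objective, res.x, method="L-BFGS-B",
                                     jac=use_jac, bounds=bounds,
                                     options=_LBFGSB_OPTIONS)
            if res2.fun < res.fun:
                res = res2
            logLs.append(-res.fun if np.isfinite(res.fun) else -np.inf)
            xs.append(res.x)
        n_done = n_target
        n_conv, flag = assess_convergence(logLs, config.convergence_tol,
                                          config.min_converged)
        if flag:
            break

    arr = np.asarray(logLs)
    if not np.any(np.isfinite(arr)):
        raise RuntimeError("all optimization starts failed numerically")
    best = int(np.argmax(arr))
    x_best = np.clip(xs[best], [b[0] for b in bounds], [b[1] for b in bounds])
    if concentrated:
        # reinsert the profiled sigma_hat, clipped into its bounds
        mu_obj = _make_objective(trace, model_kind, noise_kind)
        x_full = np.empty(len(names))
        x_full[opt_idx] = x_best
        p = 10.0 ** x_best
        if model_kind == "repression":
            mu = models._mean_rep_raw(trace.times, p[0], p[1], p[2], p[3])
        else:
            mu = models._mean_norep_raw(trace.times, p[0], p[1], p[2])
        s_hat = float(np.sqrt(np.mean((trace.total_gfp - mu) ** 2)))
        lo, hi = bounds_full[sigma_idx]
        x_full[sigma_idx] = np.clip(np.log10(max(s_hat, 1e-300)), lo, hi)
        best_logL = -mu_obj(x_full)
        x_best = x_full
    else:
        best_logL = float(arr[best])
    theta_hat = _theta_from_vector(10.0 ** x_best, model_kind, noise_kind)
    return FitResult(theta_hat=theta_hat, logL=best_logL,
                     model_kind=model_kind, noise_kind=noise_kind,
                     n_starts_used=n_done, n_converged=n_conv,
                     converged_flag=flag, all_start_logLs=arr)


def profile_likelihood(
    trace: CompensatedTrace,
    fit: FitResult,
    param_name: str,
    grid: Sequence[float],
    config: OptimizationConfig | None = None,
) -> np.ndarray:
    """Profile log-likelihood of one parameter along ``grid`` (natural scale).

    At each grid value the parameter is fixed and all others re-optimized,
    warm-started from the MLE (then from the previous grid point, sweeping
    outward from the value nearest the MLE). Failed points are NaN.
    """
    config = config or OptimizationConfig()
    names = param_names(fit.model_kind, fit.noise_kind)
    if param_name not in names:
        raise ValueError(f"unknown parameter {param_name!r}")
    idx = names.index(param_name)
    bounds_all = (list(config.bounds_log10)
                  if config.bounds_log10 is not None
                  else default_bounds_log10(fit.model_kind, fit.noise_kind))
    # under constant noise sigma is profiled out analytically, so the
    # vector seen by the optimizer omits it (unless sigma itself is the
    # profiled parameter)
    concentrated = fit.noise_kind == "constant" and param_name != "sigma"
    if concentrated:
        sigma_idx = names.index("sigma")
        vec_idx = [i for i in range(len(names)) if i != sigma_idx]
        objective_full = _make_concentrated_objective(trace, fit.model_kind)
    else:
        vec_idx = list(range(len(names)))
        objective_full = _make_objective(trace, fit.model_kind,
                                         fit.noise_kind)
    names = [names[i] for i in vec_idx]
    bounds_full = [bounds_all[i] for i in vec_idx]
    idx = names.index(param_name)
    free = [i for i in range(len(names)) if i != idx]
    bounds_free = [bounds_full[i] for i in free]
    x_mle = np.log10([getattr(fit.theta_hat, n) for n in names])

    grid = np.asarray(grid, dtype=float)
    profile = np.full(len(grid), np.nan)
    order = np.argsort(np.abs(np.log10(np.maximum(grid, 1e-300))
                              - x_mle[idx]))
    warm: dict[int, np.ndarray] = {}
    for rank, gi in enumerate(order):
        fixed_log10 = np.log10(max(grid[gi], 1e-300))

        def objective_free(x_free: np.ndarray) -> float:
            x = np.empty(len(names))
            x[free] = x_free
            x[idx] = fixed_log10
            return objective_full(x)

        x0 = warm.get(gi, x_mle[free])
        try:
            res = optimize.minimize(objective_free, x0, method="L-BFGS-B",
                                    bounds=bounds_free,
                                    options=_LBFGSB_OPTIONS)
            if np.isfinite(res.fun):
                profile[gi] = -res.fun
                # warm-start the next point outward on the same side
                nxt = order[rank + 1] if rank + 1 < len(order) else None
                if nxt is not None and nxt not in warm:
                    warm[nxt] = res.x
        except (ValueError, FloatingPointError):
            continue
    return profile
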