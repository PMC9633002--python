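"""Kinetic models of single-cell Gal1-GFP repression.

Two nested birth--death models describe a dilution-compensated total-GFP
trace over the first two hours of glucose repression:

* **no_repression** -- constant basal production ``r_basal`` and first-order
  degradation ``r_deg``::

      dGFP/dt = r_basal - r_deg * GFP

* **repression** -- production at rate ``r_prod`` until a repression
  response delay ``t_delay``, after which production is switched off and
  GFP decays with ``r_deg``.

Both ODE systems are linear, so their means and (moment-equation) variances
have closed forms, implemented here together with the Gaussian
log-likelihoods used for fitting: a constant-variance noise model
(measurement noise only) and a time-dependent one whose total variance is
``sigma**2 + Var(t)`` with ``Var(t)`` the intrinsic variance of the
birth--death process.

Units: time in hours, rates per hour, fluorescence in rescaled units
(raw total fluorescence divided by 1e7 upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Union

import numpy as np

__all__ = [
    "ThetaNoRepression",
    "ThetaRepression",
    "ModelPrediction",
    "mean_no_repression",
    "mean_repression",
    "var_no_repression",
    "var_repression",
    "loglik_constant",
    "loglik_timedep",
]

# Below this value of r_deg * t the closed forms are evaluated through a
# series expansion of (1 - exp(-x))/x to avoid catastrophic cancellation;
# the optimizer explores r_deg down to 1e-10.
_SMALL_X = 1e-8


@dataclass(frozen=True)
class ThetaNoRepression:
    """Parameters of the model without repression kinetics.

    Attributes
    ----------
    GFP_0 : float
        Initial total GFP (rescaled units).
    r_basal : float
        Basal production rate (rescaled units / h).
    r_deg : float
        Degradation rate (1/h).
    sigma : float
        Gaussian measurement-noise scale (rescaled units).
    Var_0 : float
        Initial intrinsic variance; a free parameter only under the
        time-dependent noise model, otherwise 0.
    """

    GFP_0: float
    r_basal: float
    r_deg: float
    sigma: float
    Var_0: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class ThetaRepression:
    """Parameters of the model with repression kinetics.

    ``r_prod`` acts until ``t_delay`` (hours); afterwards production is
    switched off and GFP decays with ``r_deg``.
    """

    GFP_0: float
    r_prod: float
    r_deg: float
    t_delay: float
    sigma: float
    Var_0: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v!r}")


Theta = Union[ThetaNoRepression, ThetaRepression]


@dataclass(frozen=True)
class ModelPrediction:
    """Model mean (and intrinsic variance) evaluated on a time grid."""

    times: np.ndarray
    mean: np.ndarray
    variance: np.ndarray | None = None


def _check_times(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("model time must be >= 0")
    return t


def _relax(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x, series-expanded for small x (x >= 0)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < _SMALL_X
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs * xs / 6.0
    xl = x[~small]
    out[~small] = -np.expm1(-xl) / xl
    return out


# Raw closed forms on plain floats/arrays: the single source of the
# formulas, shared by the public dataclass API and the fitting objective
# (which must avoid per-evaluation dataclass overhead).

def _mean_norep_raw(t, gfp0, r_basal, r_deg):
    x = r_deg * t
    return r_basal * t * _relax(x) + gfp0 * np.exp(-x)


def _mean_rep_raw(t, gfp0, r_prod, r_deg, t_delay):
    before = _mean_norep_raw(np.minimum(t, t_delay), gfp0, r_prod, r_deg)
    s = np.maximum(t - t_delay, 0.0)
    return before * np.exp(-r_deg * s)


def _var_norep_raw(t, gfp0, r_basal, r_deg, var0):
    x = r_deg * t
    e = np.exp(-x)
    return gfp0 * e * (1.0 - e) + var0 * e * e + r_basal * t * _relax(x)


def _var_rep_raw(t, gfp0, r_prod, r_deg, t_delay, var0):
    v_before = _var_norep_raw(np.minimum(t, t_delay), gfp0, r_prod, r_deg,
                              var0)
    s = np.maximum(t - t_delay, 0.0)
    e = np.exp(-r_deg * s)
    m_delay = _mean_norep_raw(t_delay, gfp0, r_prod, r_deg)
    return m_delay * e * (1.0 - e) + v_before * e * e


def mean_no_repression(t, theta: ThetaNoRepression):
    """Mean total GFP under basal production and degradation.

    ``GFP(t) = r_basal/r_deg (1 - exp(-r_deg t)) + GFP_0 exp(-r_deg t)``,
    evaluated as ``r_basal * t * relax(r_deg t) + ...`` so the r_deg -> 0
    limit ``GFP_0 + r_basal t`` is exact to rounding.
    """
    t = _check_times(t)
    return _mean_norep_raw(t, theta.GFP_0, theta.r_basal, theta.r_deg)


def mean_repression(t, theta: ThetaRepression):
    """Mean total GFP with production shut-off at ``t_delay``.

    Before the delay the form equals :func:`mean_no_repression` with
    ``r_prod`` in place of ``r_basal``; afterwards
    ``GFP(t) = GFP(t_delay) exp(-r_deg (t - t_delay))``. Continuous at the
    delay.
    """
    t = _check_times(t)
    return _mean_rep_raw(t, theta.GFP_0, theta.r_prod, theta.r_deg,
                         theta.t_delay)


def var_no_repression(t, theta: ThetaNoRepression):
    """Intrinsic variance of the basal birth--death process.

    Moment-equation solution, algebraically rearranged to the
    cancellation-free form::

        Var(t) = GFP_0 e^{-r t}(1 - e^{-r t}) + Var_0 e^{-2 r t}
                 + r_basal (1 - e^{-r t}) / r

    which reduces to ``Var_0 + (GFP_0 r_deg + r_basal) t`` as r_deg -> 0
    and to the stationary Poisson value ``r_basal/r_deg`` when
    ``GFP_0 = Var_0 = r_basal/r_deg``.
    """
    t = _check_times(t)
    return _var_norep_raw(t, theta.GFP_0, theta.r_basal, theta.r_deg,
                          theta.Var_0)


def var_repression(t, theta: ThetaRepression):
    """Intrinsic variance with production shut-off at ``t_delay``.

    Before the delay: :func:`var_no_repression` with ``r_prod``. After,
    with ``s = t - t_delay``::

        Var(s) = GFP(t_delay) e^{-r s}(1 - e^{-r s}) + Var(t_delay) e^{-2 r s}

    (the pure-death binomial-survival form). Continuous at the delay.
    """
    t = _check_times(t)
    return _var_rep_raw(t, theta.GFP_0, theta.r_prod, theta.r_deg,
                        theta.t_delay, theta.Var_0)


def model_mean(t, theta: Theta):
    """Dispatch to the mean of whichever model ``theta`` parameterizes."""
    if isinstance(theta, ThetaRepression):
        return mean_repression(t, theta)
    return mean_no_repression(t, theta)


def model_variance(t, theta: Theta):
    """Dispatch to the intrinsic variance of the model of ``theta``."""
    if isinstance(theta, ThetaRepression):
        return var_repression(t, theta)
    return var_no_repression(t, theta)


def predict(times, theta: Theta, with_variance: bool = False) -> ModelPrediction:
    """Evaluate mean (and optionally intrinsic variance) on a grid."""
    times = _check_times(times)
    mean = model_mean(times, theta)
    var = model_variance(times, theta) if with_variance else None
    return ModelPrediction(times=times, mean=mean, variance=var)


def _gaussian_loglik(y: np.ndarray, mu: np.ndarray, var: np.ndarray) -> float:
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * var) + (y - mu) ** 2 / var))


def loglik_constant(observations, times, theta: Theta) -> float:
    """Gaussian log-likelihood with constant measurement variance sigma^2.

    ``logL = -1/2 sum_k [ log(2 pi sigma^2) + (y_k - y(t_k))^2 / sigma^2 ]``
    """
    y = np.asarray(observations, dtype=float)
    t = _check_times(times)
    if y.shape != t.shape:
        raise ValueError("observations and times must have equal length")
    if theta.sigma <= 0:
        raise ValueError("sigma must be > 0 for the constant noise model")
    mu = model_mean(t, theta)
    var = np.full_like(mu, theta.sigma ** 2)
    return _gaussian_loglik(y, mu, var)


def loglik_timedep(observations, times, theta: Theta) -> float:
    """Gaussian log-likelihood with total variance ``sigma^2 + Var(t_k)``.

    The intrinsic variance term comes from the moment equations of the
    matching model; with ``Var(t) = 0`` everywhere this reduces to
    :func:`loglik_constant`.
    """
    y = np.asarray(observations, dtype=float)
    t = _check_times(times)
    if y.shape != t.shape:
        raise ValueError("observations and times must have equal length")
    mu = model_mean(t, theta)
    var = theta.sigma ** 2 + model_variance(t, theta)
    if np.any(var <= 0):
        raise ValueError("total variance must be > 0 at every time point")
    return _gaussian_loglik(y, mu, var)
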