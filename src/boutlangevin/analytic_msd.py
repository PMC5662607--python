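"""Closed-form mean squared displacement of the bout-forced Langevin process.

For an animal started at rest the MSD in rescaled variables
(tau = omega t, zeta = gamma/omega, eta = sigma/omega**2) is, exactly,

    <x^2>(zeta, tau) = (2 eta^2 / zeta) * {
          tau/zeta - [1 + 2(1+zeta)^2] / [2 zeta^2 (1+zeta)]
        + 1/(zeta-1) * [ e^{-2 zeta tau}/(2 zeta^2)
                         + e^{-zeta tau} ((zeta-2)/zeta^2 - e^{-tau}/(1+zeta))
                         + e^{-tau} ] }

valid for every zeta > 0 (the 1/(zeta-1) factor multiplies a bracket that
vanishes at zeta = 1, so the singularity is removable).  This module also
provides all the standard limits of this expression:

- the drag-free curve <z^2>(tau) (zeta -> 0), which bounds the exact MSD
  from above and describes the initial superballistic spread;
- the small-time law (eta^2/4) tau^4;
- the diffusive asymptote Delta_d^2(zeta, tau), linear in tau with slope
  2 eta^2/zeta^2 (i.e. diffusion coefficient sigma^2/(gamma^2 omega));
- the low-drag (Wiener-forced Langevin) and high-drag (velocity jump
  process) approximations in physical variables;
- the large-time Gaussian dispersal kernel with variance Delta_d^2.

Numerics
--------
At small tau the exact expression is a difference of O(1/zeta^3) terms whose
result is O(tau^4); double precision loses all digits there.  Scalar
evaluations with tau below ``_TAU_HIGHPREC`` are therefore routed through
mpmath extended-precision arithmetic, and a tau-series is used for the
drag-free curve.  Near zeta = 1 the removable singularity is evaluated from
the first-order expansion of the bracket about zeta = 1.  Exponential
underflow to zero is exact in this context and deliberately permitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import mpmath as mp
import numpy as np

from .model_core import InvalidParameterError

__all__ = [
    "MSDCurve",
    "ZeroDragRequiredError",
    "AsymptoteNotValidError",
    "msd_exact",
    "msd_zero_drag",
    "msd_small_time",
    "diffusive_asymptote",
    "gaussian_kernel",
    "msd_low_drag",
    "msd_high_drag",
]

#: float evaluation of the exact MSD falls back to extended precision when
#: cancellation leaves fewer than ~11 reliable digits
_CANCEL_RTOL = 1e-11
_EPS = np.finfo(float).eps
#: half-width of the zeta-window around 1 treated via the series expansion
_ZETA_ONE_WINDOW = 1e-4

FORMULA_LABELS = (
    "exact",
    "zero_drag",
    "small_time",
    "diffusive_asymptote",
    "low_drag",
    "high_drag",
)


class ZeroDragRequiredError(ValueError):
    """msd_exact was called with zeta = 0; use msd_zero_drag instead."""


class AsymptoteNotValidError(ValueError):
    """The diffusive asymptote is not yet positive at the requested time."""


@dataclass(frozen=True)
class MSDCurve:
    """MSD values on an ordered grid of rescaled times, with provenance label."""

    tau_grid: np.ndarray
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau_grid, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if tau.shape != val.shape:
            raise InvalidParameterError("tau_grid and values must have equal shape")
        if np.any(np.diff(tau) < 0):
            raise InvalidParameterError("tau_grid must be non-decreasing")
        if self.label not in FORMULA_LABELS:
            raise InvalidParameterError(f"unknown formula label {self.label!r}")
        object.__setattr__(self, "tau_grid", tau)
        object.__setattr__(self, "values", val)


def _exp(x: np.ndarray) -> np.ndarray:
    # exp with silent, exact-in-the-limit underflow
    with np.errstate(under="ignore"):
        return np.exp(x)


def _msd_exact_highprec(zeta: float, tau: float, eta: float) -> float:
    """Extended-precision evaluation of the exact MSD (scalar)."""
    if tau < 1e-8:
        # below the resolution of the 80-digit cancellation the curve IS its
        # small-time series; keep the first correction term
        return eta**2 / 4.0 * tau**4 * (1.0 - (10.0 * zeta + 4.0) * tau / 15.0)
    with mp.workdps(80):
        z = mp.mpf(zeta)
        t = mp.mpf(tau)
        if abs(z - 1) < mp.mpf("1e-12"):
            # removable singularity: evaluate the limit by an offset far below
            # the working precision's resolution of the bracket cancellation
            z = mp.mpf(1) + mp.mpf("1e-30")
        K = (1 + 2 * (1 + z) ** 2) / (2 * z**2 * (1 + z))
        B = (
            mp.exp(-2 * z * t) / (2 * z**2)
            + mp.exp(-z * t) * ((z - 2) / z**2 - mp.exp(-t) / (1 + z))
            + mp.exp(-t)
        )
        f = t / z - K + B / (z - 1)
        return float(2 * eta**2 / z * f)


def _g_series_at_one(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Value and zeta-derivative at zeta=1 of B(zeta,tau)/(zeta-1).

    B is the bracket multiplying 1/(zeta-1) in the exact MSD; it vanishes at
    zeta = 1, and the two leading Taylor coefficients of B/(zeta-1) are

        g0 = e^{-tau}(tau+3) - e^{-2 tau}(tau/2 + 3/4)
        g1 = [ -e^{-tau}(4 tau^2 + 24 tau + 40)
               + e^{-2 tau}(6 tau^2 + 14 tau + 11) ] / 8
    """
    e1 = _exp(-tau)
    e2 = _exp(-2.0 * tau)
    g0 = e1 * (tau + 3.0) - e2 * (0.5 * tau + 0.75)
    g1 = (-e1 * (4 * tau**2 + 24 * tau + 40) + e2 * (6 * tau**2 + 14 * tau + 11)) / 8.0
    return g0, g1


def msd_exact(zeta: float, tau, eta: float = 1.0):
    """Exact MSD of the bout process started at rest.

    Parameters
    ----------
    zeta : float
        Dimensionless drag gamma/omega; must be positive.  For zeta = 0 a
        :class:`ZeroDragRequiredError` is raised (use :func:`msd_zero_drag`).
    tau : float or array_like
        Rescaled time(s) omega*t, non-negative.
    eta : float
        Length scale sigma/omega**2; the MSD carries units of eta**2.

    Returns
    -------
    float or ndarray matching ``tau``.
    """
    if zeta == 0:
        raise ZeroDragRequiredError("zeta = 0: use msd_zero_drag for the drag-free MSD")
    if not (zeta > 0):
        raise InvalidParameterError(f"zeta must be > 0, got {zeta}")
    if not (eta > 0):
        raise InvalidParameterError(f"eta must be > 0, got {eta}")
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau_arr < 0):
        raise InvalidParameterError("tau must be >= 0")

    z = float(zeta)
    out = np.empty_like(tau_arr)
    K = (1 + 2 * (1 + z) ** 2) / (2 * z**2 * (1 + z))
    if abs(z - 1.0) <= _ZETA_ONE_WINDOW:
        g0, g1 = _g_series_at_one(tau_arr)
        f = tau_arr / z - K + g0 + (z - 1.0) * g1
        magnitude = tau_arr / z + K + np.abs(g0) + abs(z - 1.0) * np.abs(g1)
    else:
        t1 = _exp(-2 * z * tau_arr) / (2 * z**2 * (z - 1.0))
        t2 = _exp(-z * tau_arr) * ((z - 2) / z**2 - _exp(-tau_arr) / (1 + z)) / (z - 1.0)
        t3 = _exp(-tau_arr) / (z - 1.0)
        f = tau_arr / z - K + t1 + t2 + t3
        magnitude = tau_arr / z + K + np.abs(t1) + np.abs(t2) + np.abs(t3)
    out[:] = 2 * eta**2 / z * f

    # the sum is a cancellation of O(magnitude) terms; where the float result
    # cannot guarantee ~11 digits (e.g. small tau: O(tau^4) from O(1/zeta^3)
    # terms), re-evaluate in extended precision
    with np.errstate(invalid="ignore", divide="ignore"):
        unreliable = (f <= 0) | (_EPS * magnitude > _CANCEL_RTOL * np.abs(f))
    for i in np.flatnonzero(unreliable):
        ti = tau_arr[i]
        out[i] = 0.0 if ti == 0.0 else _msd_exact_highprec(z, ti, eta)

    return out if np.ndim(tau) else float(out[0])


def _zero_drag_bracket_series(tau: np.ndarray) -> np.ndarray:
    # bracket of the drag-free MSD: sum_{n>=4} 6 (-1)^n (n-1)/n! tau^n
    acc = np.zeros_like(tau)
    power = np.ones_like(tau)
    fact = 1.0
    # terms shrink factorially; n=30 leaves truncation error << 1 ulp for tau < 1
    for n in range(1, 31):
        power = power * tau
        fact *= n
        if n >= 4:
            acc += 6.0 * ((-1) ** n) * (n - 1) / fact * power
    return acc


def msd_zero_drag(tau, eta: float = 1.0):
    """Drag-free MSD limit: (eta^2/3)[tau^2(2 tau - 3) + 6 - 6(1+tau)e^{-tau}].

    This is the zeta -> 0 limit of the exact MSD and an upper bound on it for
    every zeta > 0; at small tau it reduces to the superballistic law
    (eta^2/4) tau^4.
    """
    if not (eta > 0):
        raise InvalidParameterError(f"eta must be > 0, got {eta}")
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau_arr < 0):
        raise InvalidParameterError("tau must be >= 0")
    bracket = np.empty_like(tau_arr)
    small = tau_arr < 1.0
    if np.any(small):
        bracket[small] = _zero_drag_bracket_series(tau_arr[small])
    if np.any(~small):
        t = tau_arr[~small]
        bracket[~small] = t**2 * (2 * t - 3) + 6 - 6 * (1 + t) * _exp(-t)
    out = eta**2 / 3.0 * bracket
    return out if np.ndim(tau) else float(out[0])


def msd_small_time(tau, eta: float = 1.0):
    """Leading small-time law (eta^2/4) tau^4 — superballistic spread."""
    if not (eta > 0):
        raise InvalidParameterError(f"eta must be > 0, got {eta}")
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise InvalidParameterError("tau must be >= 0")
    out = eta**2 / 4.0 * tau_arr**4
    return out if np.ndim(tau) else float(out)


def diffusive_asymptote(zeta: float, tau, eta: float = 1.0):
    """Large-time linear asymptote Delta_d^2(zeta, tau) of the exact MSD.

        Delta_d^2 = (2 eta^2/zeta^2) tau - eta^2 [1 + 2(1+zeta)^2] / [zeta^3 (1+zeta)]

    The slope over tau is 2 eta^2/zeta^2, i.e. twice the diffusion
    coefficient in rescaled units.  The expression is negative at small tau,
    where the asymptote is not yet meaningful; such values are returned as-is.
    """
    if not (zeta > 0):
        raise InvalidParameterError(f"zeta must be > 0, got {zeta}")
    if not (eta > 0):
        raise InvalidParameterError(f"eta must be > 0, got {eta}")
    tau_arr = np.asarray(tau, dtype=float)
    out = (2 * eta**2 / zeta**2) * tau_arr - eta**2 * (
        1 + 2 * (1 + zeta) ** 2
    ) / (zeta**3 * (1 + zeta))
    return out if np.ndim(tau) else float(out)


def gaussian_kernel(x, zeta: float, tau: float, eta: float = 1.0):
    """Large-time Gaussian dispersal kernel: N(0, Delta_d^2(zeta, tau)) density.

    Raises :class:`AsymptoteNotValidError` when Delta_d^2 <= 0 (time too
    short for the diffusive approximation).
    """
    var = diffusive_asymptote(zeta, float(tau), eta)
    if var <= 0:
        raise AsymptoteNotValidError(
            f"Delta_d^2 = {var} <= 0 at tau = {tau}: diffusive kernel not yet valid"
        )
    x_arr = np.asarray(x, dtype=float)
    out = np.exp(-(x_arr**2) / (2 * var)) / np.sqrt(2 * np.pi * var)
    return out if np.ndim(x) else float(out)


def _en3_low_drag(u: np.ndarray) -> np.ndarray:
    """u - 3/2 + 2 e^{-u} - e^{-2u}/2, series-stabilised (= u^3/3 + ... at 0)."""
    out = np.empty_like(u)
    small = u < 0.5
    if np.any(small):
        us = u[small]
        acc = np.zeros_like(us)
        power = us * us * us  # u^n starting at n=3
        fact = 6.0
        for n in range(3, 31):
            coeff = ((-1) ** n) * (2.0 - 2.0 ** (n - 1)) / fact
            acc += coeff * power
            power = power * us
            fact *= n + 1
        out[small] = acc
    if np.any(~small):
        ul = u[~small]
        out[~small] = ul - 1.5 + 2 * _exp(-ul) - 0.5 * _exp(-2 * ul)
    return out


def _en2(u: np.ndarray) -> np.ndarray:
    """u - 1 + e^{-u}, series-stabilised near 0 (= u^2/2 - u^3/6 + ...)."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u < 1e-2
    if np.any(small):
        us = u[small]
        out[small] = us**2 * (0.5 + us * (-1.0 / 6 + us * (1.0 / 24 + us * (-1.0 / 120 + us / 720))))
    if np.any(~small):
        ul = u[~small]
        out[~small] = ul - 1.0 + _exp(-ul)
    return out


def msd_low_drag(gamma: float, sigma: float, omega: float, t):
    """Low-drag (zeta << 1) MSD approximation in physical variables.

        (2 sigma^2 / (gamma^3 omega)) [gamma t - (1 - e^{-gamma t})
                                       - (1 - e^{-gamma t})^2 / 2]

    This is the MSD of the standard Langevin equation driven by a Wiener
    process of variance q^2 = 2 sigma^2/omega, started at rest; its
    small-time limit is (2 sigma^2 / (3 omega)) t^3.
    """
    if not (gamma > 0 and sigma > 0 and omega > 0):
        raise InvalidParameterError("gamma, sigma, omega must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("t must be >= 0")
    u = np.atleast_1d(gamma * t_arr)
    out = 2 * sigma**2 / (gamma**3 * omega) * _en3_low_drag(u)
    return out if np.ndim(t) else float(out[0])


def msd_high_drag(gamma: float, sigma: float, omega: float, t):
    """High-drag (zeta >> 1) MSD approximation in physical variables.

        (2 sigma^2 / (gamma^2 omega^2)) (omega t - 1 + e^{-omega t})

    This coincides with the MSD of a velocity jump process; its small-time
    limit is the ballistic law (sigma^2/gamma^2) t^2.
    """
    if not (gamma > 0 and sigma > 0 and omega > 0):
        raise InvalidParameterError("gamma, sigma, omega must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("t must be >= 0")
    u = np.atleast_1d(omega * t_arr)
    out = 2 * sigma**2 / (gamma**2 * omega**2) * _en2(u)
    return out if np.ndim(t) else float(out[0])
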