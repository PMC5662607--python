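"""Parameters, rescaling and elementary distributions of the bout-structured
random-acceleration movement model.

The model describes an animal moving along one axis through a viscous medium.
Its velocity obeys a linear-drag Langevin equation

    dv/dt = -gamma * v + a(t)

where ``gamma`` is the drag per unit body mass (Stokes regime) and ``a(t)`` is
the force per unit mass the animal exerts in response to environmental cues.
Cues arrive as a Poisson process with rate ``omega``; between two cues (a
*bout*) the acceleration is constant, drawn independently from a zero-mean
distribution with variance ``nu_a2``.  The forcing is therefore piecewise
constant, exponentially correlated and discontinuous — not a Wiener process.

Everything downstream works with the dimensionless groups

    tau = omega * t,   eta = sigma / omega**2,   zeta = gamma / omega,

with ``sigma = sqrt(nu_a2)``; physical units enter only through the optional
(mass, drag_coeff) -> gamma conversion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ACCEL_FAMILIES",
    "InvalidParameterError",
    "NoAsymptoticDiffusionError",
    "ModelParams",
    "RescaledParams",
    "AccelerationDistribution",
    "rescale_parameters",
    "diffusion_coefficient",
    "acceleration_autocovariance_theory",
    "wiener_limit_variance",
    "sample_bout_durations",
]

#: Supported zero-mean acceleration families.  All are parameterised by the
#: variance nu_a2 so that the rescaled MSD is family-independent.
ACCEL_FAMILIES = ("gaussian", "uniform", "two_point")

_GAMMA_MASS_RTOL = 1e-12


class InvalidParameterError(ValueError):
    """A model parameter violates its contract (e.g. omega <= 0)."""


class NoAsymptoticDiffusionError(ValueError):
    """Raised for gamma = 0: a drag-free mover never becomes diffusive."""


@dataclass(frozen=True)
class ModelParams:
    """Physical/stochastic parameters of the movement process.

    Parameters
    ----------
    nu_a2 : float
        Variance of the per-bout acceleration (length^2 time^-4).  Must be
        positive; ``nu_a2 = sigma**2`` for the Gaussian family.
    omega : float
        Rate of environmental cues, i.e. inverse mean bout duration
        (time^-1).  Must be positive.
    gamma : float
        Drag per unit mass (time^-1).  May be zero (drag-free motion), in
        which case the process never converges to ordinary diffusion.
    accel_dist : str
        Acceleration family: ``gaussian``, ``uniform`` (on
        ``[-sqrt(3) nu_a, +sqrt(3) nu_a]``) or ``two_point`` (``+-nu_a``
        with equal probability).
    mass, drag_coeff : float, optional
        Body mass m and whole-body drag coefficient c.  When both are given
        they must satisfy ``gamma = c / m``.
    """

    nu_a2: float
    omega: float
    gamma: float
    accel_dist: str = "gaussian"
    mass: Optional[float] = None
    drag_coeff: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.nu_a2 > 0):
            raise InvalidParameterError(f"nu_a2 must be > 0, got {self.nu_a2}")
        if not (self.omega > 0):
            raise InvalidParameterError(f"omega must be > 0, got {self.omega}")
        if not (self.gamma >= 0):
            raise InvalidParameterError(f"gamma must be >= 0, got {self.gamma}")
        if self.accel_dist not in ACCEL_FAMILIES:
            raise InvalidParameterError(
                f"accel_dist must be one of {ACCEL_FAMILIES}, got {self.accel_dist!r}"
            )
        if (self.mass is None) != (self.drag_coeff is None):
            raise InvalidParameterError("mass and drag_coeff must be given together")
        if self.mass is not None:
            if not (self.mass > 0) or not (self.drag_coeff >= 0):
                raise InvalidParameterError("mass must be > 0 and drag_coeff >= 0")
            implied = self.drag_coeff / self.mass
            scale = max(abs(self.gamma), abs(implied), 1e-300)
            if abs(self.gamma - implied) > _GAMMA_MASS_RTOL * scale:
                raise InvalidParameterError(
                    f"gamma={self.gamma} inconsistent with drag_coeff/mass={implied}"
                )

    @property
    def sigma(self) -> float:
        """Acceleration scale sigma = sqrt(nu_a2)."""
        return math.sqrt(self.nu_a2)

    # -- JSON config round-trip -------------------------------------------

    _JSON_KEYS = frozenset(
        {"nu_a2", "omega", "gamma", "accel_dist", "mass", "drag_coeff", "seed"}
    )

    def to_json_dict(self) -> dict:
        d = {
            "nu_a2": self.nu_a2,
            "omega": self.omega,
            "gamma": self.gamma,
            "accel_dist": self.accel_dist,
        }
        if self.mass is not None:
            d["mass"] = self.mass
            d["drag_coeff"] = self.drag_coeff
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - cls._JSON_KEYS
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            nu_a2=float(d["nu_a2"]),
            omega=float(d["omega"]),
            gamma=float(d["gamma"]),
            accel_dist=d.get("accel_dist", "gaussian"),
            mass=None if d.get("mass") is None else float(d["mass"]),
            drag_coeff=None if d.get("drag_coeff") is None else float(d["drag_coeff"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_json_dict(json.loads(s))


@dataclass(frozen=True)
class RescaledParams:
    """Dimensionless parameter set (eta, zeta) and rescaled time tau = omega*t."""

    eta: float
    zeta: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not (self.eta > 0):
            raise InvalidParameterError(f"eta must be > 0, got {self.eta}")
        if not (self.zeta >= 0):
            raise InvalidParameterError(f"zeta must be >= 0, got {self.zeta}")
        if not (self.tau >= 0):
            raise InvalidParameterError(f"tau must be >= 0, got {self.tau}")

    def to_physical(self, omega: float) -> tuple[float, float, float]:
        """Invert the rescaling for a given cue rate: returns (sigma, gamma, t)."""
        if not (omega > 0):
            raise InvalidParameterError(f"omega must be > 0, got {omega}")
        return self.eta * omega**2, self.zeta * omega, self.tau / omega


@dataclass(frozen=True)
class AccelerationDistribution:
    """Zero-mean acceleration law of a bout, parameterised by its variance.

    The three families share mean 0 and variance ``variance`` so the
    rescaled MSD does not depend on the family choice:

    - ``gaussian``: N(0, variance);
    - ``uniform``: U(-sqrt(3 variance), +sqrt(3 variance));
    - ``two_point``: +-sqrt(variance) with probability 1/2 each.
    """

    family: str
    variance: float

    def __post_init__(self) -> None:
        if self.family not in ACCEL_FAMILIES:
            raise InvalidParameterError(
                f"family must be one of {ACCEL_FAMILIES}, got {self.family!r}"
            )
        if not (self.variance > 0):
            raise InvalidParameterError(f"variance must be > 0, got {self.variance}")

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        nu = math.sqrt(self.variance)
        if self.family == "gaussian":
            return rng.standard_normal(size) * nu
        if self.family == "uniform":
            half = math.sqrt(3.0) * nu
            return rng.uniform(-half, half, size)
        # two_point
        return nu * np.where(rng.random(size) < 0.5, -1.0, 1.0)

    @classmethod
    def from_params(cls, params: ModelParams) -> "AccelerationDistribution":
        return cls(family=params.accel_dist, variance=params.nu_a2)


def rescale_parameters(params: ModelParams, t: float = 0.0) -> RescaledParams:
    """Map physical parameters to the dimensionless groups.

    Returns ``eta = sigma/omega**2``, ``zeta = gamma/omega`` and
    ``tau = omega*t``, with ``sigma = sqrt(nu_a2)`` for every acceleration
    family (only the variance enters the second-moment theory).
    """
    if t < 0:
        raise InvalidParameterError(f"t must be >= 0, got {t}")
    return RescaledParams(
        eta=params.sigma / params.omega**2,
        zeta=params.gamma / params.omega,
        tau=params.omega * t,
    )


def diffusion_coefficient(params: ModelParams) -> float:
    """Large-time diffusion coefficient D = nu_a2 / (gamma**2 * omega).

    Equivalently ``D = m**2 nu_a2 / (c**2 omega)`` in terms of body mass and
    whole-body drag.  Raises :class:`NoAsymptoticDiffusionError` for
    ``gamma = 0``: without drag the MSD grows as t^3 forever and no diffusive
    asymptote exists.
    """
    if params.gamma == 0:
        raise NoAsymptoticDiffusionError(
            "gamma = 0: drag-free movement never converges to diffusion"
        )
    return params.nu_a2 / (params.gamma**2 * params.omega)


def acceleration_autocovariance_theory(params: ModelParams, lag) -> np.ndarray | float:
    """Stationary autocovariance of the forcing: nu_a2 * exp(-omega * lag).

    The piecewise-constant bout forcing is exponentially correlated with the
    cue rate as decay constant.  ``lag`` must be non-negative (the process is
    stationary; pass ``abs(lag)``).
    """
    lag_arr = np.asarray(lag, dtype=float)
    if np.any(lag_arr < 0):
        raise InvalidParameterError("lag must be >= 0 (pass |lag|)")
    out = params.nu_a2 * np.exp(-params.omega * lag_arr)
    return out if out.ndim else float(out)


def wiener_limit_variance(params: ModelParams) -> float:
    """Forcing variance q^2 = 2 sigma^2 / omega of the matched Wiener process.

    In the low-drag limit the model reduces to the standard Langevin equation
    driven by white noise of this variance.
    """
    return 2.0 * params.nu_a2 / params.omega


def sample_bout_durations(omega: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. exponential bout durations with mean ``1/omega``."""
    if not (omega > 0):
        raise InvalidParameterError(f"omega must be > 0, got {omega}")
    if n < 0:
        raise InvalidParameterError(f"n must be >= 0, got {n}")
    if n == 0:
        return np.empty(0)
    return rng.standard_exponential(int(n)) / omega
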