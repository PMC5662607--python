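"""Exact-in-bout Monte Carlo simulation of the bout-forced Langevin process.

A trajectory is a sequence of bouts: exponential durations with rate omega
and i.i.d. zero-mean accelerations held constant within each bout.  Inside a
bout the linear-drag equation of motion has the closed-form solution

    v(t) = v0 e^{-gamma t} + (a/gamma) (1 - e^{-gamma t})
    y(t) = y0 + (v0/gamma) (1 - e^{-gamma t})
              + (a/gamma^2) (gamma t + e^{-gamma t} - 1)

so trajectories are advanced *exactly* — there is no time-stepping error,
only Monte Carlo noise.  Reading the position at an observation time
truncates the active bout for the read-out but does not terminate it: a bout
ends only when the next cue arrives.

The ensemble estimators (MSD with standard errors, displacement histograms,
forcing autocovariance) exist to validate the closed-form theory in
``analytic_msd`` and to reproduce its regime taxonomy from raw simulation.

Randomness contract: every stochastic function takes an integer seed;
independent sub-streams are derived deterministically from it with
``numpy.random.SeedSequence`` spawning, so ensembles are bit-reproducible
for a fixed chunk layout (the chunk size is a keyword with a fixed default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .analytic_msd import _en2, diffusive_asymptote
from .model_core import (
    AccelerationDistribution,
    InvalidParameterError,
    ModelParams,
)

__all__ = [
    "MotionState",
    "EnsembleMSD",
    "RenormalizedPdf",
    "advance_within_bout",
    "positions_from_bouts",
    "simulate_positions",
    "sample_displacements",
    "ensemble_msd",
    "ensemble_pdf",
    "empirical_acc_autocov",
]

#: below this drag the drag-free closed forms are used (removable singularity)
_GAMMA_FREE = 1e-12

#: trajectories per vectorised block; sized so per-block arrays stay cache-
#: and allocator-friendly (results are invariant to this once fixed)
_DEFAULT_CHUNK = 1024


@dataclass(frozen=True)
class MotionState:
    """Instantaneous state of one animal within its current bout."""

    t: float = 0.0
    y: float = 0.0
    v: float = 0.0
    bout_index: int = 0
    a_current: float = 0.0
    bout_end: float = math.inf

    def __post_init__(self) -> None:
        if self.t > self.bout_end:
            raise InvalidParameterError("t must not exceed bout_end")
        if self.bout_index < 0:
            raise InvalidParameterError("bout_index must be >= 0")


@dataclass(frozen=True)
class EnsembleMSD:
    """Monte Carlo MSD estimate on a time grid, with standard errors."""

    tau_grid: np.ndarray
    msd_hat: np.ndarray
    se: np.ndarray
    n: int


@dataclass(frozen=True)
class RenormalizedPdf:
    """Histogram estimate of the dispersal kernel at one rescaled time,
    renormalised by its central-bin value so the peak sits at 1."""

    tau: float
    bin_centers: np.ndarray
    density: np.ndarray
    density_renorm: np.ndarray
    samples: Optional[np.ndarray] = None


def advance_within_bout(state: MotionState, dt: float, gamma: float) -> MotionState:
    """Advance a state by ``dt`` inside its active bout, exactly.

    ``dt`` must not carry the state past ``bout_end``.  The update uses the
    closed-form within-bout solution, evaluated through expm1-style helpers
    so that small gamma*dt does not lose precision; for gamma below 1e-12
    the drag-free forms v = v0 + a dt, y = y0 + v0 dt + a dt^2/2 are used.
    """
    if dt < 0:
        raise InvalidParameterError(f"dt must be >= 0, got {dt}")
    if state.t + dt > state.bout_end * (1 + 1e-12):
        raise InvalidParameterError("dt advances past the end of the active bout")
    a, v0, y0 = state.a_current, state.v, state.y
    if gamma < _GAMMA_FREE:
        v = v0 + a * dt
        y = y0 + v0 * dt + 0.5 * a * dt**2
    else:
        u = gamma * dt
        w = -np.expm1(-u)  # 1 - e^{-gamma dt}
        v = v0 * (1.0 - w) + a / gamma * w
        y = y0 + v0 / gamma * w + a / gamma**2 * float(_en2(np.atleast_1d(u))[0])
    return replace(state, t=state.t + dt, y=float(y), v=float(v))


def _coverage_columns(omega: float, t_max: float) -> int:
    # Poisson bout count: mean + 6 sd + slack covers t_max except ~1e-9/row,
    # and the rare shortfall is topped up explicitly
    lam = omega * t_max
    return int(lam + 6.0 * math.sqrt(lam + 1.0) + 16.0)


def _draw_bouts(
    params: ModelParams, n: int, t_max: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Durations, accelerations and cumulative bout end times covering t_max.

    Returns arrays of shape (n, M); rows are topped up (rarely) until every
    cumulative duration exceeds t_max.
    """
    dist = AccelerationDistribution.from_params(params)
    m = _coverage_columns(params.omega, t_max)
    dur = rng.standard_exponential((n, m)) / params.omega
    acc = dist.sample((n, m), rng)
    ends = np.cumsum(dur, axis=1)
    while np.any(ends[:, -1] <= t_max):
        short = np.flatnonzero(ends[:, -1] <= t_max)
        extra_d = rng.standard_exponential((len(short), 16)) / params.omega
        extra_a = dist.sample((len(short), 16), rng)
        pad_d = np.zeros((n, 16))
        pad_a = np.zeros((n, 16))
        pad_d[short] = extra_d
        pad_a[short] = extra_a
        dur = np.concatenate([dur, pad_d], axis=1)
        acc = np.concatenate([acc, pad_a], axis=1)
        ends = np.cumsum(dur, axis=1)
    return dur, acc, ends


def _positions_kernel(
    acc: np.ndarray,
    dur: np.ndarray,
    ends: np.ndarray,
    gamma: float,
    sample_times: np.ndarray,
) -> np.ndarray:
    """Positions (n, S) of n trajectories at S times, by the closed-form sum.

    For each observation time s, completed bouts contribute
    a_n [en2(g t_n) + w_n q_n] / g^2 with w_n = 1 - e^{-g t_n} and
    q_n = 1 - e^{-g (s - E_n)} (E_n the bout's absolute end time); the
    active bout, truncated at s, contributes a_k en2(g t_k') / g^2.  Both
    pieces are individually small at small drag, so no cancellation occurs
    and the drag-free limit is recovered smoothly.
    """
    n, m = acc.shape
    out = np.empty((n, len(sample_times)))
    rows = np.arange(n)
    starts = ends - dur
    free = gamma < _GAMMA_FREE
    if not free:
        en2_full = _en2(gamma * dur)
        w_full = -np.expm1(-gamma * dur)
    buf = np.empty_like(acc)  # reused per sample time to limit allocation churn
    for j, s in enumerate(sample_times):
        if s == 0.0:
            out[:, j] = 0.0
            continue
        done = ends < s
        k = done.sum(axis=1)  # index of the active bout
        t_act = s - starts[rows, k]
        a_act = acc[rows, k]
        np.subtract(s, ends, out=buf)
        np.clip(buf, 0.0, None, out=buf)  # time elapsed since each bout's end
        if free:
            buf *= dur
            buf += 0.5 * dur**2 * done
            buf *= acc
            buf *= done
            x = buf.sum(axis=1)
            x += 0.5 * a_act * t_act**2
        else:
            buf *= -gamma
            with np.errstate(under="ignore"):
                np.expm1(buf, out=buf)
            np.negative(buf, out=buf)  # q = 1 - e^{-gamma (s - E)}
            buf *= w_full
            buf += en2_full
            buf *= acc
            buf *= done
            x = buf.sum(axis=1)
            x += a_act * _en2(gamma * t_act)
            x /= gamma**2
        out[:, j] = x
    return out


def positions_from_bouts(
    accels: Sequence[float],
    durations: Sequence[float],
    gamma: float,
    sample_times: Sequence[float],
) -> np.ndarray:
    """Positions of a single trajectory with a predetermined bout list.

    ``accels`` and ``durations`` fully determine the trajectory (started at
    rest); the bout list must cover every sample time.
    """
    acc = np.asarray(accels, dtype=float)[None, :]
    dur = np.asarray(durations, dtype=float)[None, :]
    if acc.shape != dur.shape:
        raise InvalidParameterError("accels and durations must have equal length")
    st = np.asarray(sample_times, dtype=float)
    if st.size == 0:
        return np.empty(0)
    if np.any(np.diff(st) < 0) or np.any(st < 0):
        raise InvalidParameterError("sample_times must be non-decreasing and >= 0")
    if acc.size == 0:
        # no cues ever arrive: the animal stays at rest
        return np.zeros(st.size)
    ends = np.cumsum(dur, axis=1)
    if ends[0, -1] < st[-1]:
        raise InvalidParameterError("bout list does not cover the last sample time")
    return _positions_kernel(acc, dur, ends, gamma, st)[0]


def simulate_positions(
    params: ModelParams, sample_times: Sequence[float], seed: int
) -> np.ndarray:
    """One trajectory started at rest, read out at the given times.

    Bout durations are exponential with rate omega; accelerations i.i.d.
    from the configured family.  Observation never terminates a bout.
    """
    st = np.asarray(sample_times, dtype=float)
    if st.size == 0:
        return np.empty(0)
    if np.any(np.diff(st) < 0) or np.any(st < 0):
        raise InvalidParameterError("sample_times must be non-decreasing and >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dur, acc, ends = _draw_bouts(params, 1, float(st[-1]), rng)
    return _positions_kernel(acc, dur, ends, params.gamma, st)[0]


def _ensemble_chunks(n: int, chunk: int) -> list[int]:
    sizes = [chunk] * (n // chunk)
    if n % chunk:
        sizes.append(n % chunk)
    return sizes


def sample_displacements(
    params: ModelParams,
    t: float,
    n: int,
    seed: int,
    chunk_size: int = _DEFAULT_CHUNK,
) -> np.ndarray:
    """Displacements x(t) of ``n`` independent trajectories (1D array)."""
    if not (t >= 0):
        raise InvalidParameterError(f"t must be >= 0, got {t}")
    out = np.empty(n)
    sizes = _ensemble_chunks(n, chunk_size)
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    pos = 0
    for size, child in zip(sizes, children):
        rng = np.random.default_rng(child)
        dur, acc, ends = _draw_bouts(params, size, t, rng)
        out[pos : pos + size] = _positions_kernel(
            acc, dur, ends, params.gamma, np.array([t])
        )[:, 0]
        pos += size
    return out


def ensemble_msd(
    params: ModelParams,
    sample_times: Sequence[float],
    n: int,
    seed: int,
    chunk_size: int = _DEFAULT_CHUNK,
) -> EnsembleMSD:
    """Monte Carlo MSD over ``n`` independent trajectories.

    Returns the per-time mean of x^2 together with its standard error
    (sample std of x^2 over sqrt(n)).  Time values are the physical ones
    passed in; multiply by omega for the rescaled grid.
    """
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    st = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(st) < 0) or np.any(st < 0):
        raise InvalidParameterError("sample_times must be non-decreasing and >= 0")
    s1 = np.zeros(st.size)
    s2 = np.zeros(st.size)
    sizes = _ensemble_chunks(n, chunk_size)
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    for size, child in zip(sizes, children):
        rng = np.random.default_rng(child)
        dur, acc, ends = _draw_bouts(params, size, float(st[-1]), rng)
        x = _positions_kernel(acc, dur, ends, params.gamma, st)
        x2 = x**2
        s1 += x2.sum(axis=0)
        s2 += (x2**2).sum(axis=0)
    msd_hat = s1 / n
    var = np.clip(s2 / n - msd_hat**2, 0.0, None) * n / (n - 1)
    se = np.sqrt(var / n)
    return EnsembleMSD(tau_grid=st * params.omega, msd_hat=msd_hat, se=se, n=n)


def ensemble_pdf(
    params: ModelParams,
    tau: float,
    n: int,
    n_bins: int,
    seed: int,
    chunk_size: int = _DEFAULT_CHUNK,
) -> RenormalizedPdf:
    """Histogram estimate of the dispersal kernel at rescaled time ``tau``.

    Bins are symmetric about 0 with an odd count so the central bin is
    centred at the origin; the range covers +-6 standard deviations of the
    diffusive asymptote (or of the sample, when the asymptote is not yet
    positive).  ``density_renorm`` divides by the central-bin density.
    """
    if n < 1000:
        raise InvalidParameterError(f"n must be >= 1000 for a usable histogram, got {n}")
    if n_bins < 3:
        raise InvalidParameterError(f"n_bins must be >= 3, got {n_bins}")
    if n_bins % 2 == 0:
        n_bins += 1  # force a bin centred at the origin
    rescaled = rescale_zeta_eta(params)
    t_phys = tau / params.omega
    x = sample_displacements(params, t_phys, n, seed, chunk_size)
    var = diffusive_asymptote(rescaled[0], tau, rescaled[1]) if rescaled[0] > 0 else -1.0
    half_width = 6.0 * math.sqrt(var) if var > 0 else 6.0 * float(np.std(x))
    edges = np.linspace(-half_width, half_width, n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    density = counts / (n * (edges[1] - edges[0]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    central = n_bins // 2
    if counts[central] < 10:
        warnings.warn(
            "fewer than 10 samples in the central bin: renormalisation unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        renorm = density / density[central] if density[central] > 0 else density * np.nan
    return RenormalizedPdf(
        tau=float(tau),
        bin_centers=centers,
        density=density,
        density_renorm=renorm,
        samples=x,
    )


def rescale_zeta_eta(params: ModelParams) -> tuple[float, float]:
    """(zeta, eta) of a parameter set — convenience for the estimators."""
    return params.gamma / params.omega, params.sigma / params.omega**2


def empirical_acc_autocov(
    params: ModelParams,
    lags: Sequence[float],
    total_time: float,
    seed: int,
    n_batches: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-average autocovariance of the piecewise-constant forcing.

    One long realisation of a(t) is sampled on a regular grid (20 points per
    mean bout); for each lag the product a(t) a(t+lag) is averaged over the
    grid.  Standard errors come from batch means over ``n_batches``
    contiguous blocks, which absorbs the serial correlation of the forcing.

    Returns (lags, estimates, standard errors).
    """
    lag_arr = np.asarray(lags, dtype=float)
    if np.any(lag_arr < 0):
        raise InvalidParameterError("lags must be >= 0")
    max_lag = float(lag_arr.max(initial=0.0))
    if total_time < 100.0 * max(max_lag, 1.0 / params.omega):
        raise InvalidParameterError(
            "total_time must be much larger than the lags and the mean bout"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    horizon = total_time + max_lag
    dur, acc, ends = _draw_bouts(params, 1, horizon, rng)
    ends_1d, acc_1d = ends[0], acc[0]

    dt = 1.0 / (20.0 * params.omega)
    t_grid = np.arange(0.0, total_time, dt)
    a_t = acc_1d[np.searchsorted(ends_1d, t_grid, side="right")]
    est = np.empty(lag_arr.size)
    se = np.empty(lag_arr.size)
    for i, lag in enumerate(lag_arr):
        a_lag = acc_1d[np.searchsorted(ends_1d, t_grid + lag, side="right")]
        prod = a_t * a_lag
        batches = np.array_split(prod, n_batches)
        bm = np.array([b.mean() for b in batches])
        est[i] = prod.mean()
        se[i] = bm.std(ddof=1) / math.sqrt(n_batches)
    return lag_arr, est, se
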