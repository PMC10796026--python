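"""Bacterial replication: two stalling forks on a circular genome.

Two replisomes leave a single origin (coordinate 0 == L on a circular
genome of length L) in opposite directions.  Each fork position is the
running extremum of an auxiliary drift-diffusion process,

    dy1 = v0 h(tau) dtau + sqrt(2 D h(tau)) dW1,   x1 = running max y1,
    dy2 = -v0 h(tau) dtau + sqrt(2 D h(tau)) dW2,  x2 = running min y2,

so negative excursions of y translate into stochastic stalling of x.  The
optional factor h(tau) = 1 + delta cos(omega tau + phi) modulates speed
(and diffusivity) over the cell cycle.  The single-fork replication
program is then the first-passage law of y through x — an inverse-Gaussian
CDF evaluated at the rescaled clock H(tau) = integral_0^tau h — and the
joint program is f = 1 - (1 - f1)(1 - f2), from which the abundance
follows by averaging exp(-Lambda tau) over replication ages.

The dimensionless Peclet number Pe = L v0 / (4 D) controls stalling:
large Pe means nearly deterministic forks.  The two forks meet at a random
point Z near L/2 with spread Delta Z = sqrt(D L / (2 v0)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, optimize, special

from .core import GrowthRate, DEFAULT_QUAD_TOL

#: zeta(1/2)/sqrt(2*pi): barrier-shift constant for discretely monitored crossings
_BARRIER_BETA = 0.5826

__all__ = [
    "SpeedModulation",
    "BacterialParams",
    "ForkTrajectories",
    "modulation_integral",
    "fork_program",
    "abundance",
    "simulate_forks",
    "first_passage_times",
    "meeting_point_spread",
]


@dataclass(frozen=True)
class SpeedModulation:
    """Oscillatory speed factor h(tau) = 1 + delta*cos(omega*tau + phi)."""

    delta: float
    omega: float  # rad/s
    phi: float  # rad

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta < 1.0):
            raise ValueError("delta must be in [0, 1) so that h(tau) stays positive")
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    def h(self, tau) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        return 1.0 + self.delta * np.cos(self.omega * tau + self.phi)

    def canonical(self) -> "SpeedModulation":
        """Resolve the (delta, phi) <-> (-delta, phi+pi) and phi mod 2*pi gauges."""
        delta, phi = self.delta, self.phi
        if delta < 0:  # defensive; constructor forbids it
            delta, phi = -delta, phi + math.pi
        return SpeedModulation(delta, self.omega, phi % (2.0 * math.pi))


@dataclass(frozen=True)
class BacterialParams:
    """Two-replisome model parameters on a circular genome."""

    L: float  # genome length, bp
    v0: float  # baseline fork speed, bp/s
    D: float  # fork diffusivity, bp^2/s
    growth: GrowthRate
    modulation: SpeedModulation | None = None

    def __post_init__(self) -> None:
        if self.L <= 0 or self.v0 <= 0:
            raise ValueError("genome length and baseline speed must be positive")
        if self.D < 0:
            raise ValueError("diffusivity must be non-negative")

    @property
    def peclet(self) -> float:
        if self.D == 0:
            return math.inf
        return self.L * self.v0 / (4.0 * self.D)


def modulation_integral(mod: SpeedModulation | None, tau) -> np.ndarray | float:
    """Rescaled clock H(tau) = integral_0^tau h(u) du (strictly increasing)."""
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("age must be non-negative")
    if mod is None or mod.delta == 0.0:
        out = tau_arr.copy()
    else:
        out = tau_arr + (mod.delta / mod.omega) * (
            np.sin(mod.omega * tau_arr + mod.phi) - math.sin(mod.phi)
        )
    return out if out.shape else float(out)


def _invert_modulation(mod: SpeedModulation | None, target: float) -> float:
    """Solve H(tau) = target for tau (H is strictly increasing)."""
    if mod is None or mod.delta == 0.0:
        return target
    lo = target / (1.0 + mod.delta)
    hi = target / (1.0 - mod.delta) + 2.0 * math.pi / mod.omega
    return float(optimize.brentq(lambda t: modulation_integral(mod, t) - target, lo, hi))


def _ig_cdf(t, mu, lam_shape) -> np.ndarray:
    """Inverse-Gaussian CDF with mean mu and shape lam = mu^3/sigma^2.

    Uses the numerically stable two-Phi closed form, with the exp(2 lam/mu)
    factor handled in log space through log_ndtr.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast(t, mu, lam_shape).shape)
    pos = t > 0
    if not np.any(pos):
        return out
    tb, mub, lb = np.broadcast_arrays(t, mu, lam_shape)
    tp, mp, lp = tb[pos], mub[pos], lb[pos]
    s = np.sqrt(lp / tp)
    z1 = s * (tp / mp - 1.0)
    z2 = -s * (tp / mp + 1.0)
    out[pos] = special.ndtr(z1) + np.exp(2.0 * lp / mp + special.log_ndtr(z2))
    return np.clip(out, 0.0, 1.0)


def fork_program(params: BacterialParams, x, tau, fork: int) -> np.ndarray | float:
    """Single-fork replication program f_i(x, tau).

    Fork 1 starts at 0 moving right; fork 2 starts at L moving left.  The
    first-passage distance is x (fork 1) or L - x (fork 2); with D > 0 the
    program is the inverse-Gaussian CDF with mean dist/v0 and variance
    2 D dist / v0^3, evaluated at the modulated clock H(tau); with D = 0 it
    is the deterministic step H(tau) >= dist/v0.
    """
    if fork not in (1, 2):
        raise ValueError("fork must be 1 or 2")
    x_arr = np.asarray(x, dtype=float)
    if np.any((x_arr < 0) | (x_arr > params.L)):
        raise ValueError("position must lie in [0, L]")
    dist = x_arr if fork == 1 else params.L - x_arr
    ht = np.asarray(modulation_integral(params.modulation, tau), dtype=float)
    dist, ht = np.broadcast_arrays(dist, ht)
    out = np.empty(dist.shape)
    zero = dist == 0.0
    out[zero] = 1.0  # degenerate first passage at the fork's own start
    if params.D == 0.0:
        out[~zero] = (ht[~zero] >= dist[~zero] / params.v0).astype(float)
    else:
        mu = dist[~zero] / params.v0
        lam_shape = dist[~zero] ** 2 / (2.0 * params.D)  # mu^3 / sigma^2
        out[~zero] = _ig_cdf(ht[~zero], mu, lam_shape)
    return out if out.shape else float(out)


def abundance(
    params: BacterialParams,
    positions: Sequence[float] | np.ndarray,
    quad_tol: float = DEFAULT_QUAD_TOL,
) -> np.ndarray:
    """DNA abundance P(x) = 1 - int_0^inf Lambda e^{-Lambda tau} (1-f1)(1-f2) dtau.

    The origin bins (x = 0 and x = L) have P = 1; the minimum sits near the
    fork meeting region around L/2, where the profile is smooth for D > 0
    and develops a cusp in the deterministic limit D = 0.
    """
    x = np.asarray(positions, dtype=float)
    if np.any((x < 0) | (x > params.L)):
        raise ValueError("positions must lie in [0, L]")
    lam = params.growth.lam
    if params.D == 0.0:
        # deterministic forks: replication age solves H(tau) = min(x, L-x)/v0
        dist = np.minimum(x, params.L - x)
        out = np.empty_like(dist)
        for i, d in enumerate(dist):
            tau_rep = _invert_modulation(params.modulation, d / params.v0)
            out[i] = math.exp(-lam * tau_rep)
        return out

    tau_max = -math.log(quad_tol) / lam
    # the integrand also dies once both forks are essentially done
    slowest = 1.0 - (params.modulation.delta if params.modulation else 0.0)
    tau_done = _invert_modulation(params.modulation, params.L / params.v0) + 10.0 * math.sqrt(
        2.0 * params.D * params.L / params.v0**3
    ) / max(slowest, 1e-6)
    upper = min(tau_max, tau_done)

    def integrand(tau: float) -> np.ndarray:
        f1 = fork_program(params, x, tau, fork=1)
        f2 = fork_program(params, x, tau, fork=2)
        return lam * math.exp(-lam * tau) * (1.0 - f1) * (1.0 - f2)

    val, err = integrate.quad_vec(integrand, 0.0, upper, epsabs=quad_tol, epsrel=1e-9, limit=200)
    if not np.all(np.isfinite(val)):
        raise RuntimeError("abundance quadrature failed")
    return np.clip(1.0 - val, 0.0, 1.0)


@dataclass
class ForkTrajectories:
    """Ensemble of simulated fork-pair trajectories.

    ``meeting_point`` and ``completion_age`` are per path; full paths
    (y1, y2 and the running extrema x1, x2 on ``time``) are recorded only
    for the first ``record_paths`` paths to keep memory bounded.
    """

    meeting_point: np.ndarray  # Z, bp
    completion_age: np.ndarray  # s
    flagged: np.ndarray  # paths hitting the age cap before completion
    time: np.ndarray | None = None
    y1: np.ndarray | None = None
    y2: np.ndarray | None = None
    x1: np.ndarray | None = None
    x2: np.ndarray | None = None


def simulate_forks(
    params: BacterialParams,
    n_paths: int,
    dt: float | None = None,
    seed: int | None = None,
    max_age: float | None = None,
    record_paths: int = 0,
) -> ForkTrajectories:
    """Euler-Maruyama simulation of the two-fork model until the forks meet.

    The default step keeps the drift displacement per step below L/1e5.
    Paths that have not completed by ``max_age`` (default: ten deterministic
    completion times) are flagged and assigned the cap age.
    """
    if dt is None:
        dt = params.L / (1e5 * params.v0)
    rng = np.random.default_rng(seed)
    mod = params.modulation
    tau_det = _invert_modulation(mod, params.L / (2.0 * params.v0))
    if max_age is None:
        max_age = 10.0 * tau_det

    n_rec = min(record_paths, n_paths)
    if n_rec:
        return _simulate_recorded(params, n_paths, dt, rng, max_age, n_rec)

    # block-vectorised stepping: within a block the y paths are plain
    # cumulative sums, the fork positions running extrema of those sums
    block = 256
    n_steps = int(math.ceil(max_age / dt))
    sqrt_dt = math.sqrt(dt)

    y1 = np.zeros(n_paths)
    y2 = np.full(n_paths, params.L)
    x1 = np.zeros(n_paths)
    x2 = np.full(n_paths, params.L)
    alive = np.arange(n_paths)
    z = np.full(n_paths, np.nan)
    t_done = np.full(n_paths, np.nan)

    step0 = 0
    while len(alive) and step0 < n_steps:
        nb = min(block, n_steps - step0)
        taus = (step0 + np.arange(nb)) * dt
        h = mod.h(taus) if mod is not None else np.ones(nb)
        drift = params.v0 * h * dt
        sig = np.sqrt(2.0 * params.D * h) * sqrt_dt
        na = len(alive)
        inc1 = drift[:, None] + sig[:, None] * rng.standard_normal((nb, na))
        y1b = y1[None, :] + np.cumsum(inc1, axis=0)
        inc2 = -drift[:, None] + sig[:, None] * rng.standard_normal((nb, na))
        y2b = y2[None, :] + np.cumsum(inc2, axis=0)
        x1b = np.maximum(np.maximum.accumulate(y1b, axis=0), x1[None, :])
        x2b = np.minimum(np.minimum.accumulate(y2b, axis=0), x2[None, :])
        met = x1b >= x2b
        met_any = met.any(axis=0)
        if met_any.any():
            first = met.argmax(axis=0)[met_any]
            cols = np.flatnonzero(met_any)
            paths = alive[cols]
            z[paths] = 0.5 * (x1b[first, cols] + x2b[first, cols])
            t_done[paths] = (step0 + first + 1) * dt
        keep = ~met_any
        y1, y2 = y1b[-1, keep], y2b[-1, keep]
        x1, x2 = x1b[-1, keep], x2b[-1, keep]
        alive = alive[keep]
        step0 += nb

    flagged = np.zeros(n_paths, dtype=bool)
    if len(alive):
        flagged[alive] = True
        z[alive] = np.clip(0.5 * (x1 + x2), 0.0, params.L)
        t_done[alive] = max_age
    np.clip(z, 0.0, params.L, out=z)
    return ForkTrajectories(meeting_point=z, completion_age=t_done, flagged=flagged)


def _simulate_recorded(
    params: BacterialParams,
    n_paths: int,
    dt: float,
    rng: np.random.Generator,
    max_age: float,
    n_rec: int,
) -> ForkTrajectories:
    """Per-step reference loop retaining full trajectories (small ensembles)."""
    mod = params.modulation
    y1 = np.zeros(n_paths)
    y2 = np.full(n_paths, params.L)
    x1 = np.zeros(n_paths)
    x2 = np.full(n_paths, params.L)
    z = np.full(n_paths, np.nan)
    t_done = np.full(n_paths, np.nan)
    active = np.ones(n_paths, dtype=bool)
    rec_t, rec_y1, rec_y2, rec_x1, rec_x2 = [], [], [], [], []

    tau = 0.0
    sqrt_dt = math.sqrt(dt)
    while active.any() and tau < max_age:
        h = float(mod.h(tau)) if mod is not None else 1.0
        drift = params.v0 * h * dt
        sig = math.sqrt(2.0 * params.D * h) * sqrt_dt
        idx = np.flatnonzero(active)
        y1[idx] += drift + sig * rng.standard_normal(len(idx))
        y2[idx] += -drift + sig * rng.standard_normal(len(idx))
        x1[idx] = np.maximum(x1[idx], y1[idx])
        x2[idx] = np.minimum(x2[idx], y2[idx])
        tau += dt
        met = idx[x1[idx] >= x2[idx]]
        if len(met):
            z[met] = 0.5 * (x1[met] + x2[met])
            t_done[met] = tau
            active[met] = False
        rec_t.append(tau)
        rec_y1.append(y1[:n_rec].copy())
        rec_y2.append(y2[:n_rec].copy())
        rec_x1.append(x1[:n_rec].copy())
        rec_x2.append(x2[:n_rec].copy())

    flagged = active.copy()
    z[flagged] = 0.5 * (x1[flagged] + x2[flagged])
    t_done[flagged] = max_age
    np.clip(z, 0.0, params.L, out=z)
    traj = ForkTrajectories(meeting_point=z, completion_age=t_done, flagged=flagged)
    traj.time = np.asarray(rec_t)
    traj.y1 = np.asarray(rec_y1).T
    traj.y2 = np.asarray(rec_y2).T
    traj.x1 = np.asarray(rec_x1).T
    traj.x2 = np.asarray(rec_x2).T
    return traj


def first_passage_times(
    params: BacterialParams,
    level: float,
    n_paths: int,
    dt: float | None = None,
    seed: int | None = None,
    max_age: float | None = None,
    fork: int = 1,
) -> np.ndarray:
    """Ages at which the chosen fork first reaches ``level`` (simulation).

    Unfinished paths (beyond the age cap) are returned as +inf; they only
    matter in the extreme tail.
    """
    if fork not in (1, 2):
        raise ValueError("fork must be 1 or 2")
    dist = level if fork == 1 else params.L - level
    if not 0 < dist <= params.L:
        raise ValueError("level must give a positive passage distance")
    if dt is None:
        dt = params.L / (1e5 * params.v0)
    rng = np.random.default_rng(seed)
    mod = params.modulation
    mu = dist / params.v0
    sd = math.sqrt(2.0 * params.D * dist / params.v0**3) if params.D > 0 else 0.0
    if max_age is None:
        max_age = _invert_modulation(mod, dist / params.v0) + max(20.0 * sd, 10.0 * mu)

    y = np.zeros(n_paths)
    t_pass = np.full(n_paths, np.inf)
    alive = np.arange(n_paths)
    block = 256
    n_steps = int(math.ceil(max_age / dt))
    sqrt_dt = math.sqrt(dt)
    # continuity correction for discretely monitored crossing: the discrete
    # running max misses within-step excursions; shifting the barrier by
    # 0.5826 * sigma * sqrt(dt) (Broadie-Glasserman) removes the O(sqrt(dt)) bias
    dist = dist - _BARRIER_BETA * math.sqrt(2.0 * params.D) * sqrt_dt
    step0 = 0
    while len(alive) and step0 < n_steps:
        nb = min(block, n_steps - step0)
        taus = (step0 + np.arange(nb)) * dt
        h = mod.h(taus) if mod is not None else np.ones(nb)
        inc = params.v0 * h[:, None] * dt + np.sqrt(2.0 * params.D * h)[:, None] * sqrt_dt * rng.standard_normal((nb, len(alive)))
        yb = y[None, :] + np.cumsum(inc, axis=0)
        crossed = np.maximum.accumulate(yb, axis=0) >= dist
        hit = crossed.any(axis=0)
        if hit.any():
            first = crossed.argmax(axis=0)[hit]
            t_pass[alive[hit]] = (step0 + first + 1) * dt
        y = yb[-1, ~hit]
        alive = alive[~hit]
        step0 += nb
    return t_pass


def replication_ages(
    params: BacterialParams,
    positions: Sequence[float] | np.ndarray,
    n_paths: int,
    dt: float | None = None,
    seed: int | None = None,
    max_age: float | None = None,
) -> np.ndarray:
    """Simulated replication age of each position: min over the two forks'
    first-passage times, with the forks independent (as in the joint
    program f = 1 - (1-f1)(1-f2)).  Returns an (n_paths, n_positions)
    array; +inf marks positions not reached by the age cap.
    """
    x = np.asarray(positions, dtype=float)
    if np.any((x < 0) | (x > params.L)):
        raise ValueError("positions must lie in [0, L]")
    if dt is None:
        dt = params.L / (1e5 * params.v0)
    rng = np.random.default_rng(seed)
    mod = params.modulation
    if max_age is None:
        sd = math.sqrt(2.0 * params.D * params.L / params.v0**3) if params.D > 0 else 0.0
        max_age = _invert_modulation(mod, params.L / params.v0) + max(20.0 * sd, params.L / params.v0)

    ages = np.full((2, n_paths, len(x)), np.inf)
    block = 256
    n_steps = int(math.ceil(max_age / dt))
    sqrt_dt = math.sqrt(dt)
    # Broadie-Glasserman continuity correction, as in first_passage_times
    shift = _BARRIER_BETA * math.sqrt(2.0 * params.D) * sqrt_dt
    for fork, dists_raw in enumerate((x, params.L - x)):
        dists = np.where(dists_raw > 0, np.maximum(dists_raw - shift, 1e-9), dists_raw)
        run = np.zeros(n_paths)
        extreme = np.zeros(n_paths)
        pending = np.flatnonzero(dists > 0)
        ages[fork][:, dists <= 0] = 0.0
        step0 = 0
        while len(pending) and step0 < n_steps:
            nb = min(block, n_steps - step0)
            taus = (step0 + np.arange(nb)) * dt
            h = mod.h(taus) if mod is not None else np.ones(nb)
            inc = params.v0 * h[:, None] * dt + np.sqrt(2.0 * params.D * h)[:, None] * sqrt_dt * rng.standard_normal((nb, n_paths))
            yb = run[None, :] + np.cumsum(inc, axis=0)
            mb = np.maximum(np.maximum.accumulate(yb, axis=0), extreme[None, :])
            still = []
            for j in pending:
                crossed = mb >= dists[j]
                hit = crossed.any(axis=0)
                not_yet = ages[fork][:, j] == np.inf
                newly = hit & not_yet
                if newly.any():
                    first = crossed.argmax(axis=0)[newly]
                    ages[fork][newly, j] = (step0 + first + 1) * dt
                if (ages[fork][:, j] == np.inf).any():
                    still.append(j)
            pending = np.array(still, dtype=int)
            run = yb[-1]
            extreme = mb[-1]
            step0 += nb
    return np.minimum(ages[0], ages[1])


def meeting_point_spread(params: BacterialParams) -> float:
    """Standard deviation of the fork meeting point: sqrt(D L / (2 v0))."""
    return math.sqrt(params.D * params.L / (2.0 * params.v0))
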