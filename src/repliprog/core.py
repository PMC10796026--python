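"""Age-structured theory of DNA abundance in growing populations.

In a steadily, exponentially growing asynchronous culture the ages tau of
the genomes (complete and incomplete) are exponentially distributed with
the population growth rate Lambda.  Any stochastic replication program --
a function f(x, tau) giving the probability that genome position x has
been copied by genome age tau -- then determines the DNA abundance
distribution

    P(x) = integral_0^inf  Lambda exp(-Lambda tau) f(x, tau) dtau,

which is what deep sequencing of such a culture measures (up to an overall
multiplicative scale).  This module implements that forward map, its
deterministic limit (a single fork moving at speed v(x)), and the inverse
of the deterministic limit: the replisome speed from the logarithmic slope
of the abundance, v(x) = -Lambda / (d ln P / dx).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

__all__ = [
    "GrowthRate",
    "AbundanceProfile",
    "SpeedProfile",
    "age_density",
    "abundance_from_program",
    "deterministic_abundance",
    "speed_from_abundance",
]

#: default truncation for exponential-weight quadratures
DEFAULT_QUAD_TOL = 1e-10


@dataclass(frozen=True)
class GrowthRate:
    """Exponential population growth rate Lambda, in 1/s.

    The doubling time of the culture is ``ln(2) / lam``.
    """

    lam: float

    def __post_init__(self) -> None:
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError(f"growth rate must be positive and finite, got {self.lam}")

    @property
    def doubling_time(self) -> float:
        return math.log(2.0) / self.lam

    @classmethod
    def from_doubling_time(cls, t2: float) -> "GrowthRate":
        return cls(math.log(2.0) / t2)


class AbundanceProfile:
    """Binned genome-wide DNA abundance track.

    Bins are 0-based, half-open ``[start, end)``, non-overlapping and sorted
    within each chromosome.  Values are non-negative and proportional to the
    abundance P(x); the overall scale is not identifiable from sequencing,
    so all comparisons against models profile a free multiplicative factor.
    """

    def __init__(self, df: pd.DataFrame, *, sort: bool = True):
        required = ["chrom", "start", "end", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"abundance table missing columns {missing}")
        df = df[required].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["value"] = df["value"].astype(float)
        if (df["end"] <= df["start"]).any():
            raise ValueError("bins must satisfy start < end")
        if (df["start"] < 0).any():
            raise ValueError("negative bin coordinates")
        if (df["value"] < 0).any():
            raise ValueError("abundance values must be non-negative")
        if sort:
            sorted_df = df.sort_values(["chrom", "start"], kind="mergesort")
            if not sorted_df.index.equals(df.index):
                warnings.warn("abundance bins were unsorted; sorting", stacklevel=2)
            df = sorted_df.reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping bins on chromosome {chrom!r}")
        self._df = df

    @classmethod
    def from_arrays(
        cls,
        chrom: str | Sequence[str],
        start: np.ndarray,
        end: np.ndarray,
        value: np.ndarray,
    ) -> "AbundanceProfile":
        n = len(start)
        chroms = [chrom] * n if isinstance(chrom, str) else list(chrom)
        return cls(pd.DataFrame({"chrom": chroms, "start": start, "end": end, "value": value}))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self._df["chrom"]))

    def __len__(self) -> int:
        return len(self._df)

    def chrom_slice(self, chrom: str) -> pd.DataFrame:
        sub = self._df[self._df["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"no bins for chromosome {chrom!r}")
        return sub

    def midpoints(self, chrom: str | None = None) -> np.ndarray:
        sub = self._df if chrom is None else self.chrom_slice(chrom)
        return 0.5 * (sub["start"].to_numpy() + sub["end"].to_numpy())

    def values(self, chrom: str | None = None) -> np.ndarray:
        sub = self._df if chrom is None else self.chrom_slice(chrom)
        return sub["value"].to_numpy()

    def bin_size(self, chrom: str | None = None) -> float:
        sub = self._df if chrom is None else self.chrom_slice(chrom)
        return float(np.median(sub["end"].to_numpy() - sub["start"].to_numpy()))

    def scaled(self, factor: float) -> "AbundanceProfile":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        df = self._df.copy()
        df["value"] *= factor
        return AbundanceProfile(df, sort=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceProfile):
            return NotImplemented
        return self._df.equals(other._df)


@dataclass
class SpeedProfile:
    """Replisome speed v(x) recovered from a deterministic abundance track.

    ``speed`` is signed: positive where the fork moves towards increasing
    coordinates.  Bins where the log-abundance slope vanishes get an
    infinite-speed sentinel and are flagged.
    """

    position: np.ndarray
    speed: np.ndarray
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = ~np.isfinite(self.speed)


def age_density(growth: GrowthRate, age) -> np.ndarray | float:
    """Probability density of genome age tau: Lambda * exp(-Lambda*tau).

    Genomes are born (age zero) when the replication round creating them
    initiates; exponential growth makes young genomes exponentially more
    common than old ones.
    """
    tau = np.asarray(age, dtype=float)
    if np.any(tau < 0):
        raise ValueError("genome age must be non-negative")
    out = growth.lam * np.exp(-growth.lam * tau)
    return out if out.shape else float(out)


def quad_truncation(growth: GrowthRate, quad_tol: float = DEFAULT_QUAD_TOL) -> float:
    """Age beyond which exp(-Lambda*tau) < quad_tol; quadratures stop there."""
    return -math.log(quad_tol) / growth.lam


def abundance_from_program(
    program: Callable[[float, float], float],
    growth: GrowthRate,
    positions: Sequence[float],
    quad_tol: float = DEFAULT_QUAD_TOL,
) -> np.ndarray:
    """DNA abundance P(x) of an arbitrary replication program.

    ``program(x, tau)`` must return the probability that position x is
    replicated by age tau (in [0, 1], non-decreasing in tau).  The integral
    over ages is evaluated by adaptive quadrature, truncated at the age
    where the exponential weight drops below ``quad_tol``.
    """
    lam = growth.lam
    tau_max = quad_truncation(growth, quad_tol)
    # a geometric panelling of the age axis: programs may jump or kink at
    # any time scale (e.g. step programs), and the panel error estimates
    # force local refinement wherever that happens
    breaks = np.concatenate([[0.0], tau_max * np.logspace(-6, 0, 25)])
    out = np.empty(len(positions))
    for i, x in enumerate(positions):
        total, total_err = 0.0, 0.0
        for lo, hi in zip(breaks[:-1], breaks[1:]):
            val, err = integrate.quad(
                lambda tau: lam * math.exp(-lam * tau) * program(x, tau),
                lo,
                hi,
                epsabs=quad_tol,
                epsrel=1e-9,
                limit=100,
            )
            total += val
            total_err += err
        if not math.isfinite(total) or total_err > max(1e-6, 100 * quad_tol):
            raise RuntimeError(
                f"quadrature did not converge at x={x}: value={total}, err={total_err}"
            )
        out[i] = total
    return np.clip(out, 0.0, 1.0)


def deterministic_abundance(
    origin_x: float,
    firing_age: float,
    speed_fn: Callable[[float], float] | float,
    growth: GrowthRate,
    positions: Sequence[float],
) -> np.ndarray:
    """Abundance for a deterministic single-origin program.

    A fork leaves the origin at ``firing_age`` and moves at local speed
    ``speed_fn(x)`` (bp/s, magnitude along the path), so position x is
    replicated at age tau(x) = firing_age + |integral_{x0}^{x} dx'/v(x')|
    and P(x) = exp(-Lambda * tau(x)).
    """
    lam = growth.lam
    if callable(speed_fn):
        v = speed_fn
    else:
        v0 = float(speed_fn)
        v = lambda x: v0  # noqa: E731
    out = np.empty(len(positions))
    for i, x in enumerate(positions):
        if x == origin_x:
            travel = 0.0
        else:
            val, _ = integrate.quad(lambda u: 1.0 / v(u), origin_x, x, limit=200)
            travel = abs(val)
        if not math.isfinite(travel):
            raise ZeroDivisionError("replisome speed vanishes on the integration path")
        out[i] = math.exp(-lam * (firing_age + travel))
    return out


def _boxcar(values: np.ndarray, window: int) -> np.ndarray:
    """Moving average with edge-aware normalisation (shrinking end windows)."""
    if window <= 1:
        return values
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def speed_from_abundance(
    profile: AbundanceProfile,
    growth: GrowthRate,
    smoothing_bp: float | None = None,
) -> SpeedProfile:
    """Invert a deterministic abundance track into a signed speed profile.

    v(x) = -Lambda / (d ln P/dx), with the log-slope estimated by central
    finite differences (one-sided at chromosome ends) after an optional
    boxcar smoothing over ``smoothing_bp``.  Defaults to 10 bins of
    smoothing.  Zero-slope bins are reported as +/-inf and flagged.
    """
    positions = []
    speeds = []
    boundary = []
    for chrom in profile.chromosomes:
        x = profile.midpoints(chrom)
        a = profile.values(chrom)
        if np.any(a <= 0):
            raise ValueError(f"abundance must be strictly positive on {chrom!r}")
        bin_bp = profile.bin_size(chrom)
        if smoothing_bp is None:
            window = 10
        else:
            window = max(1, int(round(smoothing_bp / bin_bp)))
        # smoothing in log space: an exponential decay has a linear log-track,
        # which a boxcar preserves (no boundary distortion of the slope scale)
        ln_a = _boxcar(np.log(a), window)
        slope = np.gradient(ln_a, x)
        with np.errstate(divide="ignore"):
            v = -growth.lam / slope
        positions.append(x)
        speeds.append(v)
        # the shrinking end windows bias the smoothed slope near chromosome
        # ends; mark those bins as unreliable
        edge = np.zeros(len(x), dtype=bool)
        k = window // 2 + 1 if window > 1 else 0
        if k:
            edge[:k] = True
            edge[-k:] = True
        boundary.append(edge)
    speed = np.concatenate(speeds)
    sp = SpeedProfile(position=np.concatenate(positions), speed=speed)
    sp.flagged |= np.concatenate(boundary)
    n_inf = int((~np.isfinite(speed)).sum())
    if n_inf:
        warnings.warn(
            f"{n_inf} bins have zero log-slope; speed undefined there", stacklevel=2
        )
    return sp
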