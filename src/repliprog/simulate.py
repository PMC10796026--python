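"""Synthetic abundance tracks for both model families.

The generators bin the exact model abundance and corrupt it with
measurement noise: either a multiplicative Gamma variate with mean 1 and a
configurable coefficient of variation (the default CV of 0.04 matches the
level used to benchmark origin inference), or Poisson read counts at a
given mean per-bin depth.  They emulate the noise floor of a deep
shotgun-sequencing coverage track; they do not emulate mappability gaps,
GC bias or copy-number variation, which real tracks carry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AbundanceProfile
from .yeast import YeastModelParams, closed_form_abundance
from .bacteria import BacterialParams, abundance as bacterial_abundance

__all__ = ["NoiseConfig", "simulate_yeast_abundance", "simulate_bacterial_abundance"]


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise model for synthetic tracks.

    kind="gamma": each bin is multiplied by an independent Gamma variate
    with mean 1 and coefficient of variation ``cv``.  kind="poisson": each
    bin becomes a Poisson read count with mean ``depth`` * P / mean(P).
    """

    kind: str = "gamma"
    cv: float = 0.04
    depth: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "gamma" and not self.cv >= 0:
            raise ValueError("gamma noise needs cv >= 0")
        if self.kind == "poisson" and not (self.depth and self.depth > 0):
            raise ValueError("poisson noise needs depth > 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        if self.kind == "gamma":
            if self.cv == 0.0:
                return values.copy()
            shape = 1.0 / self.cv**2
            return values * rng.gamma(shape, 1.0 / shape, size=len(values))
        mean = self.depth * values / np.mean(values)
        return rng.poisson(mean).astype(float)


def _bins(length: float, bin_bp: float) -> tuple[np.ndarray, np.ndarray]:
    if bin_bp < 1:
        raise ValueError("bin size must be at least 1 bp")
    edges = np.arange(0, int(length) + 1, int(bin_bp))
    if edges[-1] < length:
        edges = np.append(edges, int(length))
    return edges[:-1], edges[1:]


def simulate_yeast_abundance(
    params: YeastModelParams,
    chrom_length: float,
    bin_bp: float,
    noise: NoiseConfig | None = None,
    chrom: str | None = None,
) -> AbundanceProfile:
    """Binned point-origin model abundance with synthetic measurement noise."""
    if chrom is None:
        chrom = params.origins._only_chrom()
    start, end = _bins(chrom_length, bin_bp)
    mid = 0.5 * (start + end)
    values = closed_form_abundance(params, mid, chrom=chrom)
    if noise is not None:
        values = noise.apply(values)
    return AbundanceProfile.from_arrays(chrom, start, end, values)


def simulate_bacterial_abundance(
    params: BacterialParams,
    bin_bp: float,
    noise: NoiseConfig | None = None,
    chrom: str = "genome",
) -> AbundanceProfile:
    """Binned two-fork model abundance on the circular coordinate [0, L)."""
    start, end = _bins(params.L, bin_bp)
    mid = 0.5 * (start + end)
    values = bacterial_abundance(params, mid)
    if noise is not None:
        values = noise.apply(values)
    return AbundanceProfile.from_arrays(chrom, start, end, values)
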