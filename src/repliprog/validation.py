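"""Validation statistics for inferred origin sets against an annotation.

Compares two origin sets (e.g. inferred vs. a known annotation) by:

* Pearson correlation of Gaussian kernel density estimates of the two
  sets at a range of smoothing length scales (the scale is the kernel
  standard deviation), computed on a 1 kb grid per chromosome and
  concatenated across chromosomes;
* nearest-neighbour distances in either direction, with medians;
* two null models — independent uniform shifts of each origin, and a
  permutation of chromosome labels preserving within-chromosome relative
  positions — compared to the observed distances with a two-sided
  Mann-Whitney U rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .yeast import PointOriginSet

__all__ = [
    "ValidationReport",
    "density_correlation",
    "null_shift",
    "null_shuffle",
    "nearest_distances",
    "rank_test",
    "validate_origins",
]

GRID_BP = 1000.0  # density-estimate grid spacing


def _chrom_lengths(a: PointOriginSet, b: PointOriginSet | None = None) -> dict[str, float]:
    lengths: dict[str, float] = {}
    for s in (a, b) if b is not None else (a,):
        for c in s.chromosomes:
            pos, _ = s.for_chrom(c)
            lengths[c] = max(lengths.get(c, 0.0), float(pos.max()))
    return lengths


def density_correlation(
    inferred: PointOriginSet,
    known: PointOriginSet,
    scales,
    chrom_lengths: dict[str, float] | None = None,
) -> dict[float, float]:
    """Pearson correlation of the two origin densities per smoothing scale.

    Densities are unnormalised sums of Gaussian kernels (sd = scale)
    evaluated on a 1 kb grid over each chromosome present in either set,
    concatenated before the correlation.
    """
    if len(inferred) == 0 or len(known) == 0:
        raise ValueError("origin sets must be non-empty")
    lengths = chrom_lengths or _chrom_lengths(inferred, known)
    out: dict[float, float] = {}
    for scale in scales:
        dens_a, dens_b = [], []
        for c, L in lengths.items():
            grid = np.arange(0.0, L + GRID_BP, GRID_BP)
            dens_a.append(_kde(inferred, c, grid, scale))
            dens_b.append(_kde(known, c, grid, scale))
        da = np.concatenate(dens_a)
        db = np.concatenate(dens_b)
        out[float(scale)] = float(np.corrcoef(da, db)[0, 1])
    return out


def _kde(origins: PointOriginSet, chrom: str, grid: np.ndarray, scale: float) -> np.ndarray:
    try:
        pos, _ = origins.for_chrom(chrom)
    except KeyError:
        return np.zeros_like(grid)
    z = (grid[:, None] - pos[None, :]) / scale
    return np.sum(np.exp(-0.5 * z * z), axis=1)


def mean_half_spacing(origins: PointOriginSet) -> float:
    """Average half-distance between consecutive origins, pooled over chromosomes."""
    gaps = []
    for c in origins.chromosomes:
        pos, _ = origins.for_chrom(c)
        if len(pos) > 1:
            gaps.append(np.diff(pos))
    if not gaps:
        raise ValueError("need at least two origins on one chromosome")
    return float(np.mean(np.concatenate(gaps)) / 2.0)


def null_shift(
    origins: PointOriginSet,
    max_shift: float | None = None,
    seed: int | None = None,
    chrom_lengths: dict[str, float] | None = None,
) -> PointOriginSet:
    """Displace each origin by an independent uniform draw on [-max_shift, max_shift].

    The default shift range is five times the average half-distance between
    consecutive origins of the input set.  Shifted positions are clipped to
    the chromosome.
    """
    if len(origins) == 0:
        raise ValueError("origin set is empty")
    if max_shift is None:
        max_shift = 5.0 * mean_half_spacing(origins)
    lengths = chrom_lengths or _chrom_lengths(origins)
    rng = np.random.default_rng(seed)
    new_pos = origins.position + rng.uniform(-max_shift, max_shift, size=len(origins))
    limits = np.array([lengths[c] for c in origins.chrom])
    new_pos = np.clip(new_pos, 0.0, limits)
    # nudge apart exact collisions created by clipping
    for c in origins.chromosomes:
        mask = origins.chrom == c
        p = np.sort(new_pos[mask])
        for i in range(1, len(p)):
            if p[i] <= p[i - 1]:
                p[i] = p[i - 1] + 1.0
        new_pos[mask] = p
    return PointOriginSet(origins.chrom, new_pos, origins.intensity)


def null_shuffle(
    origins: PointOriginSet,
    seed: int | None = None,
    chrom_lengths: dict[str, float] | None = None,
) -> PointOriginSet:
    """Permute chromosome labels, preserving relative positions.

    Origins of chromosome i are mapped to the chromosome taking its place
    in a random permutation, keeping each origin's position as a fraction
    of chromosome length.  A single-chromosome set is returned unchanged.
    """
    if len(origins) == 0:
        raise ValueError("origin set is empty")
    lengths = chrom_lengths or _chrom_lengths(origins)
    chroms = origins.chromosomes
    if len(chroms) == 1:
        return PointOriginSet(origins.chrom, origins.position, origins.intensity)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(chroms))
    new_chrom, new_pos, new_iota = [], [], []
    for i, c in enumerate(chroms):
        target = chroms[perm[i]]
        pos, iota = origins.for_chrom(c)
        frac = pos / lengths[c]
        new_chrom.extend([target] * len(pos))
        new_pos.extend(frac * lengths[target])
        new_iota.extend(iota)
    return PointOriginSet(new_chrom, new_pos, new_iota)


def nearest_distances(a: PointOriginSet, b: PointOriginSet) -> tuple[np.ndarray, float]:
    """Distance from each origin of ``a`` to the closest origin of ``b``.

    Matches are restricted to the same chromosome; origins of ``a`` on a
    chromosome absent from ``b`` are excluded (NaN) with a warning.  Returns
    the per-origin distances (in a's sorted order) and their median.
    """
    dists = np.full(len(a), np.nan)
    missing = 0
    for c in a.chromosomes:
        pos_a, _ = a.for_chrom(c)
        mask = a.chrom == c
        try:
            pos_b, _ = b.for_chrom(c)
        except KeyError:
            missing += int(mask.sum())
            continue
        d = np.min(np.abs(pos_a[:, None] - pos_b[None, :]), axis=1)
        dists[mask] = d
    if missing:
        warnings.warn(
            f"{missing} origins on chromosomes absent from the reference; excluded from the median",
            stacklevel=2,
        )
    valid = dists[np.isfinite(dists)]
    median = float(np.median(valid)) if len(valid) else math.nan
    return dists, median


def rank_test(d_observed, d_null) -> float:
    """Two-sided Mann-Whitney U p-value for equal distance distributions."""
    d_obs = np.asarray(d_observed, dtype=float)
    d_nul = np.asarray(d_null, dtype=float)
    d_obs = d_obs[np.isfinite(d_obs)]
    d_nul = d_nul[np.isfinite(d_nul)]
    if len(d_obs) == 0 or len(d_nul) == 0:
        raise ValueError("both distance samples must be non-empty")
    pooled = np.concatenate([d_obs, d_nul])
    if np.all(pooled == pooled[0]):
        warnings.warn("all distances tied; rank test degenerate", stacklevel=2)
        return 1.0
    return float(stats.mannwhitneyu(d_obs, d_nul, alternative="two-sided").pvalue)


@dataclass
class ValidationReport:
    """Fig-3-style validation summary of inferred vs. known origins."""

    correlation_observed: dict[float, float]
    correlation_shift_null: dict[float, float]
    correlation_shuffle_null: dict[float, float]
    distances_inferred_to_known: np.ndarray
    distances_known_to_inferred: np.ndarray
    median_inferred_to_known: float
    median_known_to_inferred: float
    p_shift: float
    p_shuffle: float
    extras: dict = field(default_factory=dict)


def validate_origins(
    inferred: PointOriginSet,
    known: PointOriginSet,
    scales=(2e3, 5e3, 7e3, 1e4, 2e4, 5e4, 1e5),
    seed: int | None = None,
    chrom_lengths: dict[str, float] | None = None,
) -> ValidationReport:
    """Full validation pipeline: density correlations, distances, null tests."""
    lengths = chrom_lengths or _chrom_lengths(inferred, known)
    shifted = null_shift(known, seed=seed, chrom_lengths=lengths)
    shuffled = null_shuffle(known, seed=seed, chrom_lengths=lengths)
    corr_obs = density_correlation(inferred, known, scales, lengths)
    corr_shift = density_correlation(inferred, shifted, scales, lengths)
    corr_shuf = density_correlation(inferred, shuffled, scales, lengths)
    d_ik, med_ik = nearest_distances(inferred, known)
    d_ki, med_ki = nearest_distances(known, inferred)
    d_shift, _ = nearest_distances(inferred, shifted)
    d_shuf, _ = nearest_distances(inferred, shuffled)
    return ValidationReport(
        correlation_observed=corr_obs,
        correlation_shift_null=corr_shift,
        correlation_shuffle_null=corr_shuf,
        distances_inferred_to_known=d_ik,
        distances_known_to_inferred=d_ki,
        median_inferred_to_known=med_ik,
        median_known_to_inferred=med_ki,
        p_shift=rank_test(d_ik, d_shift),
        p_shuffle=rank_test(d_ik, d_shuf),
    )
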