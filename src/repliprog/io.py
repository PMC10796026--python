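"""Reading and writing abundance tracks (bedGraph/TSV) and origin sets (BED).

bedGraph tracks are plain 4-column text (chrom, start, end, value) with
0-based half-open bins.  Origin sets are BED6; the score column carries the
rescaled intensity iota = I*/v multiplied by 1e6 and rounded, and a sidecar
TSV next to the BED duplicates the exact float values (BED scores are
conventionally integers, which would destroy the dynamic range).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AbundanceProfile
from .yeast import PointOriginSet

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_origins_bed",
    "write_origins_bed",
]

DEFAULT_INTENSITY = 1e-4  # per bp, used when a BED file carries no usable score


def _sidecar(path) -> Path:
    return Path(str(path) + ".intensities.tsv")


def read_abundance(path, format: str | None = None) -> AbundanceProfile:
    """Read a binned abundance track from bedGraph or TSV.

    The two formats are the same 4-column table; TSV may carry a header
    line.  Unsorted input is sorted (with a warning); overlapping bins are
    an error.  Malformed lines raise with their line number.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "bedgraph"
    rows = []
    first_data = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "tsv" and first_data and not _is_numeric(fields[1:2]):
                first_data = False
                continue  # header
            first_data = False
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no data lines")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return AbundanceProfile(df)


def write_abundance(profile: AbundanceProfile, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "bedgraph"
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("chrom\tstart\tend\tvalue\n")
        for row in profile.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{float(row.value)!r}\n")


def _is_numeric(fields) -> bool:
    try:
        [float(f) for f in fields]
        return True
    except ValueError:
        return False


def write_origins_bed(origins: PointOriginSet, path, name_prefix: str = "origin") -> None:
    """Write origins as BED6 plus an exact-intensity sidecar TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, (c, p, io) in enumerate(zip(origins.chrom, origins.position, origins.intensity)):
            start = int(p)
            score = int(round(io * 1e6))
            fh.write(f"{c}\t{start}\t{start + 1}\t{name_prefix}_{i}\t{score}\t.\n")
    with open(_sidecar(path), "w") as fh:
        fh.write("chrom\tposition\tintensity\n")
        for c, p, io in zip(origins.chrom, origins.position, origins.intensity):
            fh.write(f"{c}\t{float(p)!r}\t{float(io)!r}\n")


def read_origins_bed(path) -> PointOriginSet:
    """Read an origin set from BED; exact intensities come from the sidecar
    TSV when present, otherwise score/1e6, otherwise a flagged default."""
    path = Path(path)
    side = _sidecar(path)
    if side.exists():
        df = pd.read_csv(side, sep="\t")
        return PointOriginSet(df["chrom"], df["position"], df["intensity"])
    chroms, pos, iota = [], [], []
    defaulted = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            chroms.append(fields[0])
            pos.append(float(start))
            if len(fields) >= 5 and _is_numeric(fields[4:5]) and float(fields[4]) > 0:
                iota.append(float(fields[4]) / 1e6)
            else:
                iota.append(DEFAULT_INTENSITY)
                defaulted += 1
    if defaulted:
        warnings.warn(
            f"{defaulted} origins had no usable score; intensity defaulted to {DEFAULT_INTENSITY}",
            stacklevel=2,
        )
    return PointOriginSet(chroms, pos, iota)
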