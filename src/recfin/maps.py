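"""Containers for per-interval and windowed population recombination maps.

A :class:`RhoMap` holds inter-SNP intervals with a per-bp population
recombination rate rho = 4*Ne*r, as produced by LD-based inference.
A :class:`WindowedMap` is the same landscape averaged into fixed-width
windows tiling each chromosome; windows with no underlying SNP-interval
coverage carry NaN (missing), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from recfin import intervals as iv


@dataclass
class RhoMap:
    """Sorted, non-overlapping intervals with per-bp rho; 0-based half-open."""

    df: pd.DataFrame  # chrom, start, end, rho

    def __post_init__(self):
        required = {"chrom", "start", "end", "rho"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"RhoMap frame needs columns {sorted(required)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> "RhoMap":
        rho = self.df["rho"].to_numpy(dtype=float)
        if np.any(~np.isfinite(rho)) or np.any(rho < 0):
            raise ValueError("rho must be finite and >= 0")
        iv.check_sorted_disjoint(self.df, "RhoMap")
        return self

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def chrom_lengths(self) -> dict[str, int]:
        """Chromosome extents implied by the map (max interval end)."""
        return {c: int(s["end"].max()) for c, s in self.df.groupby("chrom", sort=False)}

    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths().values()))

    def total_recombination(self) -> float:
        """Genome total of rho*bp (bp-weighted mass, conserved by re-windowing)."""
        return float((self.df["rho"] * (self.df["end"] - self.df["start"])).sum())

    def write(self, path: str | Path, header: bool = True) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write("#chrom\tstart\tend\trho\n")
            self.df.to_csv(fh, sep="\t", header=False, index=False,
                           columns=["chrom", "start", "end", "rho"])


def read_rho_map(path: str | Path, strict: bool = False) -> RhoMap:
    """Read a 4-column tab map (chrom, start, end, rho/bp); header optional.

    Malformed rows raise with the offending 1-based line number. Unsorted
    input is rejected when ``strict`` else sorted; overlaps always reject.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                parts = line.split()
            if lineno == 1 and parts[0].lower() in ("chrom", "chr", "chromosome"):
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            try:
                chrom, start, end, rho = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            if not np.isfinite(rho) or rho < 0:
                raise ValueError(f"{path}: line {lineno}: invalid rho {rho}")
            rows.append((chrom, start, end, rho))
    if not rows:
        raise ValueError(f"{path}: no intervals")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "rho"])
    sorted_df = iv.sort_intervals(df)
    if strict and not df[["chrom", "start", "end"]].equals(sorted_df[["chrom", "start", "end"]]):
        raise ValueError(f"{path}: intervals not sorted (strict mode)")
    return RhoMap(sorted_df).validate()


@dataclass
class WindowedMap:
    """Fixed-width windows tiling chromosomes; NaN rho marks missing coverage."""

    df: pd.DataFrame  # chrom, start, end, rho, covered
    width: int

    def __len__(self) -> int:
        return len(self.df)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(s["end"].max()) for c, s in self.df.groupby("chrom", sort=False)}

    def total_recombination(self) -> float:
        """rho mass with each window weighted by its covered bp."""
        sub = self.df[self.df["rho"].notna()]
        return float((sub["rho"] * sub["covered"]).sum())

    def genome_wide_rate(self) -> float:
        sub = self.df[self.df["rho"].notna()]
        cov = sub["covered"].sum()
        if cov <= 0:
            raise ValueError("windowed map has no covered bp")
        return float((sub["rho"] * sub["covered"]).sum() / cov)

    def as_track(self) -> pd.DataFrame:
        """Non-missing windows as a plain value track (for interval arithmetic)."""
        return self.df[self.df["rho"].notna()].reset_index(drop=True)

    def write_bedgraph(self, path: str | Path) -> None:
        sub = self.df[self.df["rho"].notna()]
        sub.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "rho"])
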