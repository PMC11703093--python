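"""Recombination hotspot calling from LD-based maps.

Two callers mirror two hotspot definitions:

* ``call_raw_hotspots`` works on the raw inter-SNP map: an interval is a
  candidate when its rho is at least ``fold`` times the bp-weighted mean
  rho of its flanking regions (default 50 kb each side, candidate
  excluded); maximal runs of consecutive candidates merge into one
  hotspot.
* ``call_window_hotspots`` works on a fixed-width windowed map (2 kb by
  default); within each maximal run of consecutive qualifying windows
  only the single highest-rate window is retained as the hotspot.

Flank means near chromosome ends fall back to the available one-sided
flank. Missing windows never qualify and break runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from recfin import intervals as iv
from recfin.maps import RhoMap, WindowedMap


@dataclass
class HotspotSet:
    """Called hotspots: chrom, start, end, peak rho, flank mean, fold."""

    df: pd.DataFrame  # chrom, start, end, peak, flank_mean, fold
    caller: str  # "raw" | "window2kb"

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> pd.DataFrame:
        return self.df[["chrom", "start", "end"]]

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def write_bed(self, path: str | Path) -> None:
        out = self.df.copy()
        out["name"] = [f"hs{i}" for i in range(len(out))]
        out["score"] = out["fold"].round(3)
        out["strand"] = "."
        out.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "name", "score", "strand"])

    @classmethod
    def read_bed(cls, path: str | Path, caller: str = "window2kb") -> "HotspotSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        df = iv.sort_intervals(df)
        df["peak"] = np.nan
        df["flank_mean"] = np.nan
        df["fold"] = np.nan
        return cls(df, caller)


@dataclass
class HotspotSummary:
    count: int
    fraction_recombination: float
    density_per_mb: float
    occupancy: float
    width_quantiles: dict[float, float]


def _flank_means(cov: iv.Coverage, starts: np.ndarray, ends: np.ndarray,
                 flank: int) -> np.ndarray:
    """bp-weighted mean rho over [s-flank, s) + [e, e+flank), clipped to data.

    Spans beyond chromosome ends simply contribute no coverage, so terminal
    intervals use the available one-sided flank. NaN when no flank covered.
    """
    ls = np.maximum(starts - flank, 0.0)
    w1, l1 = cov.span_sums(ls, starts.astype(float))
    w2, l2 = cov.span_sums(ends.astype(float), ends + float(flank))
    w, l = w1 + w2, l1 + l2
    return np.where(l > 0, (w / np.where(l > 0, l, 1.0)), np.nan)


def call_raw_hotspots(rmap: RhoMap, fold: float = 5.0, flank: int = 50000) -> HotspotSet:
    """Call hotspots on the raw inter-SNP map (see module docstring)."""
    if len(rmap) == 0:
        raise ValueError("empty map")
    records = []
    any_flank = False
    for chrom, sub in rmap.df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        rho = sub["rho"].to_numpy(dtype=float)
        cov = iv.Coverage(s.astype(float), e.astype(float), rho)
        fm = _flank_means(cov, s, e, flank)
        any_flank = any_flank or bool(np.any(~np.isnan(fm)))
        qual = ~np.isnan(fm) & (fm > 0) & (rho >= fold * fm)
        # maximal runs of consecutive qualifying intervals
        i = 0
        n = len(sub)
        while i < n:
            if not qual[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and qual[j + 1]:
                j += 1
            hs_s, hs_e = int(s[i]), int(e[j])
            peak = float(rho[i:j + 1].max())
            # re-audit against the merged span's own flanks
            mfm = _flank_means(cov, np.array([hs_s]), np.array([hs_e]), flank)[0]
            if np.isfinite(mfm) and mfm > 0 and peak >= fold * mfm:
                records.append((chrom, hs_s, hs_e, peak, mfm, peak / mfm))
            i = j + 1
    if not any_flank:
        raise ValueError("chromosomes too short: no interval has flank coverage")
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "peak",
                                        "flank_mean", "fold"])
    return HotspotSet(iv.sort_intervals(df), caller="raw")


def call_window_hotspots(wmap: WindowedMap, fold: float = 5.0,
                         flank: int = 50000) -> HotspotSet:
    """Call fixed-width hotspots on a windowed map (see module docstring)."""
    records = []
    for chrom, sub in wmap.df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        rho = sub["rho"].to_numpy(dtype=float)
        covered = sub["covered"].to_numpy(dtype=float)
        present = ~np.isnan(rho)
        cov = iv.Coverage(s[present].astype(float), e[present].astype(float),
                          rho[present])
        fm = np.full(len(sub), np.nan)
        fm[present] = _flank_means(cov, s[present], e[present], flank)
        qual = present & ~np.isnan(fm) & (fm > 0) & (rho >= fold * fm)
        i, n = 0, len(sub)
        while i < n:
            if not qual[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and qual[j + 1]:
                j += 1
            run = slice(i, j + 1)
            best = i + int(np.argmax(rho[run]))  # leftmost max: argmax ties -> first
            records.append((chrom, int(s[best]), int(e[best]), float(rho[best]),
                            float(fm[best]), float(rho[best] / fm[best])))
            i = j + 1
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "peak",
                                        "flank_mean", "fold"])
    return HotspotSet(iv.sort_intervals(df), caller=f"window{wmap.width // 1000}kb")


def summarize_hotspots(hs: HotspotSet, rmap: RhoMap,
                       genome_len: int | None = None) -> HotspotSummary:
    """Count, recombination fraction, density per Mb, genome occupancy, widths."""
    if genome_len is None:
        genome_len = rmap.genome_length()
    if len(hs) == 0:
        return HotspotSummary(0, 0.0, 0.0, 0.0, {})
    covs = iv.coverages(rmap.df, "rho")
    in_hs = 0.0
    for chrom, sub in hs.df.groupby("chrom", sort=False):
        if chrom not in covs:
            continue
        w, _ = covs[chrom].span_sums(sub["start"].to_numpy(dtype=float),
                                     sub["end"].to_numpy(dtype=float))
        in_hs += w.sum()
    total = rmap.total_recombination()
    widths = hs.widths()
    qs = (0.1, 0.25, 0.5, 0.75, 0.9)
    return HotspotSummary(
        count=len(hs),
        fraction_recombination=in_hs / total if total > 0 else 0.0,
        density_per_mb=len(hs) / (genome_len / 1e6),
        occupancy=float(widths.sum()) / genome_len,
        width_quantiles={q: float(np.quantile(widths, q)) for q in qs},
    )


def occupancy_from_density(density_per_mb: float, width: int = 2000) -> float:
    """Genome fraction occupied by fixed-width hotspots at a given density.

    density [1/Mb] * width [bp] / 1e6 [bp/Mb]; e.g. 13.6/Mb * 2 kb -> 2.7%.
    """
    return density_per_mb * width / 1e6


def width_distribution(hs: HotspotSet) -> tuple[dict[float, float], float]:
    """Width quantiles and the fraction of hotspots narrower than 2 kb."""
    if len(hs) == 0:
        raise ValueError("empty hotspot set")
    widths = hs.widths()
    qs = {q: float(np.quantile(widths, q)) for q in (0.1, 0.25, 0.5, 0.75, 0.9)}
    return qs, float(np.mean(widths < 2000))
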